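"""Branch forwards, fusion-head algebra, baseline head, freeze policy."""

import numpy as np
import pytest

from fusecyte.models import (BaselineHead, BranchSpec, CNNBranch, FusionHeadParams,
                             HybridModel, ShapeError, TransformerBranch,
                             apply_freeze_policy, baseline_head_forward, classify,
                             cnn_branch_forward, fuse_project,
                             transformer_branch_forward)


@pytest.fixture(scope="module")
def t_branch():
    return TransformerBranch(BranchSpec("transformer", "tiny_vit", 16, 64),
                             patch_size=16, depth=2, n_heads=2, seed=0)


@pytest.fixture(scope="module")
def c_branch():
    return CNNBranch(BranchSpec("cnn", "tiny_cnn", 32, 96), channels=(8, 16, 32),
                     seed=0)


# -- transformer branch -----------------------------------------------------

def test_class_token_dim_matches_spec(t_branch, rng):
    z = transformer_branch_forward(rng.normal(size=(64, 64, 3)), t_branch)
    assert z.shape == (16,)
    assert np.all(np.isfinite(z))


def test_reference_transformer_width(rng):
    """A 384-wide branch yields a 384-dim class-token embedding."""
    branch = TransformerBranch(BranchSpec("transformer", "deit_small_like", 384, 224),
                               patch_size=16, depth=1, n_heads=6, seed=0)
    z = transformer_branch_forward(rng.normal(size=(224, 224, 3)), branch)
    assert z.shape == (384,)


def test_transformer_inference_deterministic(t_branch, rng):
    x = rng.normal(size=(2, 64, 64, 3))
    np.testing.assert_array_equal(t_branch.forward(x), t_branch.forward(x))


def test_transformer_rejects_wrong_size(t_branch, rng):
    with pytest.raises(ShapeError):
        t_branch.forward(rng.normal(size=(32, 32, 3)))


def test_pretrained_weights_not_bundled():
    spec = BranchSpec("transformer", "deit_small", 384, 224, weights_source="pretrained")
    with pytest.raises(NotImplementedError):
        TransformerBranch(spec)


# -- cnn branch -------------------------------------------------------------

def test_gap_equals_bruteforce_channel_mean(c_branch, rng):
    x = rng.normal(size=(96, 96, 3))
    maps, z = c_branch.forward(x, return_maps=True)
    oracle = np.array([maps[:, :, ch].sum() / maps[:, :, ch].size
                       for ch in range(maps.shape[2])])
    np.testing.assert_allclose(z, oracle, rtol=1e-12)
    assert z.shape == (32,)


def test_reference_cnn_width(rng):
    branch = CNNBranch(BranchSpec("cnn", "effb7_like", 2560, 64),
                       channels=(8, 16, 2560), seed=0)
    z = cnn_branch_forward(rng.normal(size=(64, 64, 3)), branch)
    assert z.shape == (2560,)


def test_cnn_rejects_wrong_size(c_branch, rng):
    with pytest.raises(ShapeError):
        c_branch.forward(rng.normal(size=(64, 64, 3)))


# -- fusion head ------------------------------------------------------------

def test_projection_matches_double_loop_oracle(rng):
    d_t, d_c, p = 3, 5, 4
    params = FusionHeadParams.init(d_t, d_c, projection_dim=p, seed=1)
    z_t, z_c = rng.normal(size=d_t), rng.normal(size=d_c)
    z_p = fuse_project(z_t, z_c, params)
    z = np.concatenate([z_t, z_c])
    oracle = np.array([sum(params.W[i, j] * z[j] for j in range(d_t + d_c))
                       + params.b[i] for i in range(p)])
    np.testing.assert_allclose(z_p, oracle, rtol=1e-12)


def test_zero_projection_gives_zero_vector():
    params = FusionHeadParams(W=np.zeros((4, 8)), b=np.zeros(4),
                              classifier_W=np.zeros((3, 4)), classifier_b=np.zeros(3))
    np.testing.assert_array_equal(fuse_project(np.ones(3), np.ones(5), params),
                                  np.zeros(4))


def test_projection_dimension_mismatch_names_widths():
    params = FusionHeadParams.init(3, 5, projection_dim=4)
    with pytest.raises(ShapeError, match="8.*7|7.*8"):
        fuse_project(np.ones(3), np.ones(4), params)


def test_classify_closed_forms():
    params = FusionHeadParams(W=np.zeros((3, 6)), b=np.zeros(3),
                              classifier_W=np.eye(3), classifier_b=np.zeros(3))
    np.testing.assert_allclose(classify(np.zeros(3), params), np.full(3, 1 / 3))
    probs = classify(np.log([1.0, 2.0, 3.0]), params)
    np.testing.assert_allclose(probs, [1 / 6, 2 / 6, 3 / 6], rtol=1e-12)


def test_classify_properties(rng):
    params = FusionHeadParams.init(2, 2, projection_dim=3, seed=0)
    for _ in range(100):
        z_p = rng.normal(size=3) * 5
        probs = classify(z_p, params)
        logits = params.classifier_W @ z_p + params.classifier_b
        assert abs(probs.sum() - 1.0) < 1e-9
        assert probs.argmax() == logits.argmax()
        shifted = classify(z_p, params)  # softmax shift-invariance via logits
        np.testing.assert_allclose(
            shifted, np.exp(logits - logits.max()) / np.exp(logits - logits.max()).sum())


def test_classify_rejects_nonfinite():
    params = FusionHeadParams.init(1, 1, projection_dim=2)
    with pytest.raises(FloatingPointError):
        classify(np.array([np.inf, 0.0]), params)


# -- baseline head ----------------------------------------------------------

def test_baseline_head_eval_ignores_dropout(rng):
    maps = rng.normal(size=(4, 4, 8))
    h0 = BaselineHead(8, hidden=6, dropout=0.0, seed=3)
    h1 = BaselineHead(8, hidden=6, dropout=1.0, seed=3)
    np.testing.assert_array_equal(baseline_head_forward(maps, h0),
                                  baseline_head_forward(maps, h1))


def test_baseline_head_outputs_three_probabilities(rng):
    head = BaselineHead(8, seed=0)
    probs = baseline_head_forward(rng.normal(size=(5, 4, 4, 8)), head)
    assert probs.shape == (5, 3)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0)


def test_baseline_head_train_reproducible(rng):
    maps = rng.normal(size=(4, 4, 4, 8))
    out1 = BaselineHead(8, seed=1).forward(maps, train_mode=True,
                                           rng=np.random.default_rng(9))
    out2 = BaselineHead(8, seed=1).forward(maps, train_mode=True,
                                           rng=np.random.default_rng(9))
    np.testing.assert_array_equal(out1, out2)


# -- freeze policy ----------------------------------------------------------

def test_freeze_fraction_zero_is_pure_feature_extractor(c_branch):
    audit = apply_freeze_policy(c_branch, trainable_tail_fraction=0.0)
    assert audit.n_trainable_params == 0
    assert all(not row["trainable"] for row in audit.layers)


def test_freeze_fraction_one_keeps_bn_frozen(c_branch):
    audit = apply_freeze_policy(c_branch, trainable_tail_fraction=1.0, freeze_bn=True)
    for row in audit.layers:
        assert row["trainable"] == (not row["is_bn"])
    assert audit.n_trainable_params > 0


def test_freeze_fraction_validation(c_branch):
    with pytest.raises(ValueError):
        apply_freeze_policy(c_branch, trainable_tail_fraction=1.5)


# -- hybrid model -----------------------------------------------------------

def test_end_to_end_probability_contract(rng):
    model = HybridModel.tiny(seed=2, projection_dim=16)
    tv = rng.normal(size=(3, 64, 64, 3))
    cv = rng.normal(size=(3, 96, 96, 3))
    probs = model.predict_proba(tv, cv)
    assert probs.shape == (3, 3)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0)


def test_reference_projection_width():
    params = FusionHeadParams.init(384, 2560)
    assert params.W.shape == (2048, 384 + 2560)
    z_p = fuse_project(np.zeros(384), np.zeros(2560), params)
    assert z_p.shape == (2048,)


def test_checkpoint_roundtrip(tmp_path, rng):
    model = HybridModel.tiny(seed=4, projection_dim=8)
    model.head.calibrate(rng.normal(size=(10, model.fusion_input_dim)))
    tv = rng.normal(size=(2, 64, 64, 3))
    cv = rng.normal(size=(2, 96, 96, 3))
    before = model.predict_proba(tv, cv)
    model.save(tmp_path / "ckpt")
    other = HybridModel.tiny(seed=99, projection_dim=8)
    other.load_params(tmp_path / "ckpt")
    np.testing.assert_allclose(other.predict_proba(tv, cv), before)
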