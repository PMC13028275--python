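"""Manifest I/O, stratified splitting, dual views and batch augmentation."""

import math

import numpy as np
import pytest

from fusecyte.constants import CLASSES
from fusecyte.dataio import (AugmentConfig, DatasetManifest, DualViewSample,
                             InfeasibleSplitError, ManifestError, ManifestRecord,
                             SplitPlan, UnknownLabelError, load_manifest,
                             make_dual_views, mixup_cutmix, stratified_holdout,
                             stratified_kfold)


def make_manifest(counts):
    """In-memory manifest with dummy paths (no files needed for splitting)."""
    records, rid = [], 0
    for label, n in zip(CLASSES, counts):
        for _ in range(n):
            records.append(ManifestRecord(rid, f"{label}_{rid}.png", label))
            rid += 1
    return DatasetManifest(records)


# -- manifest loading -------------------------------------------------------

def test_load_manifest_roundtrip(tiny_dataset_dir):
    m = load_manifest(tiny_dataset_dir)
    assert len(m) == 60
    assert m.class_counts == {"astrocyte": 20, "cortical": 20, "shsy5y": 20}
    assert [r.record_id for r in m.records] == list(range(60))


def test_load_manifest_errors(tmp_path):
    with pytest.raises(ManifestError):
        load_manifest(tmp_path)  # missing csv
    (tmp_path / "manifest.csv").write_text("filename,label\n")
    with pytest.raises(ManifestError, match="no records"):
        load_manifest(tmp_path)
    (tmp_path / "manifest.csv").write_text("filename,label\nx.png,neuron\n")
    with pytest.raises(UnknownLabelError, match="row 2"):
        load_manifest(tmp_path)
    (tmp_path / "manifest.csv").write_text("filename,label\nmissing.png,cortical\n")
    with pytest.raises(ManifestError, match="row 2"):
        load_manifest(tmp_path)


# -- stratified holdout -----------------------------------------------------

def holdout_sizes_oracle(counts, fractions):
    """Hand application of the rounding rule: per-class floors, remainders by
    largest fractional part, ties to the earlier role."""
    totals = [0, 0, 0]
    for n in counts:
        exact = [f * n for f in fractions]
        base = [math.floor(e) for e in exact]
        rem = n - sum(base)
        order = sorted(range(3), key=lambda i: (-(exact[i] - base[i]), i))
        for i in order[:rem]:
            base[i] += 1
        for i in range(3):
            totals[i] += base[i]
    return tuple(totals)


def test_holdout_sizes_on_reference_counts():
    """320/150/130 at 70/15/15 gives (420, 91, 89) under the stated rule."""
    counts = (130, 320, 150)  # manifest order: astrocyte, cortical, shsy5y
    manifest = make_manifest(counts)
    plan = stratified_holdout(manifest, (0.70, 0.15, 0.15), seed=0)
    sizes = tuple(len(plan.role_ids(r)) for r in ("train", "val", "test"))
    assert sizes == holdout_sizes_oracle(counts, (0.70, 0.15, 0.15)) == (420, 91, 89)
    assert sum(sizes) == len(manifest)


def test_holdout_exact_fractions():
    plan = stratified_holdout(make_manifest((100, 100, 100)), seed=1)
    labels = make_manifest((100, 100, 100)).labels
    for role, expected in zip(("train", "val", "test"), (70, 15, 15)):
        ids = plan.role_ids(role)
        for c in range(3):
            assert int(np.sum(labels[ids] == c)) == expected


def test_holdout_seed_changes_membership_not_counts():
    manifest = make_manifest((40, 25, 18))
    p1 = stratified_holdout(manifest, seed=1)
    p2 = stratified_holdout(manifest, seed=2)
    assert p1.assignments != p2.assignments
    labels = manifest.labels
    for role in ("train", "val", "test"):
        c1 = np.bincount(labels[p1.role_ids(role)], minlength=3)
        c2 = np.bincount(labels[p2.role_ids(role)], minlength=3)
        assert (c1 == c2).all()


def test_holdout_infeasible_class():
    with pytest.raises(InfeasibleSplitError):
        stratified_holdout(make_manifest((2, 10, 10)), seed=0)


def test_split_plan_json_roundtrip(tmp_path):
    plan = stratified_holdout(make_manifest((10, 10, 10)), seed=3)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    back = SplitPlan.from_json(path)
    assert back.assignments == plan.assignments
    assert back.kind == "holdout" and back.seed == 3


# -- stratified k-fold ------------------------------------------------------

def test_kfold_partition_properties():
    manifest = make_manifest((130, 320, 150))
    plan = stratified_kfold(manifest, k=5, seed=0)
    all_ids = sorted(i for k in range(5) for i in plan.role_ids(k))
    assert all_ids == list(range(len(manifest)))  # disjoint + exhaustive
    labels = manifest.labels
    # reference counts are divisible by 5: every fold is exactly 120
    for k in range(5):
        ids = plan.role_ids(k)
        assert len(ids) == 120
        assert np.bincount(labels[ids], minlength=3).tolist() == [26, 64, 30]


def test_kfold_matches_sklearn_fold_size_profile():
    """Per-class fold occupancy agrees with sklearn's StratifiedKFold."""
    from sklearn.model_selection import StratifiedKFold

    manifest = make_manifest((17, 23, 11))
    labels = manifest.labels
    plan = stratified_kfold(manifest, k=4, seed=0)
    skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
    sk_folds = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
    for c in range(3):
        ours = sorted(int(np.sum(labels[plan.role_ids(k)] == c)) for k in range(4))
        theirs = sorted(int(np.sum(labels[f] == c)) for f in sk_folds)
        assert ours == theirs


def test_kfold_k1_and_infeasible():
    manifest = make_manifest((4, 4, 4))
    plan = stratified_kfold(manifest, k=1, seed=0)
    assert plan.role_ids(0) == list(range(12))
    with pytest.raises(InfeasibleSplitError):
        stratified_kfold(manifest, k=5, seed=0)


# -- dual views -------------------------------------------------------------

def test_eval_views_shapes_and_label(rng):
    img = rng.random((256, 256))
    s = make_dual_views(img, label=1)
    assert s.transformer_view.shape == (224, 224, 3)
    assert s.cnn_view.shape == (448, 448, 3)
    assert s.label.tolist() == [0.0, 1.0, 0.0]


def test_zero_magnitude_train_equals_eval(small_aug, rng):
    img = rng.random((128, 128))
    ev = make_dual_views(img, aug=small_aug)
    tr = make_dual_views(img, train_mode=True, aug=small_aug.zeroed(),
                         rng=np.random.default_rng(0))
    np.testing.assert_allclose(tr.transformer_view, ev.transformer_view)
    np.testing.assert_allclose(tr.cnn_view, ev.cnn_view)


def test_train_views_deterministic_given_rng(small_aug, rng):
    img = rng.random((128, 128))
    a = make_dual_views(img, train_mode=True, aug=small_aug, rng=np.random.default_rng(5))
    b = make_dual_views(img, train_mode=True, aug=small_aug, rng=np.random.default_rng(5))
    np.testing.assert_array_equal(a.transformer_view, b.transformer_view)
    np.testing.assert_array_equal(a.cnn_view, b.cnn_view)


def test_views_share_one_crop(small_aug, rng):
    """Downsampled CNN view correlates strongly with the transformer view."""
    from scipy.ndimage import gaussian_filter
    from skimage.transform import resize

    img = gaussian_filter(rng.random((160, 160)), 4.0)
    img = (img - img.min()) / (img.max() - img.min())
    s = make_dual_views(img, aug=small_aug)
    down = resize(s.cnn_view[:, :, 0], (64, 64), preserve_range=True)
    corr = np.corrcoef(down.ravel(), s.transformer_view[:, :, 0].ravel())[0, 1]
    assert corr > 0.9


def test_small_image_upsampled_with_warning(small_aug, caplog):
    import logging

    img = np.random.default_rng(0).random((20, 20))
    with caplog.at_level(logging.WARNING, logger="fusecyte.dataio"):
        s = make_dual_views(img, aug=small_aug)
    assert s.transformer_view.shape == (64, 64, 3)
    assert any("upsampling" in r.message for r in caplog.records)


# -- mixup / cutmix ---------------------------------------------------------

class ScriptedRng:
    """Minimal rng stand-in driving mixup_cutmix down a chosen path."""

    def __init__(self, randoms, beta_value, perm):
        self._randoms = list(randoms)
        self._beta = beta_value
        self._perm = np.asarray(perm)

    def random(self):
        return self._randoms.pop(0)

    def beta(self, a, b):
        return self._beta

    def permutation(self, n):
        return self._perm


def _sample(rng, label, size=8):
    v = rng.random((size, size, 3))
    return DualViewSample(v, rng.random((2 * size, 2 * size, 3)), label)


def test_mixup_label_arithmetic(rng):
    batch = [_sample(rng, 0), _sample(rng, 1)]
    # path: apply (0.0 < prob), mixup (0.1 < 0.5), lam = 0.3, swap pairing
    out = mixup_cutmix(batch, apply_prob=0.5, rng=ScriptedRng([0.0, 0.1], 0.3, [1, 0]))
    np.testing.assert_allclose(out[0].label, [0.3, 0.7, 0.0])
    np.testing.assert_allclose(
        out[0].transformer_view,
        0.3 * batch[0].transformer_view + 0.7 * batch[1].transformer_view)


def test_lambda_one_is_identity(rng):
    batch = [_sample(rng, 0), _sample(rng, 2)]
    out = mixup_cutmix(batch, apply_prob=1.0, rng=ScriptedRng([0.0, 0.1], 1.0, [1, 0]))
    for a, b in zip(out, batch):
        np.testing.assert_allclose(a.transformer_view, b.transformer_view)
        np.testing.assert_allclose(a.label, b.label)


def test_cutmix_label_weight_tracks_patch_area(rng):
    batch = [_sample(rng, 0, size=32), _sample(rng, 1, size=32)]
    # cutmix path with lam=0.75 -> 25% patch centered in the image
    out = mixup_cutmix(batch, apply_prob=1.0,
                       rng=ScriptedRng([0.0, 0.9, 0.5, 0.5], 0.75, [1, 0]))
    changed = np.any(out[0].cnn_view != batch[0].cnn_view, axis=2).mean()
    host_weight = out[0].label[0]
    assert abs(host_weight - (1 - changed)) < 1 / 32  # one row of quantization
    assert abs(host_weight - 0.75) < 0.05


def test_batch_of_one_returned_unchanged(rng):
    batch = [_sample(rng, 0)]
    assert mixup_cutmix(batch, rng=rng) is batch


def test_labels_remain_probability_vectors(rng):
    batch = [_sample(rng, i % 3) for i in range(6)]
    for trial in range(10):
        out = mixup_cutmix(batch, apply_prob=1.0, rng=np.random.default_rng(trial))
        for s in out:
            assert np.all(s.label >= -1e-12)
            assert abs(s.label.sum() - 1.0) < 1e-9
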