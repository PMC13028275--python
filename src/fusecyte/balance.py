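"""Feature-space SMOTE rebalancing with an explicit leakage guard.

Class rebalancing happens in representation space, not pixel space: embeddings
are taken at the fusion point — the concatenation ``[z_t; z_c]`` of the
transformer class-token vector and the globally pooled CNN descriptor — under
deterministic eval-mode preprocessing.  Synthetic minority samples are linear
interpolations ``x + u * (x_nn - x)`` between a minority vector and one of its
k same-class nearest neighbors (Euclidean), generated until every class
reaches the majority count.  Synthetic rows are flagged and may only ever be
attached to training data; :func:`leakage_guard` audits that rule plus
train/eval record disjointness before any metric is reported.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from fusecyte.constants import CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSet", "LeakageError", "ContractError", "LeakageAudit",
    "extract_embeddings", "smote_balance", "leakage_guard",
]

REAL, SYNTHETIC = "real", "synthetic"
EVAL_SPLITS = ("val", "test")


class LeakageError(RuntimeError):
    """Synthetic data or training records reached an evaluation split."""


class ContractError(ValueError):
    """A model's declared embedding width disagrees with its output."""


@dataclass
class EmbeddingSet:
    """Fusion-point feature vectors with labels and provenance flags.

    ``record_ids`` ties real rows back to manifest records; synthetic rows
    carry ``record_id = -1``.
    """

    vectors: np.ndarray           # (N, D)
    labels: np.ndarray            # (N,) integer class indices
    provenance: np.ndarray        # (N,) "real" | "synthetic"
    source_split: str             # "train" | "val" | "test"
    record_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        n = self.vectors.shape[0]
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValueError("labels/provenance length must match vector count")
        if self.record_ids is None:
            rid = np.arange(n)
            rid[self.provenance == SYNTHETIC] = -1
            self.record_ids = rid
        self.record_ids = np.asarray(self.record_ids, dtype=int)
        if self.record_ids.shape != (n,):
            raise ValueError("record_ids length must match vector count")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_real(self) -> int:
        return int(np.sum(self.provenance == REAL))

    @property
    def n_synthetic(self) -> int:
        return int(np.sum(self.provenance == SYNTHETIC))

    def class_counts(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    def save(self, path: str | Path) -> None:
        """Write vectors to ``<path>.npz`` plus a JSON sidecar with metadata."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), vectors=self.vectors)
        sidecar = {
            "labels": self.labels.tolist(),
            "provenance": self.provenance.tolist(),
            "record_ids": self.record_ids.tolist(),
            "dims": int(self.dim),
            "source_split": self.source_split,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingSet":
        path = Path(path)
        vectors = np.load(path.with_suffix(".npz"))["vectors"]
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        return cls(vectors=vectors, labels=np.array(meta["labels"]),
                   provenance=np.array(meta["provenance"], dtype=object),
                   source_split=meta["source_split"],
                   record_ids=np.array(meta["record_ids"]))


def extract_embeddings(model, records: Sequence, source_split: str = "train",
                       aug=None, batch_size: int = 32) -> EmbeddingSet:
    """Embed manifest records at the model's fusion point.

    Runs eval-mode preprocessing (deterministic center crop, no jitter) and
    the frozen branches; one row of ``[z_t; z_c]`` per record, provenance all
    real.  Raises :class:`ContractError` if the model's declared fusion width
    disagrees with what it produces.
    """
    from fusecyte.dataio import load_image, make_dual_views

    vecs: list[np.ndarray] = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        tvs, cvs = [], []
        for rec in chunk:
            sample = make_dual_views(load_image(rec.path), train_mode=False, aug=aug)
            tvs.append(sample.transformer_view)
            cvs.append(sample.cnn_view)
        z = model.embed_views(np.stack(tvs), np.stack(cvs))
        vecs.append(np.asarray(z, dtype=np.float64))
    vectors = np.concatenate(vecs, axis=0) if vecs else np.zeros((0, model.fusion_input_dim))
    declared = int(model.fusion_input_dim)
    if vectors.shape[1] != declared:
        raise ContractError(
            f"model declares fusion width {declared} but produced {vectors.shape[1]}")
    from fusecyte.constants import CLASS_TO_INDEX
    labels = np.array([CLASS_TO_INDEX[r.label] for r in records], dtype=int)
    return EmbeddingSet(vectors=vectors, labels=labels,
                        provenance=np.array([REAL] * len(records), dtype=object),
                        source_split=source_split,
                        record_ids=np.array([r.record_id for r in records], dtype=int))


def smote_balance(embeddings: EmbeddingSet, k_neighbors: int = 5,
                  seed: int = 0) -> EmbeddingSet:
    """Oversample every minority class to the majority count by SMOTE.

    For each needed synthetic row a minority vector ``x`` is drawn at random,
    one of its ``k`` same-class nearest neighbors ``x_nn`` is drawn, and the
    new row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``.  Original
    rows are retained unchanged (and first); synthetic rows are appended with
    provenance "synthetic".  Refuses to run on val/test-tagged embeddings.
    """
    if embeddings.source_split != "train":
        raise LeakageError(
            f"SMOTE may only be applied to training embeddings, got "
            f"source_split={embeddings.source_split!r}")
    if len(embeddings) == 0:
        raise ValueError("cannot balance an empty embedding set")
    rng = np.random.default_rng(seed)
    counts = embeddings.class_counts()
    majority = max(counts.values())

    new_vecs: list[np.ndarray] = []
    new_labels: list[int] = []
    for cls in sorted(counts):
        need = majority - counts[cls]
        if need == 0:
            continue
        X = embeddings.vectors[embeddings.labels == cls]
        n = X.shape[0]
        if n == 1:
            warnings.warn(f"class {cls} has a single sample; duplicating it "
                          f"{need} times (no neighbor exists)")
            new_vecs.append(np.repeat(X, need, axis=0))
            new_labels.extend([cls] * need)
            continue
        k = min(k_neighbors, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, n, size=need)
        pick = rng.integers(0, k, size=need)
        u = rng.random(need)
        x = X[base]
        x_nn = X[neighbor_idx[base, pick]]
        new_vecs.append(x + u[:, None] * (x_nn - x))
        new_labels.extend([cls] * need)

    if not new_vecs:
        return embeddings
    synth = np.concatenate(new_vecs, axis=0)
    return EmbeddingSet(
        vectors=np.concatenate([embeddings.vectors, synth], axis=0),
        labels=np.concatenate([embeddings.labels, np.array(new_labels, dtype=int)]),
        provenance=np.concatenate([embeddings.provenance,
                                   np.array([SYNTHETIC] * len(new_labels), dtype=object)]),
        source_split=embeddings.source_split,
        record_ids=np.concatenate([embeddings.record_ids,
                                   np.full(len(new_labels), -1, dtype=int)]),
    )


@dataclass
class LeakageAudit:
    """Machine-readable result of the leakage checks."""

    checks: dict[str, dict] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks.values())

    def to_dict(self) -> dict:
        return {"passed": self.passed, "checks": self.checks}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def leakage_guard(split_plan, embedding_sets: Sequence[EmbeddingSet]) -> LeakageAudit:
    """Audit a collection of embedding sets for evaluation leakage.

    Checks: (i) no synthetic row is tagged val/test; (ii) no real record id
    appears in both a train-tagged set and a val/test-tagged set; (iii) when a
    split plan is supplied, every real record id is covered by the plan.
    Training drivers must refuse to report metrics when the audit fails.
    """
    audit = LeakageAudit()

    bad_synth = []
    for idx, es in enumerate(embedding_sets):
        if es.source_split in EVAL_SPLITS and es.n_synthetic > 0:
            bad_synth.append((idx, es.source_split, es.n_synthetic))
    audit.checks["no_synthetic_in_eval"] = {
        "passed": not bad_synth,
        "detail": ("synthetic rows found in eval-tagged sets: " + repr(bad_synth)
                   if bad_synth else "no synthetic rows outside training sets"),
    }

    train_ids: set[int] = set()
    eval_ids: set[int] = set()
    for es in embedding_sets:
        real_ids = set(int(i) for i in es.record_ids[es.provenance == REAL] if i >= 0)
        (train_ids if es.source_split == "train" else eval_ids).update(real_ids)
    overlap = sorted(train_ids & eval_ids)
    audit.checks["train_eval_disjoint"] = {
        "passed": not overlap,
        "detail": (f"record ids in both train and eval sets: {overlap[:10]}"
                   if overlap else "train and eval record ids are disjoint"),
    }

    if split_plan is not None:
        unknown = sorted((train_ids | eval_ids) - set(split_plan.assignments))
        audit.checks["plan_coverage"] = {
            "passed": not unknown,
            "detail": (f"record ids absent from the split plan: {unknown[:10]}"
                       if unknown else "every embedded record is covered by the plan"),
        }

    if not audit.passed:
        logger.warning("leakage audit FAILED: %s", audit.to_dict())
    return audit
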