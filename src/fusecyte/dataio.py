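"""Manifest loading, stratified splitting and dual-resolution preprocessing.

The experiment protocol needs two split shapes: a stratified 70/15/15
holdout (train/val/test) and stratified k-fold cross-validation.  Both are
deterministic given a seed and allocate per class so that role proportions
deviate from the global class proportions by at most one record.

Preprocessing renders every image at two resolutions from the *same* spatial
crop — a 224 px view for the transformer branch and a 448 px view for the CNN
branch — replicating the grayscale channel to RGB and normalizing with the
backbone's pretraining statistics.  Training-time augmentation covers random
resized crops, brightness/contrast jitter (hue/saturation are undefined on
single-channel input), Gaussian blur, and batch-level MixUp/CutMix with soft
labels.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from fusecyte.constants import CLASSES, CLASS_TO_INDEX, N_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "ManifestRecord", "DatasetManifest", "SplitPlan", "AugmentConfig",
    "DualViewSample", "load_manifest", "load_image", "stratified_holdout",
    "stratified_kfold", "make_dual_views", "mixup_cutmix",
    "ManifestError", "UnknownLabelError", "InfeasibleSplitError",
]

HOLDOUT_ROLES = ("train", "val", "test")

#: ImageNet channel statistics — the pretraining distribution of the default
#: backbones; configurable per AugmentConfig.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


class ManifestError(ValueError):
    pass


class UnknownLabelError(ManifestError):
    pass


class InfeasibleSplitError(ValueError):
    pass


class ManifestRecord(NamedTuple):
    record_id: int
    path: Path
    label: str


@dataclass
class DatasetManifest:
    """Ordered image records with labels; record ids are contiguous from 0."""

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if ids != list(range(len(ids))):
            raise ManifestError("record ids must be unique and contiguous from 0")
        for r in self.records:
            if r.label not in CLASSES:
                raise UnknownLabelError(f"record {r.record_id}: unknown label {r.label!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for r in self.records:
            counts[r.label] += 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        """Integer class labels in record order."""
        return np.array([CLASS_TO_INDEX[r.label] for r in self.records], dtype=int)

    def subset(self, record_ids: Sequence[int]) -> list[ManifestRecord]:
        return [self.records[i] for i in record_ids]


def load_manifest(directory: str | Path) -> DatasetManifest:
    """Load ``manifest.csv`` (columns ``filename,label``) from a directory.

    Every row is validated: labels must belong to the three-class vocabulary
    and the referenced image file must exist.  Errors name the offending row.
    """
    directory = Path(directory)
    csv_path = directory / "manifest.csv"
    if not csv_path.exists():
        raise ManifestError(f"missing manifest: {csv_path}")
    records: list[ManifestRecord] = []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["filename", "label"]:
            raise ManifestError(f"{csv_path}: expected header 'filename,label'")
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ManifestError(f"{csv_path} row {rownum}: expected 2 columns")
            fname, label = row[0].strip(), row[1].strip().lower()
            if label not in CLASSES:
                raise UnknownLabelError(
                    f"{csv_path} row {rownum}: unknown label {label!r} "
                    f"(expected one of {CLASSES})")
            path = directory / fname
            if not path.exists():
                raise ManifestError(f"{csv_path} row {rownum}: missing image file {path}")
            records.append(ManifestRecord(len(records), path, label))
    if not records:
        raise ManifestError(f"{csv_path}: manifest contains no records")
    return DatasetManifest(records)


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


@dataclass
class SplitPlan:
    """Assignment of every record to a holdout role or a fold index."""

    kind: str  # "holdout" | "kfold"
    assignments: dict[int, object]  # record_id -> role str (holdout) or fold int (kfold)
    seed: int
    fractions: tuple[float, float, float] | None = None
    k: int | None = None

    def role_ids(self, role) -> list[int]:
        return sorted(i for i, r in self.assignments.items() if r == role)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind, "seed": self.seed,
            "fractions": list(self.fractions) if self.fractions else None,
            "k": self.k,
            "assignments": {str(i): r for i, r in self.assignments.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SplitPlan":
        p = Path(text_or_path)
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        d = json.loads(text)
        conv = (lambda v: v) if d["kind"] == "holdout" else int
        return cls(kind=d["kind"],
                   assignments={int(i): conv(r) for i, r in d["assignments"].items()},
                   seed=d["seed"],
                   fractions=tuple(d["fractions"]) if d.get("fractions") else None,
                   k=d.get("k"))


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n items: floors, then remainders by largest
    fractional part, ties broken by position (train > val > test)."""
    exact = [f * n for f in fractions]
    base = [math.floor(e) for e in exact]
    remainder = n - sum(base)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def stratified_holdout(manifest: DatasetManifest,
                       fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                       seed: int = 0) -> SplitPlan:
    """Stratified train/val/test split at the given fractions.

    Per class the allocation is floor(fraction * class_count) with remainders
    assigned by largest fractional part (ties: train before val before test),
    so role sizes are a deterministic function of the class counts; only the
    membership depends on the seed.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignments: dict[int, object] = {}
    for label in CLASSES:
        ids = np.array([r.record_id for r in manifest.records if r.label == label])
        if ids.size == 0:
            continue
        if ids.size < len(HOLDOUT_ROLES):
            raise InfeasibleSplitError(
                f"class {label!r} has {ids.size} records; need at least "
                f"{len(HOLDOUT_ROLES)} for a {len(HOLDOUT_ROLES)}-way split")
        rng.shuffle(ids)
        sizes = _allocate(ids.size, fractions)
        start = 0
        for role, sz in zip(HOLDOUT_ROLES, sizes):
            for rid in ids[start:start + sz]:
                assignments[int(rid)] = role
            start += sz
    return SplitPlan("holdout", assignments, seed, fractions=tuple(fractions))


def stratified_kfold(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified k-fold partition; per-class fold sizes differ by <= 1.

    ``k = 1`` degenerates to a single fold holding every record.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    assignments: dict[int, object] = {}
    rng = np.random.default_rng(seed)
    for label in CLASSES:
        ids = np.array([r.record_id for r in manifest.records if r.label == label])
        if ids.size == 0:
            continue
        if ids.size < k:
            raise InfeasibleSplitError(
                f"class {label!r} has {ids.size} records, fewer than k={k}")
        rng.shuffle(ids)
        for pos, rid in enumerate(ids):  # round-robin deal
            assignments[int(rid)] = pos % k
    return SplitPlan("kfold", assignments, seed, k=k)


# ---------------------------------------------------------------------------
# dual-resolution preprocessing


@dataclass
class AugmentConfig:
    """Preprocessing + augmentation knobs.

    size_t / size_c are the transformer and CNN view resolutions.  Setting
    every magnitude to zero makes train-mode preprocessing identical to the
    deterministic eval path.
    """

    size_t: int = 224
    size_c: int = 448
    crop_scale: tuple[float, float] = (0.6, 1.0)
    crop_ratio: tuple[float, float] = (3 / 4, 4 / 3)
    brightness: float = 0.2
    contrast: float = 0.2
    blur_sigma_max: float = 1.0
    min_source_side: int = 64
    mean: tuple[float, float, float] = IMAGENET_MEAN
    std: tuple[float, float, float] = IMAGENET_STD

    def zeroed(self) -> "AugmentConfig":
        """Copy with all augmentation magnitudes at zero (identity transform)."""
        return AugmentConfig(size_t=self.size_t, size_c=self.size_c,
                             crop_scale=(1.0, 1.0), crop_ratio=(1.0, 1.0),
                             brightness=0.0, contrast=0.0, blur_sigma_max=0.0,
                             min_source_side=self.min_source_side,
                             mean=self.mean, std=self.std)


@dataclass
class DualViewSample:
    """One image rendered at two resolutions plus a (possibly soft) label."""

    transformer_view: np.ndarray  # (size_t, size_t, 3) float
    cnn_view: np.ndarray          # (size_c, size_c, 3) float
    label: np.ndarray | None = None  # probability vector over the 3 classes

    def __post_init__(self) -> None:
        if self.label is not None:
            if np.ndim(self.label) == 0:  # integer class index -> one-hot
                idx = int(self.label)
                self.label = np.zeros(N_CLASSES)
                self.label[idx] = 1.0
            self.label = np.asarray(self.label, dtype=np.float64)
            if self.label.shape != (N_CLASSES,) or np.any(self.label < -1e-12) \
                    or abs(self.label.sum() - 1.0) > 1e-6:
                raise ValueError("label must be a probability vector over the 3 classes")


def _as_label_vector(label) -> np.ndarray | None:
    if label is None:
        return None
    if np.isscalar(label) or isinstance(label, (int, np.integer)):
        v = np.zeros(N_CLASSES)
        v[int(label)] = 1.0
        return v
    return np.asarray(label, dtype=np.float64)


def _center_square(h: int, w: int) -> tuple[int, int, int, int]:
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    return top, left, side, side


def _random_resized_crop(h: int, w: int, cfg: AugmentConfig,
                         rng: np.random.Generator) -> tuple[int, int, int, int]:
    area = h * w
    log_lo, log_hi = math.log(cfg.crop_ratio[0]), math.log(cfg.crop_ratio[1])
    for _ in range(10):
        target = area * rng.uniform(*cfg.crop_scale)
        ar = math.exp(rng.uniform(log_lo, log_hi))
        cw = int(round(math.sqrt(target * ar)))
        ch = int(round(math.sqrt(target / ar)))
        if 0 < cw <= w and 0 < ch <= h:
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            return top, left, ch, cw
    return _center_square(h, w)


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    return _sk_resize(img, (size, size), order=1, mode="reflect",
                      anti_aliasing=img.shape[0] > size, preserve_range=True)


def make_dual_views(image: np.ndarray, train_mode: bool = False,
                    aug: AugmentConfig | None = None,
                    rng: np.random.Generator | None = None,
                    label=None) -> DualViewSample:
    """Render one grayscale image as a normalized transformer/CNN view pair.

    Both views come from the same spatial crop.  In eval mode the crop is the
    deterministic center square; in train mode a random resized crop,
    brightness/contrast jitter and Gaussian blur are sampled from ``rng``.
    """
    cfg = aug or AugmentConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() > 1.5:  # 8-/16-bit input
        img = img / (255.0 if img.max() <= 255 else 65535.0)

    if min(img.shape) < cfg.min_source_side:
        logger.warning("image %s smaller than minimum crop side %d; upsampling",
                       img.shape, cfg.min_source_side)
        scale = cfg.min_source_side / min(img.shape)
        img = _sk_resize(img, (int(round(img.shape[0] * scale)),
                               int(round(img.shape[1] * scale))),
                         order=1, mode="reflect", preserve_range=True)

    h, w = img.shape
    if train_mode:
        if rng is None:
            raise ValueError("train_mode preprocessing requires an rng")
        top, left, ch, cw = _random_resized_crop(h, w, cfg, rng)
        crop = img[top:top + ch, left:left + cw]
        if cfg.brightness > 0:
            crop = crop * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
        if cfg.contrast > 0:
            m = crop.mean()
            crop = (crop - m) * rng.uniform(1 - cfg.contrast, 1 + cfg.contrast) + m
        if cfg.blur_sigma_max > 0:
            sigma = rng.uniform(0.0, cfg.blur_sigma_max)
            if sigma > 1e-3:
                from scipy.ndimage import gaussian_filter
                crop = gaussian_filter(crop, sigma=sigma)
        crop = np.clip(crop, 0.0, 1.0)
    else:
        top, left, ch, cw = _center_square(h, w)
        crop = img[top:top + ch, left:left + cw]

    views = []
    for size in (cfg.size_t, cfg.size_c):
        v = _resize(crop, size)
        v3 = np.repeat(v[:, :, None], 3, axis=2)
        v3 = (v3 - np.asarray(cfg.mean)) / np.asarray(cfg.std)
        views.append(v3.astype(np.float64))
    return DualViewSample(views[0], views[1], _as_label_vector(label))


def mixup_cutmix(batch: list[DualViewSample],
                 mixup_alpha: float = 0.2, cutmix_alpha: float = 1.0,
                 apply_prob: float = 0.5,
                 rng: np.random.Generator | None = None) -> list[DualViewSample]:
    """Batch-level MixUp/CutMix; the two are mutually exclusive per batch.

    MixUp takes the convex combination ``lam * x_i + (1-lam) * x_{perm(i)}``
    of pixels and labels with ``lam ~ Beta(alpha, alpha)``.  CutMix pastes a
    rectangular patch from the partner image; the host label weight is the
    unpasted area fraction (computed on the CNN view; the transformer view is
    patched at the same relative coordinates).  Batches of size < 2 are
    returned unchanged.
    """
    if len(batch) < 2:
        return batch
    if rng is None:
        raise ValueError("mixup_cutmix requires an rng")
    if any(s.label is None for s in batch):
        raise ValueError("all samples need labels for MixUp/CutMix")
    if rng.random() >= apply_prob:
        return batch
    use_mixup = rng.random() < 0.5
    perm = rng.permutation(len(batch))
    out: list[DualViewSample] = []
    if use_mixup:
        lam = float(rng.beta(mixup_alpha, mixup_alpha)) if mixup_alpha > 0 else 1.0
        for i, j in enumerate(perm):
            a, b = batch[i], batch[int(j)]
            out.append(DualViewSample(
                lam * a.transformer_view + (1 - lam) * b.transformer_view,
                lam * a.cnn_view + (1 - lam) * b.cnn_view,
                lam * a.label + (1 - lam) * b.label))
        return out
    # CutMix: one patch geometry (in relative coordinates) for the whole batch
    lam = float(rng.beta(cutmix_alpha, cutmix_alpha)) if cutmix_alpha > 0 else 1.0
    cut = math.sqrt(max(0.0, 1.0 - lam))
    cy, cx = rng.random(), rng.random()
    y0, y1 = np.clip([cy - cut / 2, cy + cut / 2], 0.0, 1.0)
    x0, x1 = np.clip([cx - cut / 2, cx + cut / 2], 0.0, 1.0)

    def _paste(host: np.ndarray, donor: np.ndarray) -> tuple[np.ndarray, float]:
        s = host.shape[0]
        r0, r1 = int(round(y0 * s)), int(round(y1 * s))
        c0, c1 = int(round(x0 * s)), int(round(x1 * s))
        mixed = host.copy()
        mixed[r0:r1, c0:c1] = donor[r0:r1, c0:c1]
        return mixed, (r1 - r0) * (c1 - c0) / (s * s)

    for i, j in enumerate(perm):
        a, b = batch[i], batch[int(j)]
        tv, _ = _paste(a.transformer_view, b.transformer_view)
        cv, frac = _paste(a.cnn_view, b.cnn_view)  # label weight from the CNN view
        out.append(DualViewSample(tv, cv, (1 - frac) * a.label + frac * b.label))
    return out
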