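"""Synthetic phase-contrast microscopy image generator.

Emulates label-free phase-contrast appearance of three cultured cell types —
astrocytes (many branched radiating processes), cortical neurons (few long
thin neurites) and SH-SY5Y neuroblastoma (small round clustered cells, no
processes) — so that the full classification pipeline can be exercised and
tested without access to real microscopy data.

The phase-contrast look is built from three ingredients: dark somata stamped
as filled ellipses, a bright halo ring obtained as the positive part of a
difference-of-Gaussians of the soma mask, and dark thin processes drawn as
jittered random walks from the soma rim.  Additive Gaussian noise and a
linear illumination gradient complete the background.

Determinism contract: each image is rendered from an independent substream
keyed by ``(seed, record_index)``, so regenerating any single record — in any
order — yields byte-identical pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from fusecyte.constants import CLASSES

__all__ = [
    "MorphologyParams",
    "DEFAULT_MORPHOLOGIES",
    "DEFAULT_CLASS_COUNTS",
    "render_cell_field",
    "generate_dataset",
    "EmptyDatasetError",
]

#: Per-class image counts matching the reference imbalanced dataset.
DEFAULT_CLASS_COUNTS: dict[str, int] = {"astrocyte": 130, "cortical": 320, "shsy5y": 150}

SOMA_INTENSITY = 0.25
PROCESS_INTENSITY = 0.35
BACKGROUND = 0.5
HALO_GAIN = 0.45  # peak halo brightness above background = HALO_GAIN * halo_intensity
GRADIENT_GAIN = 0.15


class EmptyDatasetError(ValueError):
    """Raised when a dataset generation request contains zero records."""


@dataclass(frozen=True)
class MorphologyParams:
    """Rendering parameters for one cell class.

    halo_intensity and illumination_gradient are unitless in [0, 1];
    noise_sd is the standard deviation of additive pixel noise on a [0, 1]
    intensity scale; lengths and radii are in pixels.
    """

    cell_class: str
    cells_per_image: int
    soma_radius_px: float
    process_count: int
    process_length_px: float
    halo_intensity: float = 0.8
    noise_sd: float = 0.03
    illumination_gradient: float = 0.3

    def __post_init__(self) -> None:
        if self.cell_class not in CLASSES:
            raise ValueError(f"unknown cell_class {self.cell_class!r}; expected one of {CLASSES}")
        if self.cells_per_image < 0:
            raise ValueError("cells_per_image must be >= 0")
        if self.soma_radius_px <= 0:
            raise ValueError("soma_radius_px must be positive")
        if self.process_count < 0 or self.process_length_px < 0:
            raise ValueError("process_count and process_length_px must be non-negative")
        if not 0.0 <= self.halo_intensity <= 1.0:
            raise ValueError("halo_intensity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must lie in [0, 1]")


#: Default morphologies.  Astrocytes are process-rich and branched, cortical
#: neurons carry a couple of long thin neurites, SH-SY5Y are round, clustered
#: and process-free.  Values are invented rendering parameters, not
#: measurements.
DEFAULT_MORPHOLOGIES: dict[str, MorphologyParams] = {
    "astrocyte": MorphologyParams(
        cell_class="astrocyte", cells_per_image=5, soma_radius_px=7.0,
        process_count=7, process_length_px=40.0,
    ),
    "cortical": MorphologyParams(
        cell_class="cortical", cells_per_image=7, soma_radius_px=5.0,
        process_count=2, process_length_px=70.0,
    ),
    "shsy5y": MorphologyParams(
        cell_class="shsy5y", cells_per_image=20, soma_radius_px=6.0,
        process_count=0, process_length_px=0.0, halo_intensity=0.9,
    ),
}

# eccentricity of the stamped soma ellipse per class (cortical somata are
# elongated, SH-SY5Y nearly round)
_SOMA_ECCENTRICITY = {"astrocyte": 0.15, "cortical": 0.45, "shsy5y": 0.05}


def _cell_centers(params: MorphologyParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample soma centers; SH-SY5Y cells aggregate around cluster seeds."""
    n = params.cells_per_image
    margin = max(4, int(params.soma_radius_px) + 2)
    if params.cell_class == "shsy5y" and n > 1:
        n_clusters = max(1, n // 6)
        seeds = rng.uniform(margin, size - margin, size=(n_clusters, 2))
        which = rng.integers(0, n_clusters, size=n)
        centers = seeds[which] + rng.normal(0, 2.5 * params.soma_radius_px, size=(n, 2))
        return np.clip(centers, margin, size - margin)
    return rng.uniform(margin, size - margin, size=(n, 2))


def _draw_process(mask: np.ndarray, start: np.ndarray, angle: float, length: float,
                  rng: np.random.Generator, *, jitter: float, branch: bool) -> None:
    """Draw one process as a jittered walk of 2 px segments; optionally branch once."""
    size = mask.shape[0]
    pos = start.astype(float)
    n_steps = max(1, int(length / 2.0))
    for step in range(n_steps):
        angle += rng.normal(0.0, jitter)
        nxt = pos + 2.0 * np.array([np.cos(angle), np.sin(angle)])
        rr, cc = draw_line(int(round(pos[0])), int(round(pos[1])),
                           int(round(nxt[0])), int(round(nxt[1])))
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        mask[rr[keep], cc[keep]] = True
        pos = nxt
        if branch and step == n_steps // 2 and rng.random() < 0.6:
            side = 0.7 if rng.random() < 0.5 else -0.7
            _draw_process(mask, pos.copy(), angle + side, length / 2.0, rng,
                          jitter=jitter, branch=False)


def render_cell_field(params: MorphologyParams, image_size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Render one synthetic field of cells as an 8-bit grayscale image.

    Returns a ``(image_size, image_size)`` uint8 array.  With
    ``cells_per_image == 0`` the output is pure background (noise plus
    illumination gradient).
    """
    if image_size < 8:
        raise ValueError("image_size too small to render")
    size = image_size
    img = np.full((size, size), BACKGROUND, dtype=np.float64)

    # linear illumination gradient along a random direction
    g = params.illumination_gradient
    theta = rng.uniform(0, 2 * np.pi)
    if g > 0:
        yy, xx = np.mgrid[0:size, 0:size]
        proj = (np.cos(theta) * (yy - size / 2) + np.sin(theta) * (xx - size / 2)) / (size / 2)
        img += GRADIENT_GAIN * g * proj

    soma_mask = np.zeros((size, size), dtype=bool)
    process_mask = np.zeros((size, size), dtype=bool)
    ecc = _SOMA_ECCENTRICITY[params.cell_class]
    centers = _cell_centers(params, size, rng)
    for cy, cx in centers:
        orient = rng.uniform(0, np.pi)
        r_major = params.soma_radius_px * (1 + ecc)
        r_minor = params.soma_radius_px * (1 - ecc)
        rr, cc = draw_ellipse(cy, cx, r_major, r_minor, shape=(size, size), rotation=orient)
        soma_mask[rr, cc] = True
        for _ in range(params.process_count):
            angle = rng.uniform(0, 2 * np.pi)
            start = np.array([cy, cx]) + params.soma_radius_px * np.array(
                [np.cos(angle), np.sin(angle)])
            jitter = 0.12 if params.cell_class == "cortical" else 0.3
            length = params.process_length_px * rng.uniform(0.7, 1.3)
            _draw_process(process_mask, start, angle, length, rng,
                          jitter=jitter, branch=params.cell_class == "astrocyte")

    img[process_mask] = PROCESS_INTENSITY
    img[soma_mask] = SOMA_INTENSITY

    # bright halo: positive part of a difference-of-Gaussians of the soma mask
    if params.halo_intensity > 0 and soma_mask.any():
        m = soma_mask.astype(np.float64)
        wide = gaussian_filter(m, sigma=max(1.5, params.soma_radius_px / 2.0))
        narrow = gaussian_filter(m, sigma=0.8)
        ring = np.clip(wide - narrow, 0.0, None)
        peak = ring.max()
        if peak > 0:
            img += HALO_GAIN * params.halo_intensity * (ring / peak)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)

    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _record_rng(seed: int, record_index: int) -> np.random.Generator:
    """Independent, order-free substream for one record."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(record_index),)))


def generate_dataset(class_counts: dict[str, int] | None = None,
                     image_size: int = 256, seed: int = 0,
                     out_dir: str | Path = "data",
                     morphologies: dict[str, MorphologyParams] | None = None):
    """Render a labeled synthetic dataset and write it to ``out_dir``.

    Writes one grayscale PNG per record plus ``manifest.csv`` with columns
    ``filename,label`` and returns the loaded
    :class:`~fusecyte.dataio.DatasetManifest`.  Identical ``seed`` and
    parameters yield byte-identical image files.

    Parameters
    ----------
    class_counts
        Images per class; defaults to the reference imbalanced counts
        (320 cortical / 150 SH-SY5Y / 130 astrocyte).
    image_size
        Side of the square output images, >= 64 px.
    """
    from fusecyte.dataio import DatasetManifest, ManifestRecord  # avoid cycle at import time

    counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    for label, n in counts.items():
        if label not in CLASSES:
            raise ValueError(f"unknown class {label!r}")
        if n < 0:
            raise ValueError(f"negative count for class {label!r}")
    if sum(counts.values()) == 0:
        raise EmptyDatasetError("all class counts are zero")
    if image_size < 64:
        raise ValueError("image_size must be >= 64")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = morphologies or DEFAULT_MORPHOLOGIES

    records: list[ManifestRecord] = []
    rows: list[tuple[str, str]] = []
    record_index = 0
    for label in CLASSES:  # fixed class order => stable record ids
        params = base.get(label, DEFAULT_MORPHOLOGIES[label])
        if params.cell_class != label:
            params = replace(params, cell_class=label)
        for i in range(counts.get(label, 0)):
            rng = _record_rng(seed, record_index)
            img = render_cell_field(params, image_size, rng)
            fname = f"{label}_{i:04d}.png"
            Image.fromarray(img, mode="L").save(out / fname)
            rows.append((fname, label))
            records.append(ManifestRecord(record_index, out / fname, label))
            record_index += 1

    with open(out / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)

    return DatasetManifest(records)
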