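"""Synthetic multi-label radiograph-like image generator.

Each of the K classes corresponds to a spatially localised motif with a
class-characteristic shape family, position, and scale — a stand-in for
the way each pathology tends to occupy a characteristic lung region at a
characteristic size.  Labels are independent Bernoulli draws with
per-class prevalences; the default prevalence profile decays
geometrically from 0.40 to 0.05 across classes, emulating the severe
class imbalance of public chest-radiograph datasets.  Images are a noisy
low-contrast background plus one additive motif per positive class, with
randomised position/scale/amplitude jitter, written as 8-bit grayscale
PNGs alongside a ChestX-ray14-dialect label CSV so that synthetic and
real data share one reader.

Generation is fully deterministic given the seed (byte-identical files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import CHESTXRAY14_CLASSES


def default_prevalence(k: int = 14, high: float = 0.40, low: float = 0.05):
    """Geometric decay from ``high`` to ``low`` across the k classes."""
    if k == 1:
        return np.array([high])
    return high * (low / high) ** (np.arange(k) / (k - 1))


@dataclass
class SyntheticSpec:
    n_images: int = 1000
    image_size: int = 224
    k: int = 14
    prevalence: np.ndarray | None = None
    noise_sd: float = 0.10
    seed: int = 0
    images_per_patient: int = 1

    def __post_init__(self):
        if self.prevalence is None:
            self.prevalence = default_prevalence(self.k)
        self.prevalence = np.clip(np.asarray(self.prevalence, dtype=float), 0.0, 1.0)
        if len(self.prevalence) != self.k:
            raise ValueError("prevalence must have one entry per class")
        if self.n_images < 1 or self.image_size < 16:
            raise ValueError("n_images and image_size must be sensible positives")


# ------------------------------------------------------------------ motifs
def _grid(size: int):
    c = np.arange(size) + 0.5
    return np.meshgrid(c, c, indexing="ij")


def _ellipse(yy, xx, cy, cx, ry, rx):
    return (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0


def _render_motif(canvas: np.ndarray, klass: int, k_total: int,
                  rng: np.random.Generator, amplitude: float) -> None:
    """Draw the class-k motif onto the canvas (in place, additive)."""
    size = canvas.shape[0]
    # characteristic centre: classes laid out on a grid over the image
    cols = int(np.ceil(np.sqrt(k_total)))
    gy, gx = divmod(klass, cols)
    rows = int(np.ceil(k_total / cols))
    cy = (gy + 0.5) / rows * size
    cx = (gx + 0.5) / cols * size
    # characteristic scale: alternates between coarse and fine motifs
    base = size * (0.10 + 0.05 * ((klass % 4) / 3.0))
    cy += rng.normal(0, 0.03 * size)
    cx += rng.normal(0, 0.03 * size)
    scale = base * rng.uniform(0.85, 1.15)
    yy, xx = _grid(size)
    family = klass % 4
    if family == 0:                                   # filled ellipse
        mask = _ellipse(yy, xx, cy, cx, scale, 0.7 * scale)
    elif family == 1:                                 # ring
        outer = _ellipse(yy, xx, cy, cx, scale, scale)
        inner = _ellipse(yy, xx, cy, cx, 0.55 * scale, 0.55 * scale)
        mask = outer & ~inner
    elif family == 2:                                 # oriented bar
        theta = np.pi / 4 if klass % 2 else -np.pi / 4
        u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        mask = (np.abs(u) <= 1.4 * scale) & (np.abs(v) <= 0.35 * scale)
    else:                                             # cross
        arm = 0.3 * scale
        mask = (((np.abs(yy - cy) <= arm) & (np.abs(xx - cx) <= 1.3 * scale)) |
                ((np.abs(xx - cx) <= arm) & (np.abs(yy - cy) <= 1.3 * scale)))
    canvas[mask] += amplitude


def render_image(labels: np.ndarray, spec: SyntheticSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one image for a binary label vector; float array in [0,1]."""
    size = spec.image_size
    canvas = np.full((size, size), 0.35, dtype=np.float64)
    # smooth illumination gradient, a crude analogue of exposure variation
    yy, xx = _grid(size)
    canvas += 0.05 * (yy / size - 0.5) * rng.uniform(-1, 1)
    canvas += 0.05 * (xx / size - 0.5) * rng.uniform(-1, 1)
    for klass in np.flatnonzero(labels > 0):
        _render_motif(canvas, int(klass), spec.k, rng,
                      amplitude=rng.uniform(0.40, 0.60))
    canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
    return np.clip(canvas, 0.0, 1.0)


def generate_synthetic_dataset(spec: SyntheticSpec, out_dir,
                               class_names=None) -> Path:
    """Write PNG images and a ChestX-ray14-dialect CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    img_dir = out_dir            # PNGs sit next to the CSV, bare filenames
    img_dir.mkdir(parents=True, exist_ok=True)
    class_names = list(class_names or CHESTXRAY14_CLASSES[:spec.k])
    if len(class_names) != spec.k:
        raise ValueError("class_names length must equal spec.k")
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random((spec.n_images, spec.k)) < spec.prevalence).astype(np.float32)
    rows = []
    for i in range(spec.n_images):
        arr = render_image(labels[i], spec, rng)
        name = f"synthetic_{i:06d}.png"
        Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(
            img_dir / name)
        finding = "|".join(class_names[j] for j in np.flatnonzero(labels[i]))
        rows.append({
            "Image Index": name,
            "Finding Labels": finding if finding else "No Finding",
            "Patient ID": str(i // spec.images_per_patient),
        })
    csv_path = out_dir / "labels.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
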