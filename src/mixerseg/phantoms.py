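"""Synthetic ultrasound speckle phantoms with exact ground-truth lesion masks.

Real breast ultrasound frames show a granular multiplicative interference
pattern (speckle) over smoothly varying tissue echogenicity, with lesions
appearing as darker (hypoechoic) roughly elliptical regions, sometimes with
a posterior acoustic shadow, and occupying only a small fraction of the
frame. The generator emulates exactly those features:

* background: a smooth tissue-texture field multiplied by unit-mean
  gamma-distributed speckle (a standard surrogate for fully developed
  speckle; the variance is configurable);
* lesions: zero to two darker ellipses whose radius is sinusoidally
  perturbed to give irregular boundaries; the interior tissue intensity is
  attenuated by a configurable fractional contrast before speckle is
  applied; an optional posterior shadow stripe darkens the column below;
* masks: the exact union of the analytic lesion supports, reconstructible
  bit-for-bit from the stored lesion parameters.

It is a stand-in for clinical data: it reproduces the statistics the
network's mechanisms target (speckle, low contrast, class imbalance), not
the acoustics of a scanner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError

CLASS_BY_COUNT = {0: "normal", 1: "benign", 2: "malignant"}


@dataclass(frozen=True)
class LesionParams:
    """Analytic description of one lesion; masks are exact functions of these."""

    cx: float
    cy: float
    a: float  # semi-axis along the rotated x' axis, pixels
    b: float  # semi-axis along the rotated y' axis, pixels
    phi: float  # orientation, radians
    irreg_amp: float  # sinusoidal boundary perturbation amplitude (fraction of radius)
    irreg_freq: int  # lobes of the boundary perturbation
    irreg_phase: float
    shadow: bool


@dataclass
class PhantomConfig:
    """Generator settings; ``seed`` is mandatory for exact reproducibility."""

    n_images: int
    seed: int
    size: int = 128
    lesions_range: tuple[int, int] = (0, 2)
    radius_frac: tuple[float, float] = (0.08, 0.20)
    lesion_contrast: float = 0.5
    irregularity: float = 0.25
    speckle_var: float = 0.08
    shadow_prob: float = 0.3
    base_intensity: float = 0.55
    texture_amp: float = 0.12

    def __post_init__(self):
        if self.radius_frac[1] >= 0.5:
            raise ConfigurationError(
                f"maximum lesion radius fraction {self.radius_frac[1]} must be < 0.5 "
                "(lesion radius would reach half the image)"
            )
        if not 0 <= self.lesions_range[0] <= self.lesions_range[1]:
            raise ConfigurationError(f"invalid lesion count range {self.lesions_range}")
        if self.speckle_var <= 0:
            raise ConfigurationError("speckle_var must be positive")


@dataclass
class Phantom:
    image: np.ndarray  # (size, size) float in [0, 1]
    mask: np.ndarray  # (size, size) uint8 in {0, 1}
    lesions: list[LesionParams] = field(default_factory=list)

    @property
    def label(self) -> str:
        return CLASS_BY_COUNT[min(len(self.lesions), 2)]


def lesion_support(lesion: LesionParams, size: int) -> np.ndarray:
    """Boolean support of one lesion on the pixel grid.

    A pixel centre (x, y) is inside when, in the lesion's rotated frame,
    ``(x'/a)^2 + (y'/b)^2 <= (1 + amp * sin(freq * theta + phase))^2``.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx = xx - lesion.cx
    dy = yy - lesion.cy
    c, s = np.cos(lesion.phi), np.sin(lesion.phi)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    r2 = (xr / lesion.a) ** 2 + (yr / lesion.b) ** 2
    theta = np.arctan2(yr, xr)
    scale = 1.0 + lesion.irreg_amp * np.sin(lesion.irreg_freq * theta + lesion.irreg_phase)
    return r2 <= scale**2


def mask_from_lesions(lesions: Sequence[LesionParams], size: int) -> np.ndarray:
    """Exact binary union of the lesion supports."""
    mask = np.zeros((size, size), dtype=np.uint8)
    for lesion in lesions:
        mask |= lesion_support(lesion, size).astype(np.uint8)
    return mask


def _sample_lesion(rng: np.random.Generator, cfg: PhantomConfig) -> LesionParams:
    s = cfg.size
    a = rng.uniform(*cfg.radius_frac) * s
    b = rng.uniform(*cfg.radius_frac) * s
    amp = rng.uniform(0.0, cfg.irregularity)
    margin = max(a, b) * (1.0 + amp) + 2.0
    if 2 * margin >= s:
        margin = s / 2.0 - 1.0
    return LesionParams(
        cx=float(rng.uniform(margin, s - margin)),
        cy=float(rng.uniform(margin, s - margin)),
        a=float(a),
        b=float(b),
        phi=float(rng.uniform(0.0, np.pi)),
        irreg_amp=float(amp),
        irreg_freq=int(rng.integers(3, 7)),
        irreg_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        shadow=bool(rng.uniform() < cfg.shadow_prob),
    )


def _render(lesions: Sequence[LesionParams], cfg: PhantomConfig, rng: np.random.Generator) -> Phantom:
    s = cfg.size
    texture = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 8.0)
    std = texture.std()
    if std > 0:
        texture *= cfg.texture_amp / std
    tissue = np.clip(cfg.base_intensity + texture, 0.35, 0.85)

    mask = np.zeros((s, s), dtype=np.uint8)
    for lesion in lesions:
        support = lesion_support(lesion, s)
        # hypoechoic interiors are more homogeneous than surrounding tissue:
        # attenuate the base level, not the local texture, which also makes
        # the configured contrast a guarantee rather than an expectation
        tissue[support] = (1.0 - cfg.lesion_contrast) * cfg.base_intensity
        mask |= support.astype(np.uint8)
        if lesion.shadow:
            x0 = max(0, int(lesion.cx - lesion.a))
            x1 = min(s, int(lesion.cx + lesion.a) + 1)
            y0 = min(s, int(lesion.cy + max(lesion.a, lesion.b) * (1.0 + lesion.irreg_amp)) + 1)
            tissue[y0:, x0:x1] *= 0.85

    shape = 1.0 / cfg.speckle_var  # gamma(k, 1/k): unit mean, variance 1/k
    speckle = rng.gamma(shape, 1.0 / shape, size=(s, s))
    image = np.clip(tissue * speckle, 0.0, 1.0)
    return Phantom(image=image, mask=mask, lesions=list(lesions))


def generate_phantoms(cfg: PhantomConfig, lesion_counts: Optional[Sequence[int]] = None) -> list[Phantom]:
    """Generate ``cfg.n_images`` phantoms, bit-identical for identical seeds.

    ``lesion_counts`` optionally fixes the per-image lesion count (used by
    the fixture writer to control class membership); otherwise counts are
    drawn uniformly from ``cfg.lesions_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    if lesion_counts is not None and len(lesion_counts) != cfg.n_images:
        raise ConfigurationError("lesion_counts length must equal n_images")
    out = []
    lo, hi = cfg.lesions_range
    for i in range(cfg.n_images):
        count = int(lesion_counts[i]) if lesion_counts is not None else int(rng.integers(lo, hi + 1))
        lesions = [_sample_lesion(rng, cfg) for _ in range(count)]
        out.append(_render(lesions, cfg, rng))
    return out


def save_phantom_png(phantom: Phantom, image_path: Path, mask_path: Path) -> None:
    """8-bit grayscale PNG pair in the public breast-ultrasound folder dialect."""
    Image.fromarray(np.round(phantom.image * 255.0).astype(np.uint8), mode="L").save(image_path)
    Image.fromarray((phantom.mask * 255).astype(np.uint8), mode="L").save(mask_path)


# train/test composition of the on-disk fixture tree (class -> lesion count is
# the fixture's labelling convention: one lesion ~ benign, two ~ malignant)
_FIXTURE_PLAN = {
    "train": [("benign", 1)] * 10 + [("malignant", 2)] * 8 + [("normal", 0)] * 6,
    "test": [("benign", 1)] * 3 + [("malignant", 2)] * 3 + [("normal", 0)] * 2,
}


def make_fixture_set(root, seed: int, size: int = 128, config: Optional[PhantomConfig] = None) -> dict:
    """Write a 24-train / 8-test phantom tree in the BUSI folder layout.

    Creates ``root/{benign,malignant,normal}`` with ``"<class> (i).png"`` /
    ``"<class> (i)_mask.png"`` pairs, a ``split.csv`` recording train/test
    membership, and a ``lesions.csv`` logging every lesion parameter for
    exact mask reconstruction. Returns ``{"train": [...], "test": [...]}``
    image paths.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    plan = [(split, cls, count) for split in ("train", "test") for cls, count in _FIXTURE_PLAN[split]]
    counts = [count for _, _, count in plan]
    cfg = config or PhantomConfig(n_images=len(plan), seed=seed, size=size)
    if cfg.n_images != len(plan):
        raise ConfigurationError(f"fixture config must generate {len(plan)} images")
    phantoms = generate_phantoms(cfg, lesion_counts=counts)

    result: dict[str, list[Path]] = {"train": [], "test": []}
    per_class: dict[str, int] = {}
    split_rows = []
    lesion_rows = []
    for (split, cls, _), phantom in zip(plan, phantoms):
        per_class[cls] = per_class.get(cls, 0) + 1
        stem = f"{cls} ({per_class[cls]})"
        cls_dir = root / cls
        cls_dir.mkdir(exist_ok=True)
        image_path = cls_dir / f"{stem}.png"
        mask_path = cls_dir / f"{stem}_mask.png"
        save_phantom_png(phantom, image_path, mask_path)
        result[split].append(image_path)
        split_rows.append((str(image_path.relative_to(root)), cls, split))
        for k, lesion in enumerate(phantom.lesions):
            lesion_rows.append(
                (str(image_path.relative_to(root)), k, lesion.cx, lesion.cy, lesion.a, lesion.b,
                 lesion.phi, lesion.irreg_amp, lesion.irreg_freq, lesion.irreg_phase, int(lesion.shadow))
            )

    with open(root / "split.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "label", "split"])
        writer.writerows(split_rows)
    with open(root / "lesions.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "lesion", "cx", "cy", "a", "b", "phi",
                        "irreg_amp", "irreg_freq", "irreg_phase", "shadow"])
        writer.writerows(lesion_rows)
    return result
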