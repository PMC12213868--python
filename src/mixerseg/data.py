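"""Dataset indexing, loading, splitting and paired augmentation.

Folder layout follows the public breast-ultrasound convention: one directory
per class (``benign``/``malignant``/``normal``), images named like
``"benign (1).png"`` with masks sharing the stem plus a ``_mask`` (optionally
``_mask_1``, ``_mask_2``) suffix. Other dialects can be mapped in through the
``mask_pattern`` argument.

Images are loaded as single-channel floats in [0, 1] and bilinearly resized
to the network size; masks are nearest-neighbour resized, binarised at 0.5
and unioned when an image carries several lesion annotations. Augmentation
applies one jointly sampled transform (flips, shifts up to 10% per axis,
zoom up to 20%, rotation up to 20 degrees, nearest-edge fill) to the image
and its mask, re-binarising the mask afterwards.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

from .exceptions import ConfigurationError

_MASK_RE = re.compile(r"^(?P<base>.+?)_mask(?:_(?P<index>\d+))?$")


@dataclass(frozen=True)
class DatasetRecord:
    """One image with its (possibly empty) list of mask paths and class label."""

    image_path: Path
    mask_paths: tuple[Path, ...]
    label: str


@dataclass(frozen=True)
class DatasetIndex:
    records: tuple[DatasetRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_label(self) -> dict[str, list[DatasetRecord]]:
        out: dict[str, list[DatasetRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.label, []).append(rec)
        return out


@dataclass
class ImageMaskPair:
    """A grayscale image in [0, 1] with its strictly binary mask."""

    image: np.ndarray
    mask: np.ndarray


def index_dataset(root, mask_pattern: re.Pattern | str = _MASK_RE) -> DatasetIndex:
    """Build a deterministic, lexicographically sorted index of a class tree.

    Masks are grouped under their parent image by stem; a mask whose parent
    image is missing triggers a warning and is skipped; a root with no images
    raises an error.
    """
    root = Path(root)
    if isinstance(mask_pattern, str):
        mask_pattern = re.compile(mask_pattern)
    if not root.is_dir():
        raise ConfigurationError(f"dataset root {root} is not a directory")
    records: list[DatasetRecord] = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        label = class_dir.name
        images: dict[str, Path] = {}
        masks: dict[str, list[tuple[str, Path]]] = {}
        for png in sorted(class_dir.glob("*.png")):
            m = mask_pattern.match(png.stem)
            if m:
                masks.setdefault(m.group("base"), []).append((png.stem, png))
            else:
                images[png.stem] = png
        for base, entries in sorted(masks.items()):
            if base not in images:
                for _, path in entries:
                    warnings.warn(f"mask {path} has no parent image; skipped")
        for stem in sorted(images):
            mask_paths = tuple(path for _, path in sorted(masks.get(stem, [])))
            records.append(DatasetRecord(images[stem], mask_paths, label))
    if not records:
        raise ConfigurationError(f"no images found under {root}")
    return DatasetIndex(tuple(records))


def _read_gray(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("L"), dtype=np.float64) / 255.0
    except Exception as exc:  # unreadable / corrupt file
        raise OSError(f"cannot read PNG {path}: {exc}") from exc


def load_pair(record: DatasetRecord, size: int = 128) -> ImageMaskPair:
    """Load one record: image scaled to [0, 1] and bilinearly resized to
    ``size x size``; masks nearest-neighbour resized, binarised at 0.5 and
    unioned. Lesion-free records with no mask file get an all-zero mask.
    """
    image = _read_gray(record.image_path)
    if image.shape != (size, size):
        image = resize(image, (size, size), order=1, preserve_range=True, anti_aliasing=True)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    mask = np.zeros((size, size), dtype=np.uint8)
    for mask_path in record.mask_paths:
        m = _read_gray(mask_path)
        if m.shape != (size, size):
            m = resize(m, (size, size), order=0, preserve_range=True, anti_aliasing=False)
        mask |= (m > 0.5).astype(np.uint8)
    return ImageMaskPair(image=image, mask=mask)


def save_pair(pair: ImageMaskPair, image_path, mask_path) -> None:
    """Write an 8-bit grayscale PNG pair (mask stored as 0/255)."""
    Image.fromarray(np.round(pair.image * 255.0).astype(np.uint8), mode="L").save(image_path)
    Image.fromarray((pair.mask * 255).astype(np.uint8), mode="L").save(mask_path)


def split_dataset(index: DatasetIndex, test_fraction: float, seed: int) -> tuple[DatasetIndex, DatasetIndex]:
    """Seeded, class-stratified, disjoint and exhaustive train/test split.

    A class with fewer than two items goes entirely to train (with a
    warning), since it cannot be represented on both sides.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    train: list[DatasetRecord] = []
    test: list[DatasetRecord] = []
    for label, recs in sorted(index.by_label().items()):
        if len(recs) < 2:
            warnings.warn(f"class {label!r} has fewer than 2 items; assigned to train")
            train.extend(recs)
            continue
        order = rng.permutation(len(recs))
        n_test = int(round(test_fraction * len(recs)))
        n_test = min(max(n_test, 0), len(recs) - 1)
        test_ids = set(order[:n_test].tolist())
        for i, rec in enumerate(recs):
            (test if i in test_ids else train).append(rec)
    return DatasetIndex(tuple(train)), DatasetIndex(tuple(test))


def index_to_csv(index: DatasetIndex, path, splits: Optional[dict] = None) -> None:
    """Serialise an index (image, ;-joined masks, label, optional split)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "masks", "label", "split"])
        for rec in index:
            split = (splits or {}).get(rec.image_path, "")
            writer.writerow([str(rec.image_path), ";".join(str(p) for p in rec.mask_paths), rec.label, split])


# ---------------------------------------------------------------------------
# Augmentation


@dataclass
class AugmentParams:
    """Augmentation bounds: flips, shifts <= 10% per axis, zoom <= 20%,
    rotation <= 20 degrees, nearest-edge fill."""

    flip_horizontal: bool = True
    flip_vertical: bool = True
    shift_frac: float = 0.10
    zoom_frac: float = 0.20
    rotation_deg: float = 20.0
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.shift_frac <= 0.10:
            raise ConfigurationError("shift_frac must lie in [0, 0.10]")
        if not 0.0 <= self.zoom_frac <= 0.20:
            raise ConfigurationError("zoom_frac must lie in [0, 0.20]")
        if not 0.0 <= self.rotation_deg <= 20.0:
            raise ConfigurationError("rotation_deg must lie in [0, 20]")
        if self.fill_mode != "nearest":
            raise ConfigurationError("only nearest-edge fill is supported")


@dataclass(frozen=True)
class TransformSample:
    """One concrete jointly-applied transform."""

    flip_h: bool = False
    flip_v: bool = False
    shift_rows: float = 0.0  # pixels
    shift_cols: float = 0.0
    zoom: float = 1.0
    angle_deg: float = 0.0


def sample_transform(params: AugmentParams, rng: np.random.Generator, size: int) -> TransformSample:
    return TransformSample(
        flip_h=bool(params.flip_horizontal and rng.uniform() < 0.5),
        flip_v=bool(params.flip_vertical and rng.uniform() < 0.5),
        shift_rows=float(rng.uniform(-params.shift_frac, params.shift_frac) * size),
        shift_cols=float(rng.uniform(-params.shift_frac, params.shift_frac) * size),
        zoom=float(rng.uniform(1.0 - params.zoom_frac, 1.0 + params.zoom_frac)),
        angle_deg=float(rng.uniform(-params.rotation_deg, params.rotation_deg)),
    )


def _affine(arr: np.ndarray, t: TransformSample, order: int) -> np.ndarray:
    if t.zoom == 1.0 and t.angle_deg == 0.0 and t.shift_rows == 0.0 and t.shift_cols == 0.0:
        return arr.copy()
    theta = np.deg2rad(t.angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    centre = (np.asarray(arr.shape, dtype=np.float64) - 1.0) / 2.0
    shift = np.array([t.shift_rows, t.shift_cols])
    # forward map: q = zoom * R (p - centre) + centre + shift; ndimage wants the inverse
    rot = np.array([[c, -s], [s, c]])
    matrix = rot.T / t.zoom
    offset = centre - matrix @ (centre + shift)
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order, mode="nearest")


def apply_transform(pair: ImageMaskPair, t: TransformSample) -> ImageMaskPair:
    """Apply one sampled transform to image and mask jointly.

    The image is bilinearly interpolated, the mask nearest-neighbour
    interpolated and re-binarised; out-of-frame pixels replicate the nearest
    edge. Flips are exact array reversals, so a double flip restores the
    input bit-for-bit.
    """
    image, mask = pair.image, pair.mask
    if t.flip_h:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if t.flip_v:
        image, mask = image[::-1, :], mask[::-1, :]
    image = np.clip(_affine(image.astype(np.float64), t, order=1), 0.0, 1.0).astype(np.float32)
    mask = (_affine(mask.astype(np.float64), t, order=0) > 0.5).astype(np.uint8)
    return ImageMaskPair(image=image, mask=mask)


def augment_pair(pair: ImageMaskPair, params: AugmentParams, rng: Optional[np.random.Generator] = None) -> ImageMaskPair:
    """Randomly augment a pair; the same transform hits image and mask."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = sample_transform(params, rng, size=pair.image.shape[0])
    return apply_transform(pair, t)


def load_arrays(index: DatasetIndex | Sequence[DatasetRecord], size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Stack an index into NHWC image/mask arrays ready for the network."""
    pairs = [load_pair(rec, size=size) for rec in index]
    images = np.stack([p.image for p in pairs])[..., None].astype(np.float32)
    masks = np.stack([p.mask for p in pairs])[..., None].astype(np.float32)
    return images, masks
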