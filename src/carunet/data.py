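"""Data pipeline: preprocessing, dataset splitting and joint augmentation.

The pipeline mirrors the standard protocol for lung-field segmentation on
chest radiographs: every image is resized to 256x256 with bilinear
interpolation and scaled to [0, 1] by dividing by 255; the dataset is split
8:1:1 into train/validation/test; and the *training* split only is expanded
to a fixed budget of augmented copies using rotations at +/-15, 30, 45 and
90 degrees, the three axis flips, and optional photometric jitter
(brightness, Gaussian blur).  Images and masks are always transformed with
identical geometry — bilinear resampling for images, nearest-neighbour for
masks so they stay strictly binary.

Coordinates are (row, col), 0-based; positive rotation angles are
counter-clockwise (consistent with ``np.rot90``); geometric transforms fill
the outside of the support with 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ShapeError

__all__ = [
    "ImagePair", "SplitCounts", "Transform", "AugmentationPlan",
    "TARGET_SIZE", "ROTATION_ANGLES", "DEFAULT_TRANSFORMS",
    "preprocess", "preprocess_mask", "split_counts", "assign_split",
    "build_augmentation_plan", "apply_transform", "augment_dataset",
    "write_pairs", "read_pairs", "read_raw_pairs", "write_manifest", "read_manifest",
]

TARGET_SIZE = 256

#: Rotation angles (degrees) used for augmentation planning.
ROTATION_ANGLES = (-15, 15, -30, 30, -45, 45, -90, 90)


@dataclass(frozen=True)
class ImagePair:
    """A grayscale image in [0, 1] with its binary mask and an identifier."""

    image: np.ndarray
    mask: np.ndarray
    id: str = ""

    def __post_init__(self):
        img, msk = np.asarray(self.image), np.asarray(self.mask)
        if img.ndim != 2 or msk.shape != img.shape:
            raise ShapeError(
                f"ImagePair {self.id!r}: image {img.shape} and mask {msk.shape} "
                "must be equal 2-D shapes")
        if img.size and (img.min() < 0 or img.max() > 1):
            raise ConfigurationError(f"ImagePair {self.id!r}: image values outside [0, 1]")
        vals = np.unique(msk)
        if not np.isin(vals, (0, 1)).all():
            raise ConfigurationError(f"ImagePair {self.id!r}: mask values must be 0/1")


@dataclass(frozen=True)
class SplitCounts:
    """Sizes of the train/validation/test partitions."""

    n_train: int
    n_val: int
    n_test: int

    @property
    def total(self) -> int:
        return self.n_train + self.n_val + self.n_test


@dataclass(frozen=True)
class Transform:
    """One augmentation operation.

    ``kind`` is one of ``rotate`` (parameter ``angle`` in degrees, positive =
    counter-clockwise), ``hflip``/``vflip``/``hvflip``, ``brightness``
    (multiplicative ``factor`` > 0) or ``gaussian_blur`` (``sigma`` > 0).
    """

    kind: str
    angle: float | None = None
    factor: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        kinds = ("rotate", "hflip", "vflip", "hvflip", "brightness", "gaussian_blur")
        if self.kind not in kinds:
            raise ConfigurationError(f"kind: unknown transform {self.kind!r}")
        if self.kind == "rotate" and self.angle is None:
            raise ConfigurationError("angle: rotate requires an angle")
        if self.kind == "brightness" and (self.factor is None or self.factor <= 0):
            raise ConfigurationError("factor: brightness requires factor > 0")
        if self.kind == "gaussian_blur" and (self.sigma is None or self.sigma <= 0):
            raise ConfigurationError("sigma: gaussian_blur requires sigma > 0")

    @property
    def tag(self) -> str:
        if self.kind == "rotate":
            a = int(self.angle) if float(self.angle).is_integer() else self.angle
            return f"rot{'m' if a < 0 else ''}{abs(a)}"
        if self.kind == "brightness":
            return f"bright{self.factor:.3f}"
        if self.kind == "gaussian_blur":
            return f"blur{self.sigma:.3f}"
        return self.kind


#: The default augmentation family: eight rotations plus the three flips.
DEFAULT_TRANSFORMS: tuple[Transform, ...] = tuple(
    [Transform("rotate", angle=a) for a in ROTATION_ANGLES]
    + [Transform("hflip"), Transform("vflip"), Transform("hvflip")]
)


@dataclass(frozen=True)
class AugmentationPlan:
    """An ordered list of (source id, transform) pairs of length ``budget``."""

    assignments: tuple[tuple[str, Transform], ...]
    budget: int

    def __post_init__(self):
        if len(self.assignments) != self.budget:
            raise ConfigurationError(
                f"budget: plan has {len(self.assignments)} assignments, expected {self.budget}")

    def per_source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sid, _ in self.assignments:
            counts[sid] = counts.get(sid, 0) + 1
        return counts


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def _resize_bilinear(a: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize with half-pixel centre alignment and edge clamping."""
    h, w = a.shape
    a = a.astype(np.float64, copy=False)

    def axis_coords(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        return i0, i1, src - i0

    r0, r1, wr = axis_coords(h, out_h)
    c0, c1, wc = axis_coords(w, out_w)
    top = a[r0][:, c0] * (1 - wc) + a[r0][:, c1] * wc
    bot = a[r1][:, c0] * (1 - wc) + a[r1][:, c1] * wc
    return top * (1 - wr[:, None]) + bot * wr[:, None]


def preprocess(raw_image: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Resize an 8-bit grayscale image to ``size`` x ``size`` and scale to
    [0, 1] by dividing by 255."""
    raw = np.asarray(raw_image)
    if raw.ndim != 2 or raw.size == 0:
        raise ShapeError(f"preprocess: expected a non-empty 2-D image, got shape {raw.shape}")
    out = _resize_bilinear(raw, size, size) / 255.0
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def preprocess_mask(raw_mask: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Resize a mask with nearest-neighbour sampling and binarize at 127."""
    raw = np.asarray(raw_mask)
    if raw.ndim != 2 or raw.size == 0:
        raise ShapeError(f"preprocess_mask: expected a non-empty 2-D mask, got shape {raw.shape}")
    h, w = raw.shape
    rows = np.clip(((np.arange(size) + 0.5) * (h / size) - 0.5).round().astype(int), 0, h - 1)
    cols = np.clip(((np.arange(size) + 0.5) * (w / size) - 0.5).round().astype(int), 0, w - 1)
    out = raw[rows][:, cols]
    return (out > 127).astype(np.uint8) if out.max(initial=0) > 1 else (out > 0).astype(np.uint8)


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

def split_counts(n: int) -> SplitCounts:
    """8:1:1 split sizes: validation and test take round-half-up of N/10
    each, training takes the remainder."""
    if n < 3:
        raise ConfigurationError(f"N: need at least 3 samples to split, got {n}")
    tenth = int(np.floor(n / 10 + 0.5))
    return SplitCounts(n_train=n - 2 * tenth, n_val=tenth, n_test=tenth)


def assign_split(ids: list[str], counts: SplitCounts, seed: int) -> dict[str, str]:
    """Seeded shuffle then contiguous assignment; returns id -> split name."""
    if len(set(ids)) != len(ids):
        raise ConfigurationError("ids: duplicate identifiers in split assignment")
    if len(ids) != counts.total:
        raise ConfigurationError(
            f"ids: {len(ids)} ids but counts sum to {counts.total}")
    order = list(ids)
    np.random.default_rng(seed).shuffle(order)
    out = {}
    for i, sid in enumerate(order):
        if i < counts.n_train:
            out[sid] = "train"
        elif i < counts.n_train + counts.n_val:
            out[sid] = "val"
        else:
            out[sid] = "test"
    return out


# --------------------------------------------------------------------------
# Augmentation
# --------------------------------------------------------------------------

def build_augmentation_plan(source_ids: list[str], budget: int,
                            transforms: tuple[Transform, ...] = DEFAULT_TRANSFORMS,
                            seed: int = 0) -> AugmentationPlan:
    """Distribute ``budget`` augmented copies over the sources.

    Every source is used floor(budget/n) or ceil(budget/n) times (the
    remainder goes to a seeded random subset); within a source the transform
    list is cycled in order, drawing fresh jitter parameters for brightness
    and blur entries on every use.
    """
    if budget < 0:
        raise ConfigurationError(f"budget: must be >= 0, got {budget}")
    if budget > 0 and not source_ids:
        raise ConfigurationError("source_ids: cannot augment an empty source set")
    if not transforms:
        raise ConfigurationError("transforms: need at least one transform")
    if budget == 0:
        return AugmentationPlan(assignments=(), budget=0)
    rng = np.random.default_rng(seed)
    n = len(source_ids)
    base, extra = divmod(budget, n)
    bonus = set(rng.permutation(n)[:extra].tolist())
    assignments = []
    for i, sid in enumerate(source_ids):
        count = base + (1 if i in bonus else 0)
        for k in range(count):
            t = transforms[k % len(transforms)]
            if t.kind == "brightness":
                t = Transform("brightness", factor=float(rng.uniform(0.8, 1.2)))
            elif t.kind == "gaussian_blur":
                t = Transform("gaussian_blur", sigma=float(rng.uniform(0.5, 1.5)))
            assignments.append((sid, t))
    return AugmentationPlan(assignments=tuple(assignments), budget=budget)


def _rotate(arr: np.ndarray, angle: float, order: int) -> np.ndarray:
    """Rotate about the image centre, positive angles counter-clockwise,
    constant-0 fill.  Right-angle multiples use exact ``np.rot90``."""
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(arr, k=int(angle // 90) % 4))
    theta = np.deg2rad(angle)
    # inverse map: output (row, col) -> input coordinates
    m = np.array([[np.cos(theta), np.sin(theta)],
                  [-np.sin(theta), np.cos(theta)]])
    centre = (np.asarray(arr.shape) - 1) / 2.0
    offset = centre - m @ centre
    return ndimage.affine_transform(arr, m, offset=offset, order=order,
                                    mode="constant", cval=0.0, prefilter=False)


def apply_transform(pair: ImagePair, t: Transform) -> ImagePair:
    """Apply a transform jointly to image and mask.

    Geometry acts identically on both (bilinear image / nearest mask);
    photometric transforms touch the image only.  The image is re-clipped to
    [0, 1] and the mask re-binarized at 0.5 afterwards.
    """
    img = np.asarray(pair.image, dtype=np.float32)
    msk = np.asarray(pair.mask)
    if t.kind == "hflip":
        img, msk = img[:, ::-1], msk[:, ::-1]
    elif t.kind == "vflip":
        img, msk = img[::-1, :], msk[::-1, :]
    elif t.kind == "hvflip":
        img, msk = img[::-1, ::-1], msk[::-1, ::-1]
    elif t.kind == "rotate":
        img = _rotate(img, t.angle, order=1)
        msk = _rotate(msk.astype(np.float32), t.angle, order=0)
    elif t.kind == "brightness":
        img = img * t.factor
    elif t.kind == "gaussian_blur":
        img = ndimage.gaussian_filter(img, sigma=t.sigma)
    else:  # pragma: no cover - constructor forbids it
        raise ConfigurationError(f"kind: unknown transform {t.kind!r}")
    img = np.clip(np.ascontiguousarray(img), 0.0, 1.0)
    msk = (np.ascontiguousarray(msk).astype(np.float32) > 0.5).astype(np.uint8)
    return ImagePair(image=img, mask=msk, id=f"{pair.id}__{t.tag}")


def augment_dataset(pairs: dict[str, ImagePair] | list[ImagePair],
                    plan: AugmentationPlan) -> list[ImagePair]:
    """Materialize an augmentation plan into transformed image pairs.

    Repeated (source, transform) combinations get a numeric suffix so ids
    stay unique.
    """
    if not isinstance(pairs, dict):
        pairs = {p.id: p for p in pairs}
    seen: dict[str, int] = {}
    out = []
    for sid, t in plan.assignments:
        new = apply_transform(pairs[sid], t)
        k = seen.get(new.id, 0)
        seen[new.id] = k + 1
        if k:
            new = ImagePair(new.image, new.mask, id=f"{new.id}_{k}")
        out.append(new)
    return out


# --------------------------------------------------------------------------
# PNG / manifest I/O
# --------------------------------------------------------------------------

def write_pairs(pairs: list[ImagePair], out_dir) -> None:
    """Write image/mask PNG pairs (8-bit; masks as {0, 255}) with matched
    basenames under ``images/`` and ``masks/``."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for p in pairs:
        img8 = np.round(np.asarray(p.image) * 255).astype(np.uint8)
        msk8 = (np.asarray(p.mask) * 255).astype(np.uint8)
        iio.imwrite(out / "images" / f"{p.id}.png", img8)
        iio.imwrite(out / "masks" / f"{p.id}.png", msk8)


def read_raw_pairs(in_dir) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Read raw (id, 8-bit image, 8-bit mask) triples from ``images/`` and
    ``masks/`` without normalization (input to :func:`preprocess`)."""
    root = Path(in_dir)
    out = []
    for img_path in sorted((root / "images").glob("*.png")):
        mask_path = root / "masks" / img_path.name
        if not mask_path.exists():
            raise ConfigurationError(f"masks: no mask for image {img_path.name}")
        out.append((img_path.stem,
                    np.asarray(iio.imread(img_path)),
                    np.asarray(iio.imread(mask_path))))
    return out


def read_pairs(in_dir) -> list[ImagePair]:
    """Read image/mask PNG pairs written by :func:`write_pairs`."""
    return [ImagePair(image=(img / 255.0).astype(np.float32),
                      mask=(msk > 127).astype(np.uint8), id=sid)
            for sid, img, msk in read_raw_pairs(in_dir)]


def write_manifest(assignment: dict[str, str], path) -> None:
    df = pd.DataFrame(sorted(assignment.items()), columns=["id", "split"])
    df.to_csv(path, index=False)


def read_manifest(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["id"].astype(str), df["split"].astype(str)))
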