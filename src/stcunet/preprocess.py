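"""CT preparation chain for KiTS19-style data.

Volume loading (NIfTI, per-case ``imaging``/``segmentation`` pair), canonical
reorientation, transverse slicing, window/level normalization, removal of
tumor-free slices, ROI cropping around the tumor, resampling to a uniform
square size, a seeded 8:2 train/test split, and mask-consistent online
augmentation.  Processed slices can be written to / read from a plain
directory layout: 8-bit PNG image + 0/255 PNG mask pairs indexed by a CSV
manifest (columns: case_id, slice_index, image, mask, split).

Coordinates are 0-based throughout.  Volumes are reoriented so the first
voxel axis runs inferior->superior; transverse slices are taken along it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageVolume",
    "SliceSample",
    "WindowSpec",
    "SplitResult",
    "AugmentConfig",
    "TUMOR_LABEL",
    "load_volume",
    "slice_volume",
    "apply_window",
    "filter_positive",
    "crop_roi",
    "resize_to",
    "split_dataset",
    "split_by_case",
    "augment",
    "run_pipeline",
    "write_dataset",
    "read_manifest",
    "load_sample",
]

#: KiTS19 label convention: 0 = background, 1 = kidney, 2 = tumor.
TUMOR_LABEL = 2

#: Canonical axis codes: first axis inferior->superior (transverse stacking).
_CANONICAL_AXCODES = ("S", "A", "R")


@dataclass
class ImageVolume:
    """3-D scalar field in Hounsfield-like units with geometry metadata."""

    voxels: np.ndarray  # [depth, height, width]
    spacing: tuple[float, float, float]  # mm, matching the voxel axes
    affine: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError(f"expected a [depth, H, W] volume, got {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")


@dataclass
class SliceSample:
    """One transverse slice: image, binary tumor mask and provenance."""

    image: np.ndarray  # [H, W]; HU before windowing, [0, 1] after
    mask: np.ndarray  # [H, W] in {0, 1}
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: HU range [level - width/2, level + width/2] maps
    affinely onto [0, 1].  Defaults to a conventional abdominal soft-tissue
    window (width 400 HU, level 40 HU)."""

    width: float = 400.0
    level: float = 40.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")


@dataclass(frozen=True)
class SplitResult:
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int


@dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation: crop-and-resize, flips and intensity jitter.

    Flips and crops act on image and mask jointly; jitter (brightness shift
    and contrast scale on the [0, 1] image) never touches the mask.
    """

    p_crop: float = 0.5
    crop_scale: tuple[float, float] = (0.7, 1.0)
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_jitter: float = 0.5
    brightness: float = 0.1
    contrast: float = 0.1


# ---------------------------------------------------------------------------
# loading and slicing
# ---------------------------------------------------------------------------

def _reorient(img: nib.Nifti1Image) -> nib.Nifti1Image:
    current = nib.orientations.io_orientation(img.affine)
    target = nib.orientations.axcodes2ornt(_CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(current, target)
    return img.as_reoriented(transform)


def load_volume(case_dir) -> tuple[ImageVolume, ImageVolume]:
    """Load a KiTS19-style case directory (``imaging.nii.gz`` +
    ``segmentation.nii.gz``); returns (image volume, binary tumor-label
    volume), both reoriented to the canonical axis order."""
    case_dir = Path(case_dir)
    img_path = _find_nifti(case_dir, "imaging")
    seg_path = _find_nifti(case_dir, "segmentation")
    img = _reorient(nib.load(img_path))
    seg = _reorient(nib.load(seg_path))
    voxels = np.asarray(img.get_fdata(), dtype=np.float32)
    labels = np.asarray(seg.get_fdata())
    if voxels.shape != labels.shape:
        raise ValueError(
            f"imaging shape {voxels.shape} != segmentation shape {labels.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    case_id = case_dir.name
    vol = ImageVolume(voxels, spacing, img.affine, case_id)
    mask = (labels == TUMOR_LABEL).astype(np.uint8)
    lab = ImageVolume(mask, spacing, seg.affine, case_id)
    return vol, lab


def _find_nifti(case_dir: Path, stem: str) -> Path:
    for suffix in (".nii.gz", ".nii"):
        p = case_dir / (stem + suffix)
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}.nii[.gz] in {case_dir}")


def slice_volume(vol: ImageVolume, labels: ImageVolume) -> list[SliceSample]:
    """One SliceSample per transverse index, order preserved."""
    if vol.voxels.shape != labels.voxels.shape:
        raise ValueError(
            f"volume shape {vol.voxels.shape} != label shape {labels.voxels.shape}")
    return [
        SliceSample(image=vol.voxels[k], mask=labels.voxels[k].astype(np.uint8),
                    case_id=vol.case_id, slice_index=k)
        for k in range(vol.voxels.shape[0])
    ]


# ---------------------------------------------------------------------------
# per-slice transforms
# ---------------------------------------------------------------------------

def apply_window(image: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Clip to the HU window and map it affinely to [0, 1]."""
    lo = spec.level - spec.width / 2.0
    out = (np.asarray(image, dtype=np.float64) - lo) / spec.width
    return np.clip(out, 0.0, 1.0)


def filter_positive(slices: list[SliceSample]) -> list[SliceSample]:
    """Keep exactly the slices whose mask contains at least one tumor pixel."""
    return [s for s in slices if s.mask.any()]


def crop_roi(sample: SliceSample, margin: int = 16) -> SliceSample:
    """Crop image and mask to the tumor bounding box expanded by ``margin``
    pixels and clipped to the frame."""
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    rows = np.flatnonzero(sample.mask.any(axis=1))
    cols = np.flatnonzero(sample.mask.any(axis=0))
    if rows.size == 0:
        raise ValueError(
            "mask has no positive pixels; run filter_positive before crop_roi")
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + margin, sample.mask.shape[0] - 1)
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + margin, sample.mask.shape[1] - 1)
    return replace(sample, image=sample.image[r0:r1 + 1, c0:c1 + 1],
                   mask=sample.mask[r0:r1 + 1, c0:c1 + 1])


def resize_to(sample: SliceSample, size: int = 512) -> SliceSample:
    """Resample to size x size: bilinear for the image, nearest for the mask."""
    if sample.image.shape == (size, size):
        return sample
    image = _sk_resize(sample.image.astype(np.float64), (size, size), order=1,
                       mode="edge", anti_aliasing=False, preserve_range=True)
    mask = _sk_resize(sample.mask.astype(np.float64), (size, size), order=0,
                      mode="edge", anti_aliasing=False, preserve_range=True)
    return replace(sample, image=image, mask=(mask > 0.5).astype(np.uint8))


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(n: int, train_fraction: float = 0.8, seed: int = 0) -> SplitResult:
    """Seeded random split; |train| = round-half-up(train_fraction * n)."""
    if n < 1:
        raise ValueError(f"cannot split {n} items")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_fraction * n + 0.5))
    return SplitResult(
        train_indices=tuple(int(i) for i in perm[:n_train]),
        test_indices=tuple(int(i) for i in perm[n_train:]),
        seed=seed,
    )


def split_by_case(case_ids: list[str], train_fraction: float = 0.8,
                  seed: int = 0) -> SplitResult:
    """Patient-level split: whole cases go to one partition, so slices from
    one patient never straddle train and test.  Preferred over the slice-level
    split when per-patient generalization matters."""
    if not case_ids:
        raise ValueError("cannot split an empty dataset")
    unique = sorted(set(case_ids))
    case_split = split_dataset(len(unique), train_fraction, seed)
    train_cases = {unique[i] for i in case_split.train_indices}
    train = tuple(i for i, c in enumerate(case_ids) if c in train_cases)
    test = tuple(i for i, c in enumerate(case_ids) if c not in train_cases)
    return SplitResult(train_indices=train, test_indices=test, seed=seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: SliceSample, cfg: AugmentConfig,
            rng: np.random.Generator) -> SliceSample:
    """Random crop-and-resize, flips and intensity jitter; mask stays binary
    and shapes are preserved."""
    image = sample.image
    mask = sample.mask
    h, w = image.shape
    if rng.random() < cfg.p_crop:
        scale = rng.uniform(*cfg.crop_scale)
        ch, cw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        crop = SliceSample(image[r0:r0 + ch, c0:c0 + cw],
                           mask[r0:r0 + ch, c0:c0 + cw],
                           sample.case_id, sample.slice_index)
        # resize back to the original frame (assumes square frames for the
        # shared `size`; rectangular crops resize per-axis)
        image = _sk_resize(crop.image.astype(np.float64), (h, w), order=1,
                           mode="edge", anti_aliasing=False, preserve_range=True)
        mask = (_sk_resize(crop.mask.astype(np.float64), (h, w), order=0,
                           mode="edge", anti_aliasing=False,
                           preserve_range=True) > 0.5).astype(np.uint8)
    if rng.random() < cfg.p_hflip:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if rng.random() < cfg.p_vflip:
        image = image[::-1, :]
        mask = mask[::-1, :]
    if rng.random() < cfg.p_jitter:
        shift = rng.uniform(-cfg.brightness, cfg.brightness)
        scale = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        mean = image.mean()
        image = np.clip((image - mean) * scale + mean + shift, 0.0, 1.0)
    return replace(sample, image=np.ascontiguousarray(image),
                   mask=np.ascontiguousarray(mask))


# ---------------------------------------------------------------------------
# pipeline + on-disk dataset
# ---------------------------------------------------------------------------

def run_pipeline(vol: ImageVolume, labels: ImageVolume,
                 window: WindowSpec = WindowSpec(), margin: int = 16,
                 size: int = 512) -> list[SliceSample]:
    """slice -> window -> drop tumor-free slices -> ROI crop -> resize."""
    slices = slice_volume(vol, labels)
    slices = [replace(s, image=apply_window(s.image, window)) for s in slices]
    slices = filter_positive(slices)
    return [resize_to(crop_roi(s, margin), size) for s in slices]


def write_dataset(samples: list[SliceSample], out_dir, split: SplitResult | None = None,
                  seed: int = 0) -> Path:
    """Write PNG image/mask pairs plus a CSV manifest; returns manifest path.

    Images must already be windowed to [0, 1]; they are stored as 8-bit PNG.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    if split is None:
        split = split_dataset(len(samples), seed=seed)
    assignment = {}
    for i in split.train_indices:
        assignment[i] = "train"
    for i in split.test_indices:
        assignment[i] = "test"
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "slice_index", "image", "mask", "split"])
        for i, s in enumerate(samples):
            stem = f"{s.case_id or 'case'}_{s.slice_index:04d}_{i:05d}"
            img_rel = f"images/{stem}.png"
            mask_rel = f"masks/{stem}.png"
            img8 = np.clip(np.round(s.image * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(img8).save(out_dir / img_rel)
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(out_dir / mask_rel)
            writer.writerow([s.case_id, s.slice_index, img_rel, mask_rel,
                             assignment[i]])
    return manifest


def read_manifest(manifest) -> list[dict]:
    """Rows of the CSV manifest as dicts with absolute file paths."""
    manifest = Path(manifest)
    root = manifest.parent
    rows = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            row["image"] = str(root / row["image"])
            row["mask"] = str(root / row["mask"])
            row["slice_index"] = int(row["slice_index"])
            rows.append(row)
    if not rows:
        raise ValueError(f"manifest {manifest} is empty")
    return rows


def load_sample(row: dict) -> SliceSample:
    """Read one manifest row back into a SliceSample (image in [0, 1])."""
    image = np.asarray(Image.open(row["image"]), dtype=np.float64) / 255.0
    mask = (np.asarray(Image.open(row["mask"])) > 127).astype(np.uint8)
    return SliceSample(image=image, mask=mask, case_id=row["case_id"],
                       slice_index=row["slice_index"])
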