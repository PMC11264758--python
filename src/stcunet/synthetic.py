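"""Seedable CT-like phantom generator.

Each phantom slice emulates the regime of an abdominal CT slice around a
renal tumor: a noisy soft-tissue background, a brighter organ ellipse, and —
usually — an embedded tumor blob a fixed HU offset above the organ whose
boundary is softened by a Gaussian blur.  The mask is the exact pre-blur
tumor support, so ground truth is known to the pixel.  Phantom volumes stack
slices with a contiguous tumor-bearing slab and can be written as a NIfTI
pair in the KiTS19 per-case layout, which lets the whole preprocessing chain
run without any downloaded data.

Default geometry is desk-scale (96 x 96, divisible by 16).  The tumor sits
+60 HU above the organ with a 1.5 px boundary blur over ~25 HU background
noise: clearly learnable, but not separable by a single global threshold
because organ and background overlap the tumor's blurred rim.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import (
    ImageVolume,
    SliceSample,
    SplitResult,
    WindowSpec,
    apply_window,
    write_dataset,
)

__all__ = ["PhantomParams", "make_phantom_slice", "make_phantom_volume",
           "write_phantom_case", "make_phantom_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings, intensities in Hounsfield-like units."""

    size: int = 96
    background_hu: float = -20.0
    background_noise: float = 25.0
    organ_hu: tuple[float, float] = (35.0, 55.0)
    organ_axes: tuple[float, float] = (0.22, 0.40)  # fraction of frame size
    organ_center_jitter: float = 0.08  # fraction of frame size
    tumor_offset_hu: float = 60.0
    tumor_radius: tuple[float, float] = (4.0, 10.0)  # pixels
    boundary_blur: float = 1.5  # pixels
    tumor_probability: float = 1.0
    window: WindowSpec = WindowSpec()

    def __post_init__(self):
        if self.size < 16:
            raise ValueError("frame size must be at least 16 px")
        if self.tumor_radius[0] < 1.0:
            raise ValueError("tumor radius must be >= 1 px")
        if self.boundary_blur < 0 or self.background_noise < 0:
            raise ValueError("blur and noise sigmas must be non-negative")
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ValueError("tumor_probability must be in [0, 1]")


def _phantom_hu(params: PhantomParams, rng: np.random.Generator,
                force_tumor: bool | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Raw HU slice + binary tumor mask."""
    n = params.size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    # organ ellipse
    jitter = params.organ_center_jitter * n
    cy = n / 2.0 + rng.uniform(-jitter, jitter)
    cx = n / 2.0 + rng.uniform(-jitter, jitter)
    ay = rng.uniform(*params.organ_axes) * n
    ax = rng.uniform(*params.organ_axes) * n
    organ = (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2) <= 1.0
    organ_hu = rng.uniform(*params.organ_hu)
    base = np.full((n, n), params.background_hu)
    base[organ] = organ_hu
    base = gaussian_filter(base, params.boundary_blur)

    want_tumor = (rng.random() < params.tumor_probability
                  if force_tumor is None else force_tumor)
    mask = np.zeros((n, n), dtype=np.uint8)
    if want_tumor:
        for attempt in range(50):
            r = rng.uniform(*params.tumor_radius)
            # place the tumor center well inside the organ ellipse
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rho = np.sqrt(rng.random()) * 0.55
            ty = cy + rho * ay * np.sin(theta)
            tx = cx + rho * ax * np.cos(theta)
            inside = (((ty - cy) / max(ay - r, 1e-6)) ** 2
                      + ((tx - cx) / max(ax - r, 1e-6)) ** 2) <= 1.0
            if inside and r >= 1.0:
                break
        else:
            raise RuntimeError("could not place a tumor inside the organ")
        mask = ((yy - ty) ** 2 + (xx - tx) ** 2 <= r * r).astype(np.uint8)
        if not mask.any():  # radius < half a pixel between grid points
            mask[int(round(ty)) % n, int(round(tx)) % n] = 1
        tumor_field = params.tumor_offset_hu * mask.astype(np.float64)
        base = base + gaussian_filter(tumor_field, params.boundary_blur)
    noise = rng.normal(0.0, params.background_noise, size=(n, n))
    return base + noise, mask


def make_phantom_slice(params: PhantomParams, rng: np.random.Generator,
                       windowed: bool = True,
                       force_tumor: bool | None = None) -> SliceSample:
    """One phantom slice; image windowed to [0, 1] unless ``windowed=False``
    (then raw HU)."""
    hu, mask = _phantom_hu(params, rng, force_tumor)
    image = apply_window(hu, params.window) if windowed else hu
    return SliceSample(image=image, mask=mask, case_id="phantom", slice_index=0)


def make_phantom_volume(params: PhantomParams, depth: int,
                        rng: np.random.Generator,
                        tumor_slices: tuple[int, int] | None = None,
                        ) -> tuple[ImageVolume, ImageVolume]:
    """Stack of phantom slices with a contiguous tumor-bearing slab.

    ``tumor_slices`` is a half-open (start, stop) range of slab indices;
    by default the middle half of the volume carries the tumor.  The label
    volume uses the KiTS19 0/1/2 convention (organ = 1, tumor = 2).
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if tumor_slices is None:
        tumor_slices = (depth // 4, depth // 4 + max(depth // 2, 1))
    start, stop = tumor_slices
    voxels = np.empty((depth, params.size, params.size), dtype=np.float32)
    labels = np.zeros((depth, params.size, params.size), dtype=np.uint8)
    for k in range(depth):
        in_slab = start <= k < stop
        hu, mask = _phantom_hu(params, rng, force_tumor=in_slab)
        voxels[k] = hu
        # crude organ label: everything a noise margin above background
        organ = (gaussian_filter(hu, 2.0)
                 > params.background_hu + 2.0 * params.background_noise)
        labels[k][organ] = 1
        labels[k][mask.astype(bool)] = 2
    spacing = (3.0, 1.0, 1.0)  # mm; anisotropic like abdominal CT
    # voxel axis 0 runs inferior->superior (world z), axes 1/2 along A and R,
    # so canonical reorientation leaves the array untouched
    affine = np.array([
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [spacing[0], 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    vol = ImageVolume(voxels, spacing, affine, case_id="phantom_case")
    lab = ImageVolume(labels, spacing, affine, case_id="phantom_case")
    return vol, lab


def write_phantom_case(vol: ImageVolume, lab: ImageVolume, case_dir,
                       affine: np.ndarray | None = None) -> Path:
    """Write a phantom volume pair as ``imaging.nii.gz`` +
    ``segmentation.nii.gz`` in a KiTS19-style case directory."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    aff = vol.affine if affine is None else affine
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), aff),
             case_dir / "imaging.nii.gz")
    nib.save(nib.Nifti1Image(lab.voxels.astype(np.uint8), aff),
             case_dir / "segmentation.nii.gz")
    return case_dir


def make_phantom_dataset(out_dir, n_slices: int, params: PhantomParams,
                         seed: int = 0, train_fraction: float = 0.8) -> Path:
    """Generate ``n_slices`` phantom slices and write them in the manifest
    layout the preprocessing chain produces; returns the manifest path."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_slices):
        s = make_phantom_slice(params, rng)
        s.case_id = f"phantom_{i:05d}"
        samples.append(s)
    from .preprocess import split_dataset
    split = split_dataset(n_slices, train_fraction, seed)
    return write_dataset(samples, out_dir, split=split)
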