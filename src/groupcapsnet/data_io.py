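"""CT volume reading, preprocessing and slice-sample handling.

Brain tissue and acute hemorrhage live below 90 HU, so volumes are windowed
to 0-90 HU and scaled to [0, 1].  Volumes are split into axial slices,
resized to the working resolution (bilinear for images, nearest for masks so
labels stay binary), and augmented at train time with random flips/rotations
applied identically to image and mask plus additive Gaussian noise on the
image only.

On-disk layout: one 16-bit PNG per slice image, one 8-bit PNG per mask, and
a CSV manifest with (volume_id, z, fold) — the same layout the phantom
generator writes, so synthetic and real data are interchangeable downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

HU_WINDOW = (0.0, 90.0)


@dataclass(frozen=True)
class CTVolume:
    """A CT scan in Hounsfield units, axial stacking on the last axis."""

    voxels: np.ndarray                 # (H, W, Z)
    spacing: tuple | None = None       # carried, not used by the model
    volume_id: str = "volume"

    def __post_init__(self):
        if self.voxels.ndim != 3 or self.voxels.shape[2] < 1:
            raise ValueError("CT volume must be (H, W, Z) with Z >= 1")
        if not np.isfinite(self.voxels).all():
            raise ValueError(f"{self.volume_id}: non-finite HU values")


@dataclass(frozen=True)
class SliceSample:
    """One working slice: image in [0, 1], binary mask, provenance."""

    image: np.ndarray
    mask: np.ndarray
    volume_id: str
    z: int
    fold: int | None = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} "
                "are not aligned")


def load_volume(path, volume_id=None) -> CTVolume:
    """Load a CT volume from NIfTI (.nii/.nii.gz) or a DICOM series dir."""
    path = Path(path)
    vid = volume_id or path.stem.replace(".nii", "")
    if path.is_dir():
        return _load_dicom_series(path, vid)
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=data, spacing=spacing, volume_id=vid)


def _load_dicom_series(path: Path, vid: str) -> CTVolume:
    import pydicom
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(getattr(d, "ImagePositionPatient",
                                            [0, 0, d.InstanceNumber])[2]))
    hu = [d.pixel_array * float(getattr(d, "RescaleSlope", 1.0))
          + float(getattr(d, "RescaleIntercept", 0.0)) for d in slices]
    vol = np.stack(hu, axis=-1).astype(np.float32)
    d0 = slices[0]
    spacing = None
    if hasattr(d0, "PixelSpacing"):
        st = float(getattr(d0, "SliceThickness", 1.0))
        spacing = (float(d0.PixelSpacing[0]), float(d0.PixelSpacing[1]), st)
    return CTVolume(voxels=vol, spacing=spacing, volume_id=vid)


def window_normalize(volume, window=HU_WINDOW):
    """Clip HU into [0, 90] and scale to [0, 1].

    Accepts a CTVolume or a bare array; returns the same kind.
    """
    lo, hi = window
    if isinstance(volume, CTVolume):
        out = (np.clip(volume.voxels, lo, hi) - lo) / (hi - lo)
        return CTVolume(out.astype(np.float32), volume.spacing,
                        volume.volume_id)
    arr = np.asarray(volume, dtype=np.float32)
    return ((np.clip(arr, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def slice_volume(volume: CTVolume, masks: np.ndarray, out_size: int = 256,
                 keep_empty: bool = True) -> list[SliceSample]:
    """Split a (normalized) volume into axial slice samples.

    Images are resized with bilinear interpolation, masks with
    nearest-neighbour so they stay binary.  Slices without any hemorrhage
    are retained by default.
    """
    masks = np.asarray(masks)
    if masks.shape != volume.voxels.shape:
        raise ValueError(
            f"mask volume {masks.shape} misaligned with CT volume "
            f"{volume.voxels.shape}")
    out = []
    for z in range(volume.voxels.shape[2]):
        img, msk = volume.voxels[:, :, z], masks[:, :, z]
        if img.shape != (out_size, out_size):
            img = resize(img, (out_size, out_size), order=1,
                         preserve_range=True, anti_aliasing=False)
            msk = resize(msk, (out_size, out_size), order=0,
                         preserve_range=True, anti_aliasing=False)
        msk = (msk > 0.5).astype(np.uint8)
        if not keep_empty and msk.sum() == 0:
            continue
        out.append(SliceSample(image=img.astype(np.float32), mask=msk,
                               volume_id=volume.volume_id, z=z))
    return out


def augment(sample: SliceSample, seed, noise_variance: float = 0.01,
            arbitrary_rotation: bool = False) -> SliceSample:
    """Random flip + rotation (image and mask together) and Gaussian noise
    on the image only, re-clipped to [0, 1]; deterministic given the seed.

    Rotations default to multiples of 90 degrees (lossless for mask
    binarity); arbitrary angles are available behind a flag.  The noise
    parameter is a *variance* (0.01 -> std 0.1).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    img, msk = sample.image.copy(), sample.mask.copy()
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[::-1, :], msk[::-1, :]
    if arbitrary_rotation:
        from scipy import ndimage
        angle = rng.uniform(-180.0, 180.0)
        img = ndimage.rotate(img, angle, order=1, reshape=False, cval=0.0)
        msk = ndimage.rotate(msk, angle, order=0, reshape=False, cval=0)
    else:
        k = int(rng.integers(0, 4))
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    img = img + rng.normal(0.0, np.sqrt(noise_variance), img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return replace(sample, image=np.ascontiguousarray(img),
                   mask=np.ascontiguousarray(msk.astype(np.uint8)))


# ---------------------------------------------------------------------------
# On-disk slice-sample sets
# ---------------------------------------------------------------------------

def _names(sample):
    stem = f"{sample.volume_id}_z{sample.z:03d}"
    return f"{stem}_img.png", f"{stem}_mask.png"


def save_samples(directory, samples, manifest_name="manifest.csv"):
    """Write slices as 16-bit image PNGs + 8-bit mask PNGs + CSV manifest."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for s in samples:
        img_name, mask_name = _names(s)
        img16 = np.round(np.clip(s.image, 0, 1) * 65535).astype(np.uint16)
        iio.imwrite(directory / img_name, img16)
        iio.imwrite(directory / mask_name,
                    (s.mask > 0).astype(np.uint8) * 255)
        rows.append({"volume_id": s.volume_id, "z": s.z,
                     "fold": -1 if s.fold is None else s.fold,
                     "image": img_name, "mask": mask_name})
    pd.DataFrame(rows).to_csv(directory / manifest_name, index=False)
    return directory / manifest_name


def load_samples(directory, manifest_name="manifest.csv"):
    """Read back a slice-sample set written by :func:`save_samples`."""
    directory = Path(directory)
    df = pd.read_csv(directory / manifest_name)
    samples = []
    for row in df.itertuples(index=False):
        img = iio.imread(directory / row.image).astype(np.float32) / 65535.0
        msk = (iio.imread(directory / row.mask) > 0).astype(np.uint8)
        samples.append(SliceSample(
            image=img, mask=msk, volume_id=str(row.volume_id), z=int(row.z),
            fold=None if int(row.fold) < 0 else int(row.fold)))
    return samples
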