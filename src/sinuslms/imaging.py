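"""CT volume containers, NIfTI/DICOM reading and the preprocessing chain.

Conventions
-----------
Volumes are indexed ``(slice, row, col)``, 0-based, with coronal slices
stacked on axis 0.  Image intensities live on a Hounsfield-like scale
(air ~ -1000 HU, soft tissue ~ +40 HU, bone >> +300 HU) until the final
z-score normalization step, which exists only to feed the network;
threshold-based scoring always operates on the HU-scale copy.

Preprocessing follows common CT segmentation practice: clip to
[-1000, +1000] HU, crop rows/cols to an air-driven region of interest,
resample each slice to a fixed grid (bilinear for images, nearest
neighbour for labels) and finally z-score per volume.  The fitted
:class:`PreprocessTransform` is returned so the paired label volume and
any HU-scale copy can be mapped through the identical geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import FormatError, NormalizationError, ShapeMismatchError
from .regions import Region

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "PreprocessTransform",
    "read_volume",
    "write_volume",
    "write_labels",
    "read_labels",
    "preprocess",
    "apply_transform_to_labels",
]

HU_CLIP = (-1000.0, 1000.0)
#: voxels below this HU value are treated as air-containing when locating the ROI
AIR_ROI_THRESHOLD = -300.0
ROI_MARGIN = 16


@dataclass
class ImageVolume:
    """Stack of coronal slices with Hounsfield-like intensities.

    Parameters
    ----------
    data : (n_slices, rows, cols) float array
    spacing : mm per axis, ordered like the data axes
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    coronal_axis: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3-D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer label map over the 12 Lund-Mackay regions plus background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError("label volume must be integer-typed")
        self.data = self.data.astype(np.int16, copy=False)
        if self.data.min() < 0 or self.data.max() > 12:
            raise FormatError("label codes must lie in {0..12}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# reading / writing


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write an image volume as NIfTI-1 (.nii or .nii.gz)."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))
    return path


def write_labels(labels: LabelVolume, path: str | Path, sidecar: bool = True) -> Path:
    """Write a label volume as NIfTI plus a ``{code: region}`` JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([*labels.spacing, 1.0])
    nib.save(nib.Nifti1Image(labels.data.astype(np.int16), affine), str(path))
    if sidecar:
        side = path.with_name(path.name.split(".")[0] + "_labels.json")
        side.write_text(json.dumps(Region.label_dictionary(), indent=1))
    return path


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred from the path (directory -> DICOM series).  DICOM stored
    values are converted to HU via RescaleSlope/RescaleIntercept.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        data, spacing = _read_nifti(path)
        return ImageVolume(np.asarray(data, dtype=np.float32), spacing)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> LabelVolume:
    data, spacing = _read_nifti(Path(path))
    return LabelVolume(np.rint(data).astype(np.int16), spacing)


def _read_dicom_series(directory: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM clutter is ignored
    if not datasets:
        raise IOError(f"no readable DICOM files in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise FormatError(f"mixed DICOM series in {directory}: {sorted(map(str, uids))}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice shapes in series: {shapes}")
    ds0 = datasets[0]
    pixel = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    return ImageVolume(np.stack(slices), (thickness, float(pixel[0]), float(pixel[1])))


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessTransform:
    """Record of the geometry applied by :func:`preprocess`.

    Applying the same crop/resample to the paired label volume (nearest
    neighbour) or to an HU-scale copy keeps every product aligned.
    """

    source_shape: tuple[int, int, int]
    crop_box: tuple[int, int, int, int]  # r0, r1, c0, c1 (half-open)
    target_shape: tuple[int, int]  # rows, cols
    mean: float = 0.0
    std: float = 1.0
    clip: tuple[float, float] = HU_CLIP

    def _check(self, shape: tuple[int, ...]) -> None:
        if tuple(shape) != tuple(self.source_shape):
            raise ShapeMismatchError(
                f"transform fitted on shape {self.source_shape}, got {shape}"
            )

    def apply_to_image(self, vol: ImageVolume, normalize: bool = True) -> ImageVolume:
        self._check(vol.shape)
        r0, r1, c0, c1 = self.crop_box
        data = np.clip(vol.data, *self.clip)[:, r0:r1, c0:c1]
        out = np.empty((data.shape[0], *self.target_shape), dtype=np.float32)
        for i, sl in enumerate(data):
            out[i] = _sk_resize(
                sl, self.target_shape, order=1, preserve_range=True, anti_aliasing=False
            )
        if normalize:
            out = (out - self.mean) / self.std
        return ImageVolume(out, vol.spacing)

    def apply_to_labels(self, labels: LabelVolume) -> LabelVolume:
        self._check(labels.shape)
        r0, r1, c0, c1 = self.crop_box
        data = labels.data[:, r0:r1, c0:c1]
        out = np.empty((data.shape[0], *self.target_shape), dtype=np.int16)
        for i, sl in enumerate(data):
            res = _sk_resize(
                sl.astype(np.float32),
                self.target_shape,
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            )
            out[i] = np.rint(res).astype(np.int16)
        return LabelVolume(out, labels.spacing)


def _roi_box(
    clipped: np.ndarray, threshold: float, margin: int
) -> tuple[int, int, int, int]:
    """Bounding box (rows/cols) of air-containing voxels, dilated by ``margin``."""
    air = clipped < threshold
    rows = np.any(air, axis=(0, 2))
    cols = np.any(air, axis=(0, 1))
    if not rows.any():
        return 0, clipped.shape[1], 0, clipped.shape[2]
    r = np.flatnonzero(rows)
    c = np.flatnonzero(cols)
    r0 = max(int(r[0]) - margin, 0)
    r1 = min(int(r[-1]) + 1 + margin, clipped.shape[1])
    c0 = max(int(c[0]) - margin, 0)
    c1 = min(int(c[-1]) + 1 + margin, clipped.shape[2])
    return r0, r1, c0, c1


def preprocess(
    vol: ImageVolume,
    target_rows: int = 448,
    target_cols: int = 512,
    crop: tuple[int, int, int, int] | str = "auto",
    air_threshold: float = AIR_ROI_THRESHOLD,
    margin: int = ROI_MARGIN,
) -> tuple[ImageVolume, PreprocessTransform]:
    """Clip, crop to the ROI, resample to the target grid and z-score.

    Returns the normalized volume and the fitted transform.  ``crop`` may
    be ``"auto"`` (bounding box of sub-threshold voxels dilated by
    ``margin``), ``"none"`` (full frame) or an explicit ``(r0, r1, c0, c1)``
    box.  A constant-intensity volume cannot be z-scored and raises
    :class:`NormalizationError`.
    """
    clipped = np.clip(vol.data, *HU_CLIP)
    if crop == "auto":
        box = _roi_box(clipped, air_threshold, margin)
    elif crop == "none":
        box = (0, vol.shape[1], 0, vol.shape[2])
    else:
        box = tuple(int(v) for v in crop)  # type: ignore[assignment]
        if len(box) != 4 or box[0] >= box[1] or box[2] >= box[3]:
            raise ValueError(f"invalid crop box {box}")

    tf = PreprocessTransform(vol.shape, box, (target_rows, target_cols))
    resampled = tf.apply_to_image(vol, normalize=False)
    mean = float(resampled.data.mean())
    std = float(resampled.data.std())
    if std == 0.0:
        raise NormalizationError("constant-intensity volume cannot be normalized")
    tf.mean, tf.std = mean, std
    out = ImageVolume((resampled.data - mean) / std, vol.spacing)
    return out, tf


def apply_transform_to_labels(labels: LabelVolume, transform: PreprocessTransform) -> LabelVolume:
    """Map a label volume through a fitted preprocessing transform.

    Nearest-neighbour resampling only: the label set can shrink (a region
    may vanish under heavy downscaling) but never gains new codes.
    """
    return transform.apply_to_labels(labels)
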