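"""Reading, writing and calibrating microCT volumes.

Volumes are held as 3D integer grids with an isotropic voxel size. The grid
axis convention (configurable through ``axis_labels``) is::

    axis 0 -> dorsoventral   (dorsal at index 0)
    axis 1 -> mediolateral
    axis 2 -> anteroposterior (anterior at slice 0; the DICOM slice axis)

Raw intensities are mapped to tissue mineral density (TMD, mgHA/cm^3) with a
scanner calibration of the form ``(x / divisor) * slope + intercept``. The
calibration is supplied by configuration, not read from DICOM rescale tags:
the published mapping addresses raw pixel values, and scanner exports do not
reliably carry hydroxyapatite-phantom calibrations in standard tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

__all__ = [
    "CalibrationParams",
    "CalibratedVolume",
    "DEFAULT_CALIBRATION",
    "calibrate_intensity",
    "read_dicom_series",
    "write_dicom_series",
    "reorient",
    "project",
]

#: Anatomical names accepted in ``axis_labels``.
_ANATOMICAL_AXES = ("dorsoventral", "mediolateral", "anteroposterior")


@dataclass(frozen=True)
class CalibrationParams:
    """Raw-intensity to mineral-density calibration.

    Parameters
    ----------
    slope :
        mgHA/cm^3 per normalized intensity unit.
    intercept :
        mgHA/cm^3 offset.
    divisor :
        Dimensionless normalization constant applied to raw intensities
        before the linear map. Related to (but not necessarily equal to)
        the scanner bit depth, hence configurable.
    """

    slope: float = 281.706
    intercept: float = -195.402
    divisor: float = 4096.0

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError(f"divisor must be > 0, got {self.divisor}")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


#: Calibration of the scanner used for the reference cohorts.
DEFAULT_CALIBRATION = CalibrationParams()


@dataclass
class CalibratedVolume:
    """A 3D microCT intensity grid with voxel size and HA calibration.

    ``intensities`` holds raw (uncalibrated) integer values; ``voxel_size``
    is the isotropic voxel edge in micrometres.
    """

    intensities: np.ndarray
    voxel_size: float
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    axis_labels: tuple[str, str, str] = _ANATOMICAL_AXES

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if sorted(self.axis_labels) != sorted(_ANATOMICAL_AXES):
            raise ValueError(
                f"axis_labels must be a permutation of {_ANATOMICAL_AXES}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("raw intensities must be non-negative")

    @property
    def ap_axis(self) -> int:
        """Index of the anteroposterior grid axis."""
        return self.axis_labels.index("anteroposterior")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def calibrated(self) -> np.ndarray:
        """Return the volume mapped to mineral density (mgHA/cm^3)."""
        return calibrate_intensity(self.intensities, self.calibration)


def calibrate_intensity(x, cal: CalibrationParams):
    """Map raw intensity ``x`` to tissue mineral density in mgHA/cm^3.

    Applies ``(x / divisor) * slope + intercept`` elementwise. Negative
    outputs (raw values below the zero-density crossing) are retained;
    density statistics are only ever taken over above-threshold bone voxels.
    """
    x = np.asarray(x, dtype=float)
    out = (x / cal.divisor) * cal.slope + cal.intercept
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# DICOM series I/O
# ---------------------------------------------------------------------------

def read_dicom_series(
    path: str | Path,
    calibration: CalibrationParams | None = None,
    spacing_rtol: float = 0.01,
) -> CalibratedVolume:
    """Read a directory of single-slice DICOM files into a volume.

    Slices are stacked along the anteroposterior axis in spatial order
    (ImagePositionPatient z, falling back to InstanceNumber), regardless of
    filename order on disk. Voxel size is taken from PixelSpacing /
    spacing-between-slices tags and must be isotropic within ``spacing_rtol``.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(str(p)) for p in files]
    if not datasets:
        raise FileNotFoundError(f"no DICOM slices found in {path}")

    def _zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_zpos)

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice dimensions across series: {sorted(shapes)}")

    ds0 = datasets[0]
    row_um, col_um = (float(v) * 1000.0 for v in ds0.PixelSpacing)
    if len(datasets) > 1:
        zs = np.array([_zpos(ds) for ds in datasets])
        slice_um = float(np.mean(np.diff(zs))) * 1000.0
    else:
        slice_um = float(getattr(ds0, "SliceThickness", row_um / 1000.0)) * 1000.0
    spacings = np.array([row_um, col_um, slice_um])
    if np.ptp(spacings) > spacing_rtol * spacings.mean():
        raise ValueError(
            "anisotropic voxel spacing beyond tolerance: "
            f"row={row_um:.4g} um, col={col_um:.4g} um, slice={slice_um:.4g} um"
        )

    stack = np.stack([ds.pixel_array for ds in datasets], axis=-1)
    return CalibratedVolume(
        intensities=stack,
        voxel_size=float(spacings.mean()),
        calibration=calibration or DEFAULT_CALIBRATION,
    )


def write_dicom_series(vol: CalibratedVolume, path: str | Path) -> list[Path]:
    """Write a volume as one uint16 DICOM file per anteroposterior slice.

    The round trip through :func:`read_dicom_series` is bit-exact for
    integer intensities.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.intensities)
    if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
        raise ValueError("intensities outside uint16 range")
    data = np.moveaxis(data, vol.ap_axis, -1).astype(np.uint16)

    mm = vol.voxel_size / 1000.0
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    written = []
    for k in range(data.shape[-1]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [mm, mm]
        ds.SliceThickness = mm
        ds.Rows, ds.Columns = data.shape[:2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(data[:, :, k]).tobytes()
        out = path / f"slice_{k:04d}.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def reorient(vol: CalibratedVolume, angle: float) -> CalibratedVolume:
    """Rotate the volume by ``angle`` degrees about the anteroposterior axis.

    Trilinear interpolation within each transverse slice; out-of-bounds
    voxels fill with 0. ``angle=0`` is the identity.
    """
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    if angle % 360.0 == 0.0:
        return CalibratedVolume(
            vol.intensities.copy(), vol.voxel_size, vol.calibration, vol.axis_labels
        )
    in_plane = tuple(i for i in range(3) if i != vol.ap_axis)
    rotated = ndimage.rotate(
        vol.intensities.astype(float),
        angle,
        axes=in_plane,
        reshape=False,
        order=1,
        mode="constant",
        cval=0.0,
    )
    rotated = np.clip(np.round(rotated), 0, None).astype(vol.intensities.dtype)
    return CalibratedVolume(rotated, vol.voxel_size, vol.calibration, vol.axis_labels)


def project(vol: CalibratedVolume, mode: str = "max", axis: int = 0) -> np.ndarray:
    """Maximum- or mean-intensity projection along one grid axis."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if mode == "max":
        return vol.intensities.max(axis=axis)
    if mode == "mean":
        return vol.intensities.mean(axis=axis)
    raise ValueError(f"unknown projection mode {mode!r}; use 'max' or 'mean'")
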