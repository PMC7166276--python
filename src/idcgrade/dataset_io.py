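"""Cohort manifests, grayscale slice I/O and lesion-ROI extraction.

An *image raster* is simply a 2-D ``float64`` :class:`numpy.ndarray` of
finite intensities; every pipeline stage consumes and produces that type.
A cohort is described by a CSV manifest with one row per patient::

    patient_id,slice1,slice2,slice3,roi1_row,roi1_col,roi2_row,roi2_col,roi3_row,roi3_col,grade

where each slice has a region of interest (ROI) given by the 0-based
(row, col) of its top-left corner; the ROI is a fixed square window
(60 px by default, the lesion window used throughout the pipeline) and
``grade`` is the histological grade, ``II`` or ``III``.

Coordinates are 0-based with the origin at the top-left of the image.
ROI windows must lie fully inside the image: out-of-bounds windows raise
instead of being clipped or padded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ImageFormatError, ManifestError, ValidationError

GRADES = ("II", "III")
#: Positive class for all confusion-matrix bookkeeping.
POSITIVE_GRADE = "III"

DEFAULT_ROI_SIDE = 60
#: Smallest ROI that still supports a 2-level dyadic decomposition with margin.
MIN_ROI_SIDE = 8

MANIFEST_COLUMNS = (
    "patient_id",
    "slice1", "slice2", "slice3",
    "roi1_row", "roi1_col",
    "roi2_row", "roi2_col",
    "roi3_row", "roi3_col",
    "grade",
)

# PIL modes accepted as single-channel grayscale.
_GRAY_MODES = {"L", "I", "I;16", "I;16B", "I;16L", "F", "1"}


@dataclass(frozen=True)
class RoiSpec:
    """Square lesion window: top-left corner plus side length in pixels."""

    row0: int
    col0: int
    side: int = DEFAULT_ROI_SIDE

    def __post_init__(self):
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError(
                f"ROI corner must be non-negative, got ({self.row0}, {self.col0})"
            )
        if self.side < MIN_ROI_SIDE:
            raise ValidationError(
                f"ROI side must be >= {MIN_ROI_SIDE}, got {self.side}"
            )

    @classmethod
    def from_center(cls, row: int, col: int, side: int = DEFAULT_ROI_SIDE) -> "RoiSpec":
        """Build a spec from the lesion-center pixel instead of the corner."""
        return cls(int(row) - side // 2, int(col) - side // 2, side)

    def validate_against(self, image: np.ndarray) -> None:
        h, w = image.shape
        if self.row0 + self.side > h or self.col0 + self.side > w:
            raise ValidationError(
                f"ROI ({self.row0}, {self.col0}, side={self.side}) exceeds "
                f"image bounds {h}x{w}"
            )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    slice_paths: tuple[str, str, str]
    roi_specs: tuple[RoiSpec, RoiSpec, RoiSpec]
    grade: str

    def __post_init__(self):
        if len(self.slice_paths) != 3 or len(self.roi_specs) != 3:
            raise ManifestError(
                f"patient {self.patient_id!r}: exactly 3 slices/ROIs required"
            )
        if self.grade not in GRADES:
            raise ManifestError(
                f"patient {self.patient_id!r}: grade must be one of {GRADES}, "
                f"got {self.grade!r}"
            )


@dataclass
class CohortManifest:
    """Validated list of patient records with unique IDs."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate patient ids: {dupes}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def grades(self) -> list[str]:
        return [r.grade for r in self.records]


def load_manifest(path, roi_side: int = DEFAULT_ROI_SIDE) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Rows with a grade outside ``{"II", "III"}`` or malformed coordinates
    raise :class:`ManifestError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                rois = tuple(
                    RoiSpec(int(row[f"roi{s}_row"]), int(row[f"roi{s}_col"]), roi_side)
                    for s in (1, 2, 3)
                )
                rec = PatientRecord(
                    patient_id=row["patient_id"],
                    slice_paths=(row["slice1"], row["slice2"], row["slice3"]),
                    roi_specs=rois,
                    grade=row["grade"],
                )
            except (ManifestError, ValidationError, ValueError) as exc:
                raise ManifestError(f"manifest row {i}: {exc}") from exc
            records.append(rec)
    return CohortManifest(records)


def save_manifest(manifest: CohortManifest, path) -> None:
    """Write a manifest in the canonical CSV layout (round-trips with load)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in manifest:
            row = [r.patient_id, *r.slice_paths]
            for spec in r.roi_specs:
                row += [spec.row0, spec.col0]
            row.append(r.grade)
            writer.writerow(row)


def load_image(path) -> np.ndarray:
    """Read a grayscale slice (PNG/TIFF; single-slice DICOM or NIfTI) as float64.

    Intensities are returned exactly as stored, without rescaling.
    Multi-channel (color) inputs are rejected rather than averaged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".dcm":
        pixels = _load_dicom(path)
    elif suffix in (".nii", ".gz"):
        pixels = _load_nifti(path)
    else:
        with Image.open(path) as img:
            if img.mode not in _GRAY_MODES:
                raise ImageFormatError(
                    f"{path}: mode {img.mode!r} is not single-channel grayscale"
                )
            pixels = np.asarray(img, dtype=np.float64)
    if pixels.ndim != 2:
        raise ImageFormatError(f"{path}: expected a 2-D slice, got shape {pixels.shape}")
    if not np.all(np.isfinite(pixels)):
        raise ImageFormatError(f"{path}: non-finite pixel values")
    return pixels


def _load_dicom(path):
    import pydicom

    ds = pydicom.dcmread(path)
    arr = np.asarray(ds.pixel_array, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: DICOM is not a single 2-D slice")
    return arr


def _load_nifti(path):
    import nibabel as nib

    arr = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: NIfTI is not a single 2-D slice")
    return arr


def save_image(pixels: np.ndarray, path) -> None:
    """Write an integer-valued raster losslessly as 8- or 16-bit PNG/TIFF."""
    pixels = np.asarray(pixels)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if np.any(pixels < 0) or np.any(pixels > 65535):
        raise ValidationError("save_image expects values in [0, 65535]")
    if np.any(pixels != np.round(pixels)):
        raise ValidationError("save_image expects integer-valued rasters")
    if pixels.max(initial=0) <= 255:
        Image.fromarray(pixels.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(pixels.astype(np.uint16)).save(path)


def extract_roi(image: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Crop the lesion window; a pure copy, never clipped or padded."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError(f"expected a 2-D raster, got shape {image.shape}")
    roi.validate_against(image)
    return image[roi.row0:roi.row0 + roi.side, roi.col0:roi.col0 + roi.side].copy()
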