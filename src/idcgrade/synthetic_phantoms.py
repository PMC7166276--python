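"""Seeded cohorts of textured tumor phantoms with ground-truth masks.

Each phantom slice emulates the structure of a contrast-enhanced breast
MR slice: a 352x352 background at a low base level, one bright disk (the
enhancing lesion) and additive Gaussian noise. The two histological
grades are distinguished by an oriented sinusoidal texture added inside
the disk, ``amplitude * cos(2 pi x' / lambda_t)`` with
``x' = x cos(theta_t) + y sin(theta_t)``: grade II carries theta_t = 45
degrees and grade III theta_t = 90 degrees at a common wavelength. An
oriented sinusoid (rather than a random field) makes the ground-truth
discriminative (wavelength, orientation) known exactly, so feature
ranking can be validated sharply.

The background additionally carries a smooth sinusoidal intensity
modulation (a coil-inhomogeneity-like bias field), so surrounding tissue
is not a single flat level — without it, unsupervised clustering has no
background structure to spend clusters on. Default intensities put the
lesion-background contrast well above the texture modulation, which in
turn is below the noise floor pixelwise (the oriented texture is only
detectable by matched filtering over the lesion region). Slices are
quantized to 16-bit PNG at ``QUANT_SCALE`` counts per unit intensity;
every pixel is fully determined by the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dataset_io as io
from .exceptions import ValidationError
from .wavelet_segmentation import TumorMask

QUANT_SCALE = 40000.0

#: Grade -> texture orientation (degrees).
GRADE_ORIENTATIONS = {"II": 45.0, "III": 90.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and texture settings for one cohort."""

    image_side: int = 352
    roi_side: int = 60
    blob_radius_range: tuple = (18.0, 26.0)
    background_level: float = 0.2
    tumor_level: float = 0.6
    texture_wavelength: float = 4.0
    texture_orientations: dict = field(default_factory=lambda: dict(GRADE_ORIENTATIONS))
    texture_amplitude: float = 0.03
    noise_sd: float = 0.04
    bias_amplitude: float = 0.08
    bias_period: float = 90.0
    n_slices: int = 3

    def __post_init__(self):
        if self.tumor_level <= self.background_level:
            raise ValidationError("tumor_level must exceed background_level")
        if self.texture_amplitude < 0:
            raise ValidationError("texture_amplitude must be >= 0")
        rmin, rmax = self.blob_radius_range
        if not 0 < rmin <= rmax:
            raise ValidationError("blob radius range must be 0 < rmin <= rmax")
        if 2 * rmax >= self.roi_side:
            raise ValidationError("blob must fit inside the ROI window")
        if self.roi_side > self.image_side:
            raise ValidationError("ROI cannot exceed the image")


@dataclass
class GroundTruth:
    """Per-patient truth: ROI-frame masks, grade, injected texture."""

    patient_id: str
    grade: str
    masks: list          # TumorMask per slice, on the ROI grid
    wavelength: float
    orientation_deg: float


def _render_slice(spec: PhantomSpec, grade: str, rng: np.random.Generator):
    side = spec.image_side
    r = rng.uniform(*spec.blob_radius_range)
    margin = spec.roi_side // 2 + 2
    cy = rng.integers(margin, side - margin)
    cx = rng.integers(margin, side - margin)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    theta = math.radians(spec.texture_orientations[grade])
    xp = xx * math.cos(theta) + yy * math.sin(theta)
    texture = spec.texture_amplitude * np.cos(2.0 * math.pi * xp / spec.texture_wavelength)
    # Smooth background modulation (bias-field-like), random direction/phase.
    bias_dir = rng.uniform(0.0, math.pi)
    bias_phase = rng.uniform(0.0, 2.0 * math.pi)
    bp = xx * math.cos(bias_dir) + yy * math.sin(bias_dir)
    bias = spec.bias_amplitude * np.sin(2.0 * math.pi * bp / spec.bias_period + bias_phase)
    image = spec.background_level + bias
    image[disk] = spec.tumor_level + texture[disk]
    image += spec.noise_sd * rng.standard_normal((side, side))
    roi = io.RoiSpec.from_center(int(cy), int(cx), spec.roi_side)
    roi_mask = disk[roi.row0:roi.row0 + roi.side, roi.col0:roi.col0 + roi.side]
    return image, roi, TumorMask(roi_mask), r


def quantize(image: np.ndarray) -> np.ndarray:
    """Map unit-scale intensities onto the stored 16-bit integer grid."""
    return np.clip(np.round(image * QUANT_SCALE), 0, 65535)


def make_patient(spec: PhantomSpec, grade: str, seed: int):
    """Render one patient: 3 slices, their ROI windows and ground truth.

    Slices are returned on the quantized (stored) intensity scale so the
    in-memory pipeline sees exactly what a reload from disk would.
    """
    if grade not in spec.texture_orientations:
        raise ValidationError(f"grade {grade!r} has no texture orientation")
    rng = np.random.default_rng(seed)
    slices, rois, masks, radii = [], [], [], []
    for _ in range(spec.n_slices):
        image, roi, mask, r = _render_slice(spec, grade, rng)
        slices.append(quantize(image))
        rois.append(roi)
        masks.append(mask)
        radii.append(r)
    truth = GroundTruth(
        patient_id="",
        grade=grade,
        masks=masks,
        wavelength=spec.texture_wavelength,
        orientation_deg=spec.texture_orientations[grade],
    )
    return slices, rois, truth


def make_cohort(spec: PhantomSpec, n_per_class: int, seed: int, out_dir):
    """Write a balanced cohort (images + manifest) in the dataset layout.

    Returns ``(manifest, ground_truths)``. Per-patient seeds derive
    deterministically from the master seed, so cohorts are reproducible
    and different masters give different pixel content.
    """
    if n_per_class < 2:
        raise ValidationError(f"need at least 2 patients per class, got {n_per_class}")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(seed)
    patient_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(2 * n_per_class)]
    records, truths = [], []
    idx = 0
    for grade in io.GRADES:
        for i in range(n_per_class):
            pid = f"P{idx + 1:03d}"
            slices, rois, truth = make_patient(spec, grade, patient_seeds[idx])
            truth.patient_id = pid
            paths = []
            for s, image in enumerate(slices, start=1):
                rel = f"images/{pid}_s{s}.png"
                io.save_image(image, out_dir / rel)
                paths.append(rel)
            records.append(
                io.PatientRecord(
                    patient_id=pid,
                    slice_paths=tuple(str(out_dir / p) for p in paths),
                    roi_specs=tuple(rois),
                    grade=grade,
                )
            )
            truths.append(truth)
            idx += 1
    manifest = io.CohortManifest(records)
    io.save_manifest(manifest, out_dir / "manifest.csv")
    _write_truth_json(truths, out_dir / "ground_truth.json")
    return manifest, truths


def _write_truth_json(truths, path):
    payload = [
        {
            "patient_id": t.patient_id,
            "grade": t.grade,
            "wavelength": t.wavelength,
            "orientation_deg": t.orientation_deg,
            "mask_pixels": [m.n_pixels for m in t.masks],
        }
        for t in truths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def injected_feature_names(spec: PhantomSpec, bank, n_slices: int = 3) -> list[str]:
    """Names of the bank features carrying the injected class contrast.

    These are the features at the texture wavelength and at the two
    class orientations, across all slices — the ground-truth
    discriminative set the ranking should surface.
    """
    names = []
    for s in range(1, n_slices + 1):
        for deg in spec.texture_orientations.values():
            j = bank.index_of(spec.texture_wavelength, deg)
            names.append(f"f_s{s}_{bank.kernel_label(j)}")
    return names
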