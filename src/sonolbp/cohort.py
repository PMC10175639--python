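"""Synthetic cohort generator.

The study cohort (52 patients with non-specific low back pain, split into a
mild group, VAS <= 3, n=24, and a moderate-severe group, VAS > 3, n=28) is
not publicly available.  This module generates synthetic cohorts with the
same acquisition layout — 14 B-mode ROI images per subject plus a shear-wave
elastography (SWE) mean/std pair per ROI and two muscle thicknesses — and
*controllable* class effects, so that every downstream stage is testable:

* B-mode speckle: each ROI image is a smooth anisotropic background
  (Gaussian-smoothed white noise, with separate axial and lateral
  correlation lengths) modulated by unit-mean gamma-distributed multiplicative
  speckle, log-compressed and affinely quantized to 8 bits.  The
  moderate-severe class stretches the correlation lengths and lowers the
  gamma shape by a factor ``1 + texture_effect``.
* SWE elasticity: the per-ROI SWE mean is log-normal with expectation 20 kPa
  for the mild class, shifted up by ``swe_effect`` kPa for moderate-severe.
* Thickness: log-normal around physiologic means, shifted by
  ``thickness_effect`` mm in the moderate-severe class (default 0).

With all three effects at zero, the imaging channels of the two classes are
exchangeable in distribution, so the full pipeline must perform at chance.
Demographics are sampled near the published group moments but are carried as
metadata only — they are never features.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .protocol import PROTOCOL_KEYS, ProtocolError, ROIKey

MILD = "mild"
MODERATE_SEVERE = "moderate_severe"
GROUPS = (MILD, MODERATE_SEVERE)

#: VAS threshold separating mild from moderate-severe pain.
VAS_THRESHOLD = 3.0

MIN_ROI_SIZE = 32

# Demographic sampling moments per group: (mean, std) and truncation bounds.
_DEMOGRAPHICS = {
    MILD: {"weight_kg": (65.52, 11.52), "height_m": (1.69, 0.10), "age_years": (35.96, 7.62)},
    MODERATE_SEVERE: {"weight_kg": (64.38, 10.82), "height_m": (1.69, 0.07), "age_years": (41.11, 10.24)},
}
_BOUNDS = {"weight_kg": (35.0, 130.0), "height_m": (1.40, 2.10), "age_years": (18.0, 85.0)}
_MALE_FRACTION = {MILD: 12 / 24, MODERATE_SEVERE: 15 / 28}

# Baseline speckle texture parameters (pixels / dimensionless).
_AXIAL_CORR = 1.5
_LATERAL_CORR = 3.0
_GAMMA_SHAPE = 4.0
_LOG_GAIN = 40.0  # log-compression gain before 8-bit quantization

# Baseline tissue parameters (kPa / mm).
_SWE_MEAN_MILD_KPA = 20.0
_SWE_SIGMA_LOG = 0.2
_SWE_STD_FRACTION = 0.15
_THICKNESS_MM = {"TLF": 1.8, "TrA": 3.5}
_THICKNESS_SIGMA_LOG = 0.15


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    sex: str
    weight_kg: float
    height_m: float
    bmi: float
    age_years: float
    vas: float
    group: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.vas <= 10.0):
            raise ValueError(f"VAS {self.vas} outside [0, 10]")
        expected = MILD if self.vas <= VAS_THRESHOLD else MODERATE_SEVERE
        if self.group != expected:
            raise ValueError(f"group {self.group!r} inconsistent with VAS {self.vas}")
        if abs(self.bmi - self.weight_kg / self.height_m**2) > 1e-9:
            raise ValueError("bmi inconsistent with weight/height")


@dataclass(frozen=True)
class ROISample:
    """One imaged region: 8-bit B-mode patch plus its SWE elasticity summary."""

    key: ROIKey
    image: np.ndarray
    swe_mean_kpa: float
    swe_std_kpa: float

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2 or min(img.shape) < MIN_ROI_SIZE:
            raise ProtocolError(f"ROI image must be 2-D, at least {MIN_ROI_SIZE}x{MIN_ROI_SIZE}")
        if img.dtype != np.uint8:
            raise ProtocolError("ROI image must be 8-bit (uint8)")
        if self.swe_mean_kpa <= 0 or self.swe_std_kpa < 0:
            raise ValueError("SWE mean must be positive, std non-negative")


@dataclass(frozen=True)
class AcquisitionRecord:
    """One subject's full acquisition: 14 ROIs, 2 thicknesses, metadata."""

    meta: SubjectMeta
    rois: dict[ROIKey, ROISample]
    tlf_thickness_mm: float
    tra_thickness_mm: float

    def __post_init__(self) -> None:
        expected = set(PROTOCOL_KEYS)
        got = set(self.rois)
        if got != expected:
            missing = sorted(k.site_label() for k in expected - got)
            extra = sorted(k.site_label() for k in got - expected)
            raise ProtocolError(
                f"record must hold exactly the 14 protocol ROIs; "
                f"missing={missing}, unexpected={extra}"
            )
        if self.tlf_thickness_mm <= 0 or self.tra_thickness_mm <= 0:
            raise ValueError("thicknesses must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the published cohort structure (24 mild + 28
    moderate-severe subjects) with a 6 kPa elasticity shift and a 30%
    texture-correlation shift in the moderate-severe class.
    """

    n_mild: int = 24
    n_moderate_severe: int = 28
    seed: int = 0
    roi_size: tuple[int, int] = (64, 64)
    texture_effect: float = 0.3
    swe_effect: float = 6.0
    thickness_effect: float = 0.0
    noise_scale: float = 0.5

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        problems = []
        if self.n_mild <= 0 or self.n_moderate_severe <= 0:
            problems.append("CohortConfig.n_mild/n_moderate_severe: must be positive")
        if min(self.n_mild, self.n_moderate_severe) < 5:
            problems.append(
                "CohortConfig CV feasibility: each class needs >= 5 subjects so "
                "every stratified 5-fold split contains both classes"
            )
        if min(self.roi_size) < MIN_ROI_SIZE:
            problems.append(
                f"CohortConfig.roi_size: minimum is {MIN_ROI_SIZE}x{MIN_ROI_SIZE} pixels"
            )
        if self.texture_effect < 0 or self.swe_effect < 0:
            problems.append("CohortConfig.texture_effect/swe_effect: must be >= 0")
        if self.noise_scale <= 0:
            problems.append("CohortConfig.noise_scale: must be positive")
        return problems


def _check(config: CohortConfig) -> None:
    problems = config.validate()
    if problems:
        raise ProtocolError("; ".join(problems))


def generate_roi_image(
    key: ROIKey, class_label: str, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one 8-bit B-mode speckle patch.

    Deterministic given the generator state; with ``texture_effect == 0`` the
    two classes draw identical images from identical states.
    """
    if min(config.roi_size) < MIN_ROI_SIZE:
        raise ProtocolError(f"roi_size must be at least {MIN_ROI_SIZE}x{MIN_ROI_SIZE}")
    if class_label not in GROUPS:
        raise ValueError(f"unknown class label {class_label!r}")
    h, w = config.roi_size
    stretch = 1.0 + (config.texture_effect if class_label == MODERATE_SEVERE else 0.0)

    base = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(base, sigma=(_AXIAL_CORR * stretch, _LATERAL_CORR * stretch))
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    background = np.exp(config.noise_scale * smooth)

    shape = _GAMMA_SHAPE / stretch
    speckle = rng.gamma(shape, 1.0 / shape, size=(h, w))

    envelope = background * speckle
    compressed = np.log1p(_LOG_GAIN * envelope) / np.log1p(_LOG_GAIN * 12.0)
    return (np.clip(compressed, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _truncated_normal(rng: np.random.Generator, mean: float, std: float, lo: float, hi: float) -> float:
    for _ in range(64):
        x = rng.normal(mean, std)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _lognormal_with_mean(rng: np.random.Generator, mean: float, sigma: float) -> float:
    # E[lognormal(mu, sigma)] = exp(mu + sigma^2/2)
    mu = np.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def generate_subject(
    class_label: str, config: CohortConfig, rng: np.random.Generator, subject_id: str = "S000"
) -> AcquisitionRecord:
    """Sample one subject: demographics near the published group moments,
    VAS uniform on the class interval, 14 protocol ROIs, class-shifted SWE
    and thickness values."""
    _check(config)
    if class_label not in GROUPS:
        raise ValueError(f"unknown class label {class_label!r}")
    moments = _DEMOGRAPHICS[class_label]

    sex = "M" if rng.random() < _MALE_FRACTION[class_label] else "F"
    weight = _truncated_normal(rng, *moments["weight_kg"], *_BOUNDS["weight_kg"])
    height = _truncated_normal(rng, *moments["height_m"], *_BOUNDS["height_m"])
    age = _truncated_normal(rng, *moments["age_years"], *_BOUNDS["age_years"])
    if class_label == MILD:
        vas = float(rng.uniform(1.0, 3.0))
    else:
        vas = float(rng.uniform(3.0, 8.0))
        vas = np.nextafter(3.0, 8.0) if vas <= 3.0 else vas
    meta = SubjectMeta(
        subject_id=subject_id, sex=sex, weight_kg=weight, height_m=height,
        bmi=weight / height**2, age_years=age, vas=vas, group=class_label,
    )

    swe_shift = config.swe_effect if class_label == MODERATE_SEVERE else 0.0
    rois: dict[ROIKey, ROISample] = {}
    for key in PROTOCOL_KEYS:
        image = generate_roi_image(key, class_label, config, rng)
        swe_mean = _lognormal_with_mean(rng, _SWE_MEAN_MILD_KPA + swe_shift, _SWE_SIGMA_LOG)
        swe_std = _lognormal_with_mean(rng, _SWE_STD_FRACTION * swe_mean, _SWE_SIGMA_LOG)
        rois[key] = ROISample(key=key, image=image, swe_mean_kpa=swe_mean, swe_std_kpa=swe_std)

    thick_shift = config.thickness_effect if class_label == MODERATE_SEVERE else 0.0
    tlf = _lognormal_with_mean(rng, max(_THICKNESS_MM["TLF"] + thick_shift, 0.1), _THICKNESS_SIGMA_LOG)
    tra = _lognormal_with_mean(rng, max(_THICKNESS_MM["TrA"] + thick_shift, 0.1), _THICKNESS_SIGMA_LOG)

    return AcquisitionRecord(meta=meta, rois=rois, tlf_thickness_mm=tlf, tra_thickness_mm=tra)


def generate_cohort(config: CohortConfig) -> list[AcquisitionRecord]:
    """Generate ``n_mild + n_moderate_severe`` subjects, reproducibly from
    ``config.seed`` (mild subjects first)."""
    _check(config)
    rng = np.random.default_rng(config.seed)
    records = []
    idx = 0
    for class_label, n in ((MILD, config.n_mild), (MODERATE_SEVERE, config.n_moderate_severe)):
        for _ in range(n):
            records.append(generate_subject(class_label, config, rng, subject_id=f"S{idx:03d}"))
            idx += 1
    return records


# ---------------------------------------------------------------------------
# On-disk form: one PNG per ROI + a cohort manifest CSV.

def _roi_filename(subject_id: str, key: ROIKey) -> str:
    return f"{subject_id}_{key.level}_{key.side}_{key.muscle}_{key.position}.png"


def _swe_column(key: ROIKey, which: str) -> str:
    return f"swe_{which}::{key.site_label()}"


_META_COLUMNS = ("subject_id", "sex", "weight_kg", "height_m", "bmi", "age_years", "vas", "group")


def write_cohort(records: list[AcquisitionRecord], out_dir: str | Path) -> Path:
    """Write ROI PNGs and the manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    columns = list(_META_COLUMNS) + ["tlf_thickness_mm", "tra_thickness_mm"]
    for key in PROTOCOL_KEYS:
        columns += [_swe_column(key, "mean"), _swe_column(key, "std")]
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for rec in records:
            row = {c: getattr(rec.meta, c) for c in _META_COLUMNS}
            row["tlf_thickness_mm"] = rec.tlf_thickness_mm
            row["tra_thickness_mm"] = rec.tra_thickness_mm
            for key, roi in rec.rois.items():
                row[_swe_column(key, "mean")] = roi.swe_mean_kpa
                row[_swe_column(key, "std")] = roi.swe_std_kpa
                iio.imwrite(img_dir / _roi_filename(rec.meta.subject_id, key), roi.image)
            writer.writerow(row)
    return manifest


def read_cohort(manifest_path: str | Path, images_dir: str | Path | None = None) -> list[AcquisitionRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    img_dir = Path(images_dir) if images_dir is not None else manifest_path.parent / "images"
    records = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            meta = SubjectMeta(
                subject_id=row["subject_id"], sex=row["sex"],
                weight_kg=float(row["weight_kg"]), height_m=float(row["height_m"]),
                bmi=float(row["bmi"]), age_years=float(row["age_years"]),
                vas=float(row["vas"]), group=row["group"],
            )
            rois = {}
            for key in PROTOCOL_KEYS:
                image = iio.imread(img_dir / _roi_filename(meta.subject_id, key))
                rois[key] = ROISample(
                    key=key, image=np.asarray(image, dtype=np.uint8),
                    swe_mean_kpa=float(row[_swe_column(key, "mean")]),
                    swe_std_kpa=float(row[_swe_column(key, "std")]),
                )
            records.append(AcquisitionRecord(
                meta=meta, rois=rois,
                tlf_thickness_mm=float(row["tlf_thickness_mm"]),
                tra_thickness_mm=float(row["tra_thickness_mm"]),
            ))
    return records


def cohort_config_from_dict(d: dict) -> CohortConfig:
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise ProtocolError(f"unknown CohortConfig fields: {sorted(unknown)}")
    if "roi_size" in d:
        d = {**d, "roi_size": tuple(d["roi_size"])}
    return CohortConfig(**d)
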