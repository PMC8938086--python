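"""Synthetic inputs for the whole pipeline.

Four generators, each deterministic under its config seed:

* speckle- and impulse-corrupted grayscale phantoms with exact ground-truth
  lesion masks;
* multi-annotator mask sets with boundary jitter and optional gross
  outliers;
* a multimodal patient cohort (100 patients in four arms of 25, an expected
  152 lesions split 110 malignant : 42 benign, malignant grades in
  expectation 49 poorly / 40 moderately / 21 highly differentiated) whose
  per-grade imaging-feature probabilities default to the study's observed
  frequencies;
* immunohistochemistry cohorts (79 lesional / 79 perilesional / 39 normal
  specimens) with configurable per-group and per-grade positivity
  probabilities for EZH2 and p57.

Speckle is modelled as mean-1 multiplicative log-normal noise and the
long-tail component as salt-and-pepper impulses with equal salt/pepper
probability; neither attempts physical B-mode acoustics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .modality import LesionFindings

__all__ = [
    "PhantomConfig",
    "AnnotatorConfig",
    "CohortConfig",
    "IHCCohortConfig",
    "LesionRecord",
    "PatientRecord",
    "generate_phantom",
    "simulate_annotators",
    "generate_cohort",
    "cohort_to_frame",
    "generate_ihc_cohort",
    "generate_graded_specimens",
    "DEFAULT_FEATURE_PROBABILITIES",
    "DEFAULT_GROUP_POSITIVITY",
    "DEFAULT_GRADE_POSITIVITY",
]


def _child_seed(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-stream generator so sub-steps can re-run independently."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# --------------------------------------------------------------------------
# Phantoms


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 64
    width: int = 64
    lesion_shape: str = "ellipse"  # or "irregular-blob"
    center: tuple[float, float] | None = None  # defaults to image centre
    axes: tuple[float, float] = (18.0, 12.0)
    boundary_perturbation: float = 0.0  # radial amplitude, px (irregular blob)
    background_level: int = 40
    lesion_level: int = 160
    speckle_scale: float = 0.0  # sigma of the log-normal multiplier
    impulse_density: float = 0.0  # fraction of pixels hit by salt/pepper
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8")
        if not 0.0 <= self.impulse_density <= 1.0:
            raise ValueError("impulse_density must be in [0, 1]")
        for level in (self.background_level, self.lesion_level):
            if not 0 <= level <= 255:
                raise ValueError("intensity levels must be in [0, 255]")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        if self.lesion_shape not in ("ellipse", "irregular-blob"):
            raise ValueError(f"unknown lesion shape {self.lesion_shape!r}")
        if min(self.axes) <= 0:
            raise ValueError("lesion axes must be positive")


def _lesion_mask(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    cy, cx = config.center if config.center is not None else ((h - 1) / 2, (w - 1) / 2)
    ay, ax = config.axes
    mask = np.zeros((h, w), dtype=np.uint8)
    if config.lesion_shape == "ellipse" or config.boundary_perturbation == 0:
        rr, cc = skdraw.ellipse(cy, cx, ay, ax, shape=(h, w))
        mask[rr, cc] = 1
    else:
        # Radial perturbation of the ellipse boundary by a low-order random
        # harmonic series: an "irregular blob" with a controlled amplitude.
        yy, xx = np.mgrid[0:h, 0:w]
        theta = np.arctan2(yy - cy, xx - cx)
        base = (ay * ax) / np.sqrt((ax * np.sin(theta)) ** 2 + (ay * np.cos(theta)) ** 2)
        wobble = np.zeros_like(theta)
        for harmonic in range(2, 6):
            amp = rng.normal(0.0, config.boundary_perturbation / 2)
            phase = rng.uniform(0, 2 * np.pi)
            wobble += amp * np.cos(harmonic * theta + phase)
        radius = np.hypot(yy - cy, xx - cx)
        mask[radius <= base + wobble] = 1
    if mask.sum() == 0:
        raise ValueError("degenerate lesion geometry: zero-area mask")
    return mask


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Two-level phantom corrupted by speckle then impulse noise.

    Returns ``(image, mask)``: an 8-bit grayscale image and the exact
    pre-noise binary lesion mask ({0,1}).
    """
    rng = np.random.default_rng(config.seed)
    mask = _lesion_mask(config, rng)
    clean = np.where(mask > 0, config.lesion_level, config.background_level).astype(np.float64)
    noisy = clean
    if config.speckle_scale > 0:
        sigma = config.speckle_scale
        # mean-1 multiplicative log-normal field
        multiplier = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.shape)
        noisy = clean * multiplier
    noisy = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    if config.impulse_density > 0:
        n_pixels = noisy.size
        n_hit = int(round(config.impulse_density * n_pixels))
        flat_idx = rng.choice(n_pixels, size=n_hit, replace=False)
        salt = rng.random(n_hit) < 0.5
        flat = noisy.reshape(-1)
        flat[flat_idx[salt]] = 255
        flat[flat_idx[~salt]] = 0
    return noisy, mask


# --------------------------------------------------------------------------
# Annotators


@dataclass(frozen=True)
class AnnotatorConfig:
    k: int = 3
    boundary_jitter: float = 1.0  # px-scale perturbation magnitude
    outlier_rate: float = 0.0  # probability an annotator is grossly discordant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 annotators")
        if self.boundary_jitter < 0:
            raise ValueError("jitter must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")


def _perturb_mask(mask: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    j = max(1, int(round(jitter)))
    for _ in range(64):  # redraw until the perturbation is not the identity
        shift = rng.integers(-j, j + 1, size=2)
        grow = int(rng.integers(-max(1, j // 2), max(1, j // 2) + 1))
        if shift.any() or grow != 0:
            break
    out = np.roll(mask, shift, axis=(0, 1)) > 0
    structure = ndimage.generate_binary_structure(2, 2)
    if grow > 0:
        out = ndimage.binary_dilation(out, structure, iterations=grow)
    elif grow < 0:
        eroded = ndimage.binary_erosion(out, structure, iterations=-grow)
        if eroded.any():
            out = eroded
    return out.astype(np.uint8)


def simulate_annotators(mask: np.ndarray, config: AnnotatorConfig) -> list[np.ndarray]:
    """k annotator masks: jittered copies of the input plus optional outliers.

    With ``boundary_jitter=0`` and ``outlier_rate=0`` every copy equals the
    input. An outlier annotator's mask is the lesion displaced by roughly
    half the image, i.e. grossly discordant with the rest.
    """
    base = (np.asarray(mask) > 0).astype(np.uint8)
    if base.sum() == 0:
        raise ValueError("input mask is empty")
    rng = np.random.default_rng(config.seed)
    out: list[np.ndarray] = []
    for _ in range(config.k):
        if rng.random() < config.outlier_rate:
            shift = (base.shape[0] // 2, base.shape[1] // 2)
            out.append(np.roll(base, shift, axis=(0, 1)))
        elif config.boundary_jitter > 0:
            out.append(_perturb_mask(base, config.boundary_jitter, rng))
        else:
            out.append(base.copy())
    return out


# --------------------------------------------------------------------------
# Multimodal cohort

# Per-grade probabilities of the malignant-typical category of each feature,
# as observed in the study arm with all three modalities. Benign-lesion
# probabilities are not reported anywhere and default to a mild complement
# pattern (mostly regular/clear/homogeneous, low flow, soft, no washout).
DEFAULT_FEATURE_PROBABILITIES: dict[str, dict[str, float]] = {
    "poor": {
        "irregular_shape": 0.7959,
        "unclear_boundary": 0.7551,
        "inhomogeneous_echo": 0.9388,
        "posterior_unchanged_or_enhanced": 0.898,
        "flow_grade_2_3": 0.9592,
        "elasticity_4_5": 0.898,
        "ceus_fffo": 0.8367,
    },
    "moderate": {
        "irregular_shape": 0.70,
        "unclear_boundary": 0.70,
        "inhomogeneous_echo": 0.725,
        "posterior_unchanged_or_enhanced": 0.725,
        "flow_grade_2_3": 0.90,
        "elasticity_4_5": 0.40,
        "ceus_fffo": 0.80,
    },
    "high": {
        "irregular_shape": 0.3333,
        "unclear_boundary": 0.3333,
        "inhomogeneous_echo": 0.3333,
        "posterior_unchanged_or_enhanced": 0.50,
        "flow_grade_2_3": 0.6667,
        "elasticity_4_5": 0.50,
        "ceus_fffo": 0.5714,
    },
    "benign": {
        "irregular_shape": 0.20,
        "unclear_boundary": 0.20,
        "inhomogeneous_echo": 0.20,
        "posterior_unchanged_or_enhanced": 0.50,
        "flow_grade_2_3": 0.10,
        "elasticity_4_5": 0.15,
        "ceus_fffo": 0.10,
    },
}

GROUPS = ("doppler", "contrast", "elastic", "multimodal")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    group_sizes: tuple[int, ...] = (25, 25, 25, 25)
    p_single_lesion: float = 0.74
    multiple_lesion_counts: tuple[int, ...] = (2, 3, 4)  # uniform; mean 3
    malignancy_prevalence: float = 110 / 152
    grade_probabilities: tuple[float, float, float] = (49 / 110, 40 / 110, 21 / 110)
    feature_probabilities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_FEATURE_PROBABILITIES
    )
    diameter_range_cm: tuple[float, float] = (0.8, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_patients:
            raise ValueError("group sizes must sum to n_patients")
        if not 0.0 <= self.p_single_lesion <= 1.0:
            raise ValueError("p_single_lesion must be in [0, 1]")
        if not 0.0 <= self.malignancy_prevalence <= 1.0:
            raise ValueError("malignancy_prevalence must be in [0, 1]")
        if abs(sum(self.grade_probabilities) - 1.0) > 1e-9:
            raise ValueError("grade probabilities must sum to 1")
        for grade, probs in self.feature_probabilities.items():
            for name, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {grade}/{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    pathology: str  # benign | malignant
    grade: str | None  # poor | moderate | high; None for benign
    diameter_cm: float
    findings: LesionFindings


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    group: str
    lesions: tuple[LesionRecord, ...]


def _sample_findings(
    grade_key: str,
    probs: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> LesionFindings:
    p = probs[grade_key]
    irregular = rng.random() < p["irregular_shape"]
    unclear = rng.random() < p["unclear_boundary"]
    inhomog = rng.random() < p["inhomogeneous_echo"]
    posterior = rng.random() < p["posterior_unchanged_or_enhanced"]
    high_flow = rng.random() < p["flow_grade_2_3"]
    flow = int(rng.integers(2, 4)) if high_flow else int(rng.integers(0, 2))
    stiff = rng.random() < p["elasticity_4_5"]
    elasticity = int(rng.integers(4, 6)) if stiff else int(rng.integers(1, 4))
    fffo = rng.random() < p["ceus_fffo"]
    if fffo:
        pattern, arterial, washout = "FFFO", "enhancement", "clearance"
    elif rng.random() < 0.5:
        pattern, arterial, washout = "FFNO", "enhancement", "no_clearance"
    else:
        pattern, arterial, washout = "other", "non_enhancement", "no_clearance"
    return LesionFindings(
        shape="irregular" if irregular else "regular",
        boundary="unclear" if unclear else "clear",
        internal_echo="inhomogeneous" if inhomog else "homogeneous",
        posterior_echo="unchanged_or_enhanced" if posterior else "attenuated",
        flow_grade=flow,
        elasticity_score=elasticity,
        ceus_arterial=arterial,
        ceus_washout=washout,
        ceus_pattern=pattern,
    )


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Simulate the four-arm cohort of patients with one or more lesions each."""
    rng = _child_seed(config.seed, 0)
    group_labels = np.repeat(GROUPS[: len(config.group_sizes)], config.group_sizes)
    group_labels = rng.permutation(group_labels)
    grades = ("poor", "moderate", "high")
    patients: list[PatientRecord] = []
    for idx in range(config.n_patients):
        if rng.random() < config.p_single_lesion:
            n_lesions = 1
        else:
            n_lesions = int(rng.choice(config.multiple_lesion_counts))
        lesions = []
        for j in range(n_lesions):
            malignant = rng.random() < config.malignancy_prevalence
            if malignant:
                grade = grades[rng.choice(3, p=config.grade_probabilities)]
                findings = _sample_findings(grade, config.feature_probabilities, rng)
            else:
                grade = None
                findings = _sample_findings("benign", config.feature_probabilities, rng)
            lesions.append(
                LesionRecord(
                    lesion_id=f"P{idx:04d}L{j}",
                    pathology="malignant" if malignant else "benign",
                    grade=grade,
                    diameter_cm=float(rng.uniform(*config.diameter_range_cm)),
                    findings=findings,
                )
            )
        patients.append(
            PatientRecord(
                patient_id=f"P{idx:04d}",
                group=str(group_labels[idx]),
                lesions=tuple(lesions),
            )
        )
    return patients


COHORT_COLUMNS = [
    "patient_id",
    "group",
    "lesion_id",
    "pathology",
    "grade",
    "diameter_cm",
    "shape",
    "boundary",
    "internal_echo",
    "posterior_echo",
    "flow_grade",
    "elasticity_score",
    "ceus_arterial",
    "ceus_washout",
    "ceus_pattern",
]


def cohort_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records to one lesion per row (fixed column order)."""
    rows = []
    for patient in patients:
        for lesion in patient.lesions:
            f = lesion.findings
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "group": patient.group,
                    "lesion_id": lesion.lesion_id,
                    "pathology": lesion.pathology,
                    "grade": lesion.grade,
                    "diameter_cm": round(lesion.diameter_cm, 3),
                    "shape": f.shape,
                    "boundary": f.boundary,
                    "internal_echo": f.internal_echo,
                    "posterior_echo": f.posterior_echo,
                    "flow_grade": f.flow_grade,
                    "elasticity_score": f.elasticity_score,
                    "ceus_arterial": f.ceus_arterial,
                    "ceus_washout": f.ceus_washout,
                    "ceus_pattern": f.ceus_pattern,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# --------------------------------------------------------------------------
# IHC cohorts

# Group-level positivity defaults: EZH2 from the consistent printed counts
# (60/79, 12/79, 4/39); p57 lesional from the closest consistent reading of
# the conflicting printed row (34/79), perilesional 63/79, normal 37/39.
DEFAULT_GROUP_POSITIVITY: dict[str, dict[str, float]] = {
    "EZH2": {"lesional": 60 / 79, "perilesional": 12 / 79, "normal": 4 / 39},
    "p57": {"lesional": 34 / 79, "perilesional": 63 / 79, "normal": 37 / 39},
}

# Per-differentiation-grade positivity among lesional specimens.
DEFAULT_GRADE_POSITIVITY: dict[str, dict[str, float]] = {
    "EZH2": {"poor": 0.5526, "moderate": 0.5385, "high": 0.5333},
    "p57": {"poor": 0.1683, "moderate": 0.2059, "high": 0.8079},
}

IHC_GROUPS = ("lesional", "perilesional", "normal")


@dataclass(frozen=True)
class IHCCohortConfig:
    n_lesional: int = 79
    n_perilesional: int = 79
    n_normal: int = 39
    positive_probabilities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_GROUP_POSITIVITY
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_lesional, self.n_perilesional, self.n_normal):
            if n <= 0:
                raise ValueError("group sizes must be positive")
        for marker, groups in self.positive_probabilities.items():
            for group, p in groups.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {marker}/{group}={p} outside [0, 1]")


def generate_ihc_cohort(config: IHCCohortConfig) -> pd.DataFrame:
    """Per-specimen positive/negative flags for each marker.

    Returns a frame with columns ``specimen_id``, ``group``, and one boolean
    ``<marker>_positive`` column per configured marker; aggregate with
    :func:`sonohcc.ihc.expression_table`.
    """
    rng = _child_seed(config.seed, 1)
    sizes = {
        "lesional": config.n_lesional,
        "perilesional": config.n_perilesional,
        "normal": config.n_normal,
    }
    rows = []
    counter = 0
    for group in IHC_GROUPS:
        for _ in range(sizes[group]):
            row: dict[str, object] = {"specimen_id": f"S{counter:05d}", "group": group}
            for marker, probs in config.positive_probabilities.items():
                row[f"{marker}_positive"] = bool(rng.random() < probs[group])
            rows.append(row)
            counter += 1
    return pd.DataFrame(rows)


def generate_graded_specimens(
    n_per_grade: Mapping[str, int],
    positivity: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Lesional specimens with differentiation grades and per-marker flags.

    ``n_per_grade`` maps grade -> specimen count (the study's case split is
    38 poorly / 26 moderately / 15 highly differentiated); ``positivity``
    maps marker -> grade -> probability (defaults to the observed per-grade
    rates). Returns columns ``specimen_id``, ``grade``, ``marker``,
    ``positive``.
    """
    probs = DEFAULT_GRADE_POSITIVITY if positivity is None else positivity
    rng = _child_seed(seed, 2)
    rows = []
    counter = 0
    for grade, n in n_per_grade.items():
        if n <= 0:
            raise ValueError("per-grade counts must be positive")
        for _ in range(n):
            sid = f"G{counter:06d}"
            for marker, grade_probs in probs.items():
                rows.append(
                    {
                        "specimen_id": sid,
                        "grade": grade,
                        "marker": marker,
                        "positive": bool(rng.random() < grade_probs[grade]),
                    }
                )
            counter += 1
    return pd.DataFrame(rows)


def with_seed(config, seed: int):
    """Return a copy of any generator config with its seed replaced."""
    return replace(config, seed=seed)
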