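"""Rule-based benign/malignant calls per ultrasound modality and their fusion.

Single-modality rules:

* Doppler: intralesional colour-flow grade 0-1 is benign, 2-3 malignant.
* Elastography: stiffness score 1-3 benign, 4-5 malignant.
* CEUS: a lesion is negative (benign) only if it shows neither arterial
  enhancement nor washout ("clearance"); any observed enhancement or
  washout is positive (malignant). Non-characteristic findings are grouped
  with "not observed" (the benign side) by default; the grouping is
  configurable because the clinical wording is ambiguous.

Multimodal fusion is a strict AND on malignancy: the fused call is malignant
only when Doppler, elastography, and CEUS all call malignant; a single
benign call makes the fused call benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "LesionFindings",
    "ModalityCall",
    "classify_doppler",
    "classify_elastography",
    "classify_ceus",
    "classify_findings",
    "fuse_multimodal",
]

Verdict = Literal["benign", "malignant"]
Modality = Literal["doppler", "elastography", "ceus", "multimodal"]

ARTERIAL_LEVELS = ("enhancement", "non_enhancement", "noncharacteristic")
WASHOUT_LEVELS = ("clearance", "no_clearance", "noncharacteristic")


@dataclass(frozen=True)
class LesionFindings:
    """One lesion's multimodal ultrasound observations."""

    shape: Literal["regular", "irregular"]
    boundary: Literal["clear", "unclear"]
    internal_echo: Literal["homogeneous", "inhomogeneous"]
    posterior_echo: Literal["unchanged_or_enhanced", "attenuated"]
    flow_grade: int
    elasticity_score: int
    ceus_arterial: str
    ceus_washout: str
    ceus_pattern: Literal["FFFO", "FFNO", "other"]

    def __post_init__(self) -> None:
        if not 0 <= self.flow_grade <= 3:
            raise ValueError(f"flow_grade must be in [0, 3], got {self.flow_grade}")
        if not 1 <= self.elasticity_score <= 5:
            raise ValueError(
                f"elasticity_score must be in [1, 5], got {self.elasticity_score}"
            )
        if self.ceus_arterial not in ARTERIAL_LEVELS:
            raise ValueError(f"unknown arterial pattern {self.ceus_arterial!r}")
        if self.ceus_washout not in WASHOUT_LEVELS:
            raise ValueError(f"unknown washout pattern {self.ceus_washout!r}")


@dataclass(frozen=True)
class ModalityCall:
    modality: Modality
    verdict: Verdict


def classify_doppler(flow_grade: int) -> ModalityCall:
    """Benign for flow grade 0-1, malignant for 2-3."""
    if not 0 <= flow_grade <= 3:
        raise ValueError(f"flow grade must be in [0, 3], got {flow_grade}")
    verdict: Verdict = "benign" if flow_grade <= 1 else "malignant"
    return ModalityCall("doppler", verdict)


def classify_elastography(score: int) -> ModalityCall:
    """Benign for elasticity score 1-3, malignant for 4-5."""
    if not 1 <= score <= 5:
        raise ValueError(f"elasticity score must be in [1, 5], got {score}")
    verdict: Verdict = "benign" if score <= 3 else "malignant"
    return ModalityCall("elastography", verdict)


def classify_ceus(
    arterial: str, washout: str, *, noncharacteristic_benign: bool = True
) -> ModalityCall:
    """Negative (benign) iff neither enhancement nor washout is observed.

    ``noncharacteristic_benign`` controls whether non-characteristic
    enhancement/washout counts as "not observed" (default) or as a positive
    feature.
    """
    if arterial not in ARTERIAL_LEVELS:
        raise ValueError(f"unknown arterial pattern {arterial!r}")
    if washout not in WASHOUT_LEVELS:
        raise ValueError(f"unknown washout pattern {washout!r}")
    negative_arterial = {"non_enhancement"}
    negative_washout = {"no_clearance"}
    if noncharacteristic_benign:
        negative_arterial.add("noncharacteristic")
        negative_washout.add("noncharacteristic")
    benign = arterial in negative_arterial and washout in negative_washout
    return ModalityCall("ceus", "benign" if benign else "malignant")


def classify_findings(findings: LesionFindings, modality: Modality) -> ModalityCall:
    """Apply one modality's rule (or the fused rule) to a findings record."""
    if modality == "doppler":
        return classify_doppler(findings.flow_grade)
    if modality == "elastography":
        return classify_elastography(findings.elasticity_score)
    if modality == "ceus":
        return classify_ceus(findings.ceus_arterial, findings.ceus_washout)
    if modality == "multimodal":
        return fuse_multimodal(
            [
                classify_doppler(findings.flow_grade),
                classify_elastography(findings.elasticity_score),
                classify_ceus(findings.ceus_arterial, findings.ceus_washout),
            ]
        )
    raise ValueError(f"unknown modality {modality!r}")


def fuse_multimodal(calls: Iterable[ModalityCall]) -> ModalityCall:
    """AND-fuse the three single-modality verdicts.

    Requires exactly one call per modality in {doppler, elastography, ceus};
    the fused verdict is malignant only if all three are malignant.
    """
    by_modality: dict[str, ModalityCall] = {}
    for call in calls:
        if call.modality not in ("doppler", "elastography", "ceus"):
            raise ValueError(f"cannot fuse modality {call.modality!r}")
        if call.modality in by_modality:
            raise ValueError(f"duplicated modality {call.modality!r}")
        by_modality[call.modality] = call
    missing = {"doppler", "elastography", "ceus"} - set(by_modality)
    if missing:
        raise ValueError(f"missing modalities: {sorted(missing)}")
    all_malignant = all(c.verdict == "malignant" for c in by_modality.values())
    return ModalityCall("multimodal", "malignant" if all_malignant else "benign")
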