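"""Apply each arm's modality rule to the simulated cohort and summarise.

Reads results/cohort.csv (written by 01_simulate.py; regenerated here if
missing), classifies every lesion with its arm's rule (Doppler flow grade,
elasticity score, CEUS enhancement/washout, or the AND-fusion of all
three), and tabulates diagnostic performance against the simulated
pathology labels. Also writes the per-grade imaging-feature frequency
table. Writes results/diagnostic_summary.csv and
results/feature_frequencies.csv.
"""

from pathlib import Path

import pandas as pd

from sonohcc import io as sio
from sonohcc.diagstats import build_contingency, diagnostic_performance, feature_frequency_table
from sonohcc.modality import LesionFindings, classify_findings
from sonohcc.synthgen import CohortConfig, cohort_to_frame, generate_cohort

SEED = 1
OUT = Path("results")
GROUP_TO_MODALITY = {
    "doppler": "doppler",
    "contrast": "ceus",
    "elastic": "elastography",
    "multimodal": "multimodal",
}


def findings_from_row(row) -> LesionFindings:
    return LesionFindings(
        shape=row.shape,
        boundary=row.boundary,
        internal_echo=row.internal_echo,
        posterior_echo=row.posterior_echo,
        flow_grade=int(row.flow_grade),
        elasticity_score=int(row.elasticity_score),
        ceus_arterial=row.ceus_arterial,
        ceus_washout=row.ceus_washout,
        ceus_pattern=row.ceus_pattern,
    )


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohort_path = OUT / "cohort.csv"
    if cohort_path.exists():
        cohort = sio.read_csv(cohort_path)
    else:
        cohort = cohort_to_frame(generate_cohort(CohortConfig(seed=SEED)))
    rows = []
    for group, modality_name in GROUP_TO_MODALITY.items():
        sub = cohort[cohort["group"] == group]
        calls = [classify_findings(findings_from_row(r), modality_name) for r in sub.itertuples()]
        table = build_contingency(calls, list(sub["pathology"]))
        perf = diagnostic_performance(table)
        rows.append(
            {
                "group": group,
                "modality": modality_name,
                "n_lesions": len(sub),
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "accuracy": perf.accuracy,
                "kappa": perf.kappa,
                "kappa_band": perf.kappa_band,
            }
        )
    summary = pd.DataFrame(rows)
    sio.write_csv(OUT / "diagnostic_summary.csv", summary, seed=SEED, config="rule-based diagnosis")
    print(summary.to_string(index=False))

    features = feature_frequency_table(cohort)
    sio.write_csv(OUT / "feature_frequencies.csv", features, seed=SEED, config="per-grade features")
    shape = features[features["feature"] == "shape=irregular"]
    print("\nirregular-shape frequency by differentiation grade:")
    print(shape[["grade", "n_lesions", "count", "percent"]].to_string(index=False))


if __name__ == "__main__":
    main()
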