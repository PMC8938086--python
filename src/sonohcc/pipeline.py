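"""End-to-end orchestration: generate -> filter -> evaluate -> diagnose -> report.

A :class:`PipelineConfig` (optionally loaded from YAML) toggles four stages:

* ``phantoms``  — simulate noisy phantoms, denoise them with the adaptive
  median filter, simulate annotator mask sets, pick the gold standard, and
  score every mask against it (confusion metrics + VOE);
* ``cohort``    — simulate the four-arm patient cohort, apply the modality
  rules per arm, and summarise diagnostic performance per group;
* ``ihc``       — simulate the three-tissue IHC cohort and the
  grade-stratified specimens, and tabulate expression rates;
* ``replay``    — recompute every statistic derivable from the published
  tables and flag printed values inconsistent with their own cells.

All randomness derives from the single global seed; identical config + seed
yields byte-identical CSV outputs, each stamped with seed and config hash.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .diagstats import (
    build_contingency,
    diagnostic_performance,
    feature_frequency_table,
)
from .imgproc import adaptive_median_filter
from .ihc import expression_table, grade_stratified_rates, positive_rate
from .modality import classify_findings
from .segeval import classification_metrics, confusion_counts, select_gold_standard, voe
from .synthgen import (
    AnnotatorConfig,
    CohortConfig,
    IHCCohortConfig,
    PhantomConfig,
    cohort_to_frame,
    generate_cohort,
    generate_graded_specimens,
    generate_ihc_cohort,
    generate_phantom,
    simulate_annotators,
)
from .tables import replay_diagnostics, replay_expression

logger = logging.getLogger("sonohcc")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    run_phantoms: bool = True
    run_cohort: bool = True
    run_ihc: bool = True
    run_replay: bool = True
    n_phantoms: int = 5
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        speckle_scale=0.2, impulse_density=0.1
    ))
    annotator: AnnotatorConfig = field(default_factory=AnnotatorConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ihc: IHCCohortConfig = field(default_factory=IHCCohortConfig)
    filter_initial_size: int = 3
    filter_s_max: int = 7
    write_images: bool = False


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a (possibly partial) YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "phantom": PhantomConfig,
        "annotator": AnnotatorConfig,
        "cohort": CohortConfig,
        "ihc": IHCCohortConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _stage_phantoms(config: PipelineConfig, outdir: Path, meta: dict) -> pd.DataFrame:
    rows = []
    for i in range(config.n_phantoms):
        pcfg = dataclasses.replace(config.phantom, seed=config.seed * 1000 + i)
        image, mask = generate_phantom(pcfg)
        filtered = adaptive_median_filter(
            image, config.filter_initial_size, config.filter_s_max
        )
        clean = np.where(mask > 0, pcfg.lesion_level, pcfg.background_level)
        mae_noisy = float(np.abs(image.astype(float) - clean).mean())
        mae_filtered = float(np.abs(filtered.astype(float) - clean).mean())
        acfg = dataclasses.replace(config.annotator, seed=config.seed * 1000 + i)
        annotations = simulate_annotators(mask, acfg)
        gold_idx, gold = select_gold_standard(annotations)
        for a_idx, ann in enumerate(annotations):
            counts = confusion_counts(ann, gold)
            accuracy, precision, recall = classification_metrics(counts)
            rows.append(
                {
                    "phantom": i,
                    "annotator": a_idx,
                    "is_gold": a_idx == gold_idx,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "accuracy": accuracy,
                    "precision": precision,
                    "recall": recall,
                    "voe_vs_gold": voe(ann, gold),
                    "mae_noisy": mae_noisy,
                    "mae_filtered": mae_filtered,
                }
            )
        if config.write_images:
            sio.write_image(outdir / f"phantom_{i:03d}.tif", image)
            sio.write_image(outdir / f"phantom_{i:03d}_filtered.tif", filtered)
            sio.write_mask(outdir / f"phantom_{i:03d}_mask.png", mask)
    frame = pd.DataFrame(rows)
    sio.write_csv(outdir / "segmentation_eval.csv", frame, seed=config.seed, config=meta)
    return frame


def _stage_cohort(config: PipelineConfig, outdir: Path, meta: dict) -> pd.DataFrame:
    ccfg = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = cohort_to_frame(generate_cohort(ccfg))
    sio.write_csv(outdir / "cohort.csv", cohort, seed=config.seed, config=meta)
    group_to_modality = {
        "doppler": "doppler",
        "contrast": "ceus",
        "elastic": "elastography",
        "multimodal": "multimodal",
    }
    from .modality import LesionFindings  # local to keep module import light

    summaries = []
    for group, modality_name in group_to_modality.items():
        sub = cohort[cohort["group"] == group]
        if sub.empty:
            continue
        calls = [
            classify_findings(
                LesionFindings(
                    shape=r.shape,
                    boundary=r.boundary,
                    internal_echo=r.internal_echo,
                    posterior_echo=r.posterior_echo,
                    flow_grade=int(r.flow_grade),
                    elasticity_score=int(r.elasticity_score),
                    ceus_arterial=r.ceus_arterial,
                    ceus_washout=r.ceus_washout,
                    ceus_pattern=r.ceus_pattern,
                ),
                modality_name,
            )
            for r in sub.itertuples()
        ]
        table = build_contingency(calls, list(sub["pathology"]))
        perf = diagnostic_performance(table)
        summaries.append(
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
    summary = pd.DataFrame(summaries)
    sio.write_csv(outdir / "diagnostic_summary.csv", summary, seed=config.seed, config=meta)
    features = feature_frequency_table(cohort)
    sio.write_csv(outdir / "feature_frequencies.csv", features, seed=config.seed, config=meta)
    return summary


def _stage_ihc(config: PipelineConfig, outdir: Path, meta: dict) -> pd.DataFrame:
    icfg = dataclasses.replace(config.ihc, seed=config.seed)
    specimens = generate_ihc_cohort(icfg)
    sio.write_csv(outdir / "ihc_specimens.csv", specimens, seed=config.seed, config=meta)
    rows = []
    for marker in icfg.positive_probabilities:
        flags = specimens.rename(columns={f"{marker}_positive": "positive"})
        table = expression_table(flags[["group", "positive"]])
        for group in table.index:
            rows.append(
                {
                    "marker": marker,
                    "group": group,
                    "negative": int(table.loc[group, "negative"]),
                    "positive": int(table.loc[group, "positive"]),
                    "rate_percent": positive_rate(table, group),
                }
            )
    graded = generate_graded_specimens(
        {"poor": 38, "moderate": 26, "high": 15}, seed=config.seed
    )
    for marker, table in grade_stratified_rates(graded).items():
        for grade in table.index:
            rows.append(
                {
                    "marker": marker,
                    "group": f"grade_{grade}",
                    "negative": int(table.loc[grade, "negative"]),
                    "positive": int(table.loc[grade, "positive"]),
                    "rate_percent": float(table.loc[grade, "rate_percent"]),
                }
            )
    frame = pd.DataFrame(rows)
    sio.write_csv(outdir / "ihc_rates.csv", frame, seed=config.seed, config=meta)
    return frame


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the enabled stages in order; returns every stage's summary frame."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dataclasses.asdict(config)
    meta.pop("outdir", None)  # provenance hash covers the science, not the paths
    report: dict[str, pd.DataFrame] = {}
    stages = [
        ("phantoms", config.run_phantoms, _stage_phantoms),
        ("cohort", config.run_cohort, _stage_cohort),
        ("ihc", config.run_ihc, _stage_ihc),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            continue
        logger.info("running stage %s", name)
        try:
            report[name] = fn(config, outdir, meta)
        except Exception:
            logger.exception("stage %s failed", name)
            raise
    if config.run_replay:
        logger.info("running stage replay")
        diag = replay_diagnostics()
        expr = replay_expression()
        sio.write_csv(outdir / "replay_diagnostics.csv", diag, seed=config.seed, config=meta)
        sio.write_csv(outdir / "replay_expression.csv", expr, seed=config.seed, config=meta)
        report["replay_diagnostics"] = diag
        report["replay_expression"] = expr
    return report
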