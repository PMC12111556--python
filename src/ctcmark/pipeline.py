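"""End-to-end driver: simulate every input, train the antigenicity head,
run the marker cascade, call the simulated clinical cohort, and render the
final report.  Deterministic given (config, seed)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import antigenicity, cohort_stats, ctc_call, geneselect, simdata
from .containers import cells_to_tsv
from .geneselect import CascadeConfig, CascadeReport
from .simdata import COCKTAIL_PANEL, CONVENTIONAL_PANEL, SimConfig


@dataclass
class PipelineResult:
    report: CascadeReport
    cohort_calls: ctc_call.CohortCalls
    summary: pd.DataFrame
    positivity: cohort_stats.PositivityTable
    tests: dict[str, cohort_stats.TestResult]


def train_default_head(cfg: SimConfig, n_training: int = 300) -> antigenicity.LinearHead:
    """Train the antigenicity head on a dedicated simulated training set,
    kept separate from the cascade's candidate genes."""
    train_cfg = SimConfig(seed=int(cfg.seed) + 1_000_003, protein_length_range=cfg.protein_length_range,
                          frac_antigenic=cfg.frac_antigenic, acc_lag=cfg.acc_lag)
    ids = [f"TRAIN{i:05d}" for i in range(n_training)]
    records, truth = simdata.simulate_proteins(ids, train_cfg)
    acc_cfg = antigenicity.ACCConfig(lag=cfg.acc_lag)
    features = antigenicity.acc_matrix(records, acc_cfg)
    labels = [1 if r.id in truth else 0 for r in records]
    return antigenicity.train_head(features, labels, lag=cfg.acc_lag)


def run_full_pipeline(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    cascade_cfg: CascadeConfig | None = None,
) -> PipelineResult:
    """Simulate all inputs, run the cascade and the cohort analysis.

    When ``out_dir`` is given, all simulated inputs, intermediate gene sets,
    the cascade ledger and the final report are written there.
    """
    cfg.validate()
    cascade_cfg = cascade_cfg or CascadeConfig()

    bulk, design, deg_truth = simdata.simulate_bulk(cfg)
    lines_matrix, lines_truth = simdata.simulate_cell_lines(cfg)
    sc_matrix, sc_truth = simdata.simulate_ctc_singlecell(cfg)
    annot = simdata.simulate_annotations(bulk.gene_ids, cfg)
    proteins, antigenic_truth = simdata.simulate_proteins(bulk.gene_ids, cfg)
    head = train_default_head(cfg)

    report = geneselect.run_cascade(
        bulk, design, lines_matrix, sc_matrix, annot, proteins, head, cascade_cfg
    )

    cells = simdata.simulate_cohort_cells(cfg.cohort, seed=cfg.seed)
    conv_rules = ctc_call.CTCDecisionRules(panel=tuple(sorted(CONVENTIONAL_PANEL)))
    cock_rules = ctc_call.CTCDecisionRules(panel=tuple(sorted(COCKTAIL_PANEL)))
    conv_calls = ctc_call.call_cohort(cells[cells["panel"] == "conv"], conv_rules)
    cock_calls = ctc_call.call_cohort(cells[cells["panel"] == "cocktail"], cock_rules)
    per_subject = pd.concat(
        [conv_calls.per_subject, cock_calls.per_subject], ignore_index=True
    ).sort_values(["cohort", "panel", "subject_id"], ignore_index=True)
    per_support = pd.concat(
        [conv_calls.per_support, cock_calls.per_support], ignore_index=True
    ).sort_values(["support_id"], ignore_index=True)
    calls = pd.concat([conv_calls.calls, cock_calls.calls], ignore_index=True)
    cohort_calls = ctc_call.CohortCalls(calls, per_support, per_subject)

    summary = cohort_stats.cohort_summary(per_subject)

    # Positivity over patient atypical cells, per panel.
    atypical_ids = set(calls.loc[calls["atypical"], "cell_id"])
    pat_cock = cells[
        (cells["cohort"] == "patient")
        & (cells["panel"] == "cocktail")
        & cells["cell_id"].isin(atypical_ids)
    ]
    positivity = cohort_stats.positivity_table(
        pat_cock,
        markers=list(COCKTAIL_PANEL),
        cocktails={"SCREENCELL_COCKTAIL": list(COCKTAIL_PANEL)},
    )

    tests = _cohort_tests(per_subject)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bulk.to_tsv(out_dir / "bulk.tsv")
        design.to_tsv(out_dir / "design.tsv")
        deg_truth.write(out_dir / "truth_deg.txt")
        lines_matrix.to_tsv(out_dir / "cell_lines.tsv")
        lines_truth.write(out_dir / "truth_lines.txt")
        sc_matrix.to_tsv(out_dir / "sc_ctc.tsv")
        sc_truth.write(out_dir / "truth_sc.txt")
        annot.to_tsv(out_dir / "annotations.tsv")
        antigenicity.write_fasta(proteins, out_dir / "proteins.fa")
        antigenic_truth.write(out_dir / "truth_antigenic.txt")
        head.to_json(out_dir / "head.json")
        cells_to_tsv(cells, out_dir / "cohort_cells.tsv")
        report.to_json(out_dir / "cascade_ledger.json")
        for stage in report.stages:
            _write_stage_genes(out_dir, stage)
        cohort_stats.render_report(
            out_dir,
            cascade_ledger=json.loads(report.to_json()),
            positivity=positivity,
            summary=summary,
            tests=tests,
        )
    return PipelineResult(report, cohort_calls, summary, positivity, tests)


def _write_stage_genes(out_dir: Path, stage) -> None:
    path = out_dir / f"genes_{stage.name}.txt"
    path.write_text("".join(f"{g}\n" for g in sorted(stage.genes)), encoding="utf-8")


def _cohort_tests(per_subject: pd.DataFrame) -> dict[str, cohort_stats.TestResult]:
    """The study's planned comparisons: paired per-patient panel contrasts
    and the unpaired patient-vs-donor CTC-count comparison."""
    tests: dict[str, cohort_stats.TestResult] = {}
    pat = per_subject[per_subject["cohort"] == "patient"]
    wide_ac = pat.pivot(index="subject_id", columns="panel", values="n_ac")
    wide_pct = pat.pivot(index="subject_id", columns="panel", values="pct_stained").dropna()
    wide_ctc = pat.pivot(index="subject_id", columns="panel", values="n_ctc")
    if {"conv", "cocktail"} <= set(wide_ac.columns) and len(wide_ac) >= 2:
        tests["patient_ac_conv_vs_cocktail"] = cohort_stats.paired_t(
            wide_ac["conv"].to_numpy(), wide_ac["cocktail"].to_numpy()
        )
        tests["patient_ctc_conv_vs_cocktail"] = cohort_stats.paired_t(
            wide_ctc["conv"].to_numpy(), wide_ctc["cocktail"].to_numpy()
        )
        if len(wide_pct) >= 2:
            tests["patient_pct_stained_conv_vs_cocktail"] = cohort_stats.paired_t(
                wide_pct["conv"].to_numpy(), wide_pct["cocktail"].to_numpy()
            )
    don = per_subject[
        (per_subject["cohort"] == "donor") & (per_subject["panel"] == "cocktail")
    ]
    pat_ctc = pat[pat["panel"] == "cocktail"]["n_ctc"].to_numpy(float)
    don_ctc = don["n_ctc"].to_numpy(float)
    if pat_ctc.size >= 2 and don_ctc.size >= 2:
        tests["ctc_patients_vs_donors"] = cohort_stats.unpaired_t(pat_ctc, don_ctc)
    return tests
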