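"""The marker-prioritisation cascade: the overmean expressed-and-variable
gene selector, membrane and immune filters, gene-set intersection with Venn
region counts, the three-criterion in silico sorting, and the cascade
orchestrator with its per-stage ledger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneAnnotation, GeneSet, GroupDesign, IHC_LEVELS
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """Tunable thresholds of the cascade.

    ``membrane_rule`` defaults to ``at_least_one`` (a gene flagged by either
    membrane database is kept, so no candidate is neglected); ``both_dbs``
    restricts to genes confirmed by both.  The IHC criterion keeps genes at
    ``ihc_min_level`` or above in at least ``ihc_min_fraction`` of annotated
    tumor samples.
    """

    fdr_threshold: float = 0.05
    antigenicity_threshold: float = 0.5
    ihc_min_level: str = "medium"
    ihc_min_fraction: float = 0.5
    membrane_rule: str = "at_least_one"
    refvar: str = "mean_gene_var"

    def validate(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ConfigurationError("fdr_threshold must lie in (0, 1)")
        if self.ihc_min_level not in IHC_LEVELS:
            raise ConfigurationError(f"ihc_min_level must be one of {IHC_LEVELS}")
        if not 0 <= self.ihc_min_fraction <= 1:
            raise ConfigurationError("ihc_min_fraction must lie in [0, 1]")
        if self.membrane_rule not in ("both_dbs", "at_least_one"):
            raise ConfigurationError("membrane_rule must be 'both_dbs' or 'at_least_one'")
        if self.refvar not in ("mean_gene_var", "total_var"):
            raise ConfigurationError("refvar must be 'mean_gene_var' or 'total_var'")


@dataclass
class CascadeStage:
    name: str
    criterion: str
    n_in: int
    n_out: int
    genes: list[str]
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "criterion": self.criterion,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "genes": sorted(self.genes),
        }
        if self.extra:
            d["extra"] = self.extra
        return d


@dataclass
class CascadeReport:
    """Ordered ledger of cascade stages; counts always equal set sizes."""

    stages: list[CascadeStage] = field(default_factory=list)

    def add(self, name: str, criterion: str, genes_in: GeneSet, genes_out: GeneSet, **extra):
        if not genes_out.genes <= genes_in.genes:
            raise InputError(f"stage {name!r} emitted genes outside its input")
        self.stages.append(
            CascadeStage(name, criterion, len(genes_in), len(genes_out), sorted(genes_out.genes), dict(extra))
        )

    @property
    def counts(self) -> list[int]:
        return [s.n_out for s in self.stages]

    @property
    def final_genes(self) -> GeneSet:
        if not self.stages:
            return GeneSet("final", frozenset())
        return GeneSet("final", frozenset(self.stages[-1].genes))

    def to_json(self, path=None) -> str:
        payload = {"stages": [s.to_dict() for s in self.stages]}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# overmean
# ---------------------------------------------------------------------------

def overmean(
    matrix: ExpressionMatrix, refvar: str = "mean_gene_var"
) -> tuple[GeneSet, ExpressionMatrix]:
    """Select genes that are expressed above the array mean and more variable
    between samples than the array's reference variance.

    A gene g is kept iff ``mean_g > grand_mean`` and ``var_g > ref_var``
    (strict inequalities; ties excluded), where ``mean_g`` is the gene's mean
    across samples, ``grand_mean`` the mean over all matrix entries,
    ``var_g`` the unbiased between-sample variance, and ``ref_var`` either
    the mean of the per-gene variances (default) or the variance of all
    entries pooled (``refvar='total_var'``).

    Returns the selected gene set and the row-subset matrix.
    """
    if matrix.shape[1] < 2:
        raise InputError("overmean requires at least 2 samples (variance undefined)")
    if refvar not in ("mean_gene_var", "total_var"):
        raise ConfigurationError("refvar must be 'mean_gene_var' or 'total_var'")
    values = matrix.values.to_numpy(float)
    gene_means = values.mean(axis=1)
    grand_mean = values.mean()
    gene_vars = values.var(axis=1, ddof=1)
    ref_var = gene_vars.mean() if refvar == "mean_gene_var" else values.var(ddof=1)
    keep = (gene_means > grand_mean) & (gene_vars > ref_var)
    genes = GeneSet("overmean", frozenset(np.asarray(matrix.gene_ids)[keep]))
    sub = ExpressionMatrix(matrix.values.loc[keep], platform=matrix.platform)
    return genes, sub


# ---------------------------------------------------------------------------
# Set filters
# ---------------------------------------------------------------------------

def filter_plasma_membrane(genes: GeneSet, annot: GeneAnnotation) -> GeneSet:
    """Keep genes flagged plasma-membrane by the GO cellular-component
    annotation; unannotated genes are treated as not membrane (logged)."""
    missing = [g for g in genes if g not in annot]
    if missing:
        logger.info("%d genes lack annotation; treated as non-membrane", len(missing))
    kept = frozenset(g for g in genes.genes if annot.flag(g, "go_plasma_membrane"))
    return GeneSet("plasma_membrane", kept)


def intersect(sets: Sequence[GeneSet]) -> tuple[GeneSet, dict[str, int]]:
    """Intersect 2-3 gene sets, returning the common set and the cardinality
    of every Venn region keyed by membership pattern (e.g. ``"110"``)."""
    if len(sets) < 2:
        raise InputError("intersect requires at least 2 gene sets")
    if len(sets) > 3:
        raise InputError("Venn region reporting supports at most 3 sets")
    universe = frozenset().union(*(s.genes for s in sets))
    regions: dict[str, int] = {}
    for g in universe:
        key = "".join("1" if g in s.genes else "0" for s in sets)
        regions[key] = regions.get(key, 0) + 1
    common = frozenset.intersection(*(s.genes for s in sets))
    name = "&".join(s.name for s in sets)
    return GeneSet(name, common), dict(sorted(regions.items()))


def filter_expressed_in_ctc(
    candidates: GeneSet, sc_matrix: ExpressionMatrix, refvar: str = "mean_gene_var"
) -> GeneSet:
    """Restrict candidates to genes the single-CTC matrix shows as expressed
    and variable (the overmean selection on the FPKM matrix)."""
    if sc_matrix.platform != "fpkm":
        raise InputError("single-cell matrix must carry the fpkm platform tag")
    expressed, _ = overmean(sc_matrix, refvar=refvar)
    return GeneSet("expressed_in_ctc", candidates.genes & expressed.genes)


# ---------------------------------------------------------------------------
# In silico sorting (three sequential criteria)
# ---------------------------------------------------------------------------

def _ihc_pass(levels: tuple[str, ...], min_level: str, min_fraction: float) -> bool:
    if not levels:
        return False
    threshold = IHC_LEVELS.index(min_level)
    n_ok = sum(IHC_LEVELS.index(lv) >= threshold for lv in levels)
    return n_ok / len(levels) >= min_fraction


def insilico_sort(
    genes: GeneSet, annot: GeneAnnotation, cfg: CascadeConfig | None = None
) -> tuple[GeneSet, CascadeReport]:
    """Apply the three-criterion in silico sorting:

    1. keep genes with confirmed membrane localisation under
       ``cfg.membrane_rule`` (the both-databases and single-database counts
       are reported separately);
    2. drop genes expressed by immune cells in either database;
    3. keep genes whose IHC profile reaches ``ihc_min_level`` in at least
       ``ihc_min_fraction`` of annotated tumor samples.

    Returns the surviving set and a three-stage report fragment.
    """
    cfg = cfg or CascadeConfig()
    cfg.validate()
    fragment = CascadeReport()

    both = frozenset(
        g for g in genes.genes if annot.flag(g, "membrane_db1") and annot.flag(g, "membrane_db2")
    )
    one = frozenset(
        g
        for g in genes.genes
        if annot.flag(g, "membrane_db1") ^ annot.flag(g, "membrane_db2")
    )
    kept1 = both if cfg.membrane_rule == "both_dbs" else both | one
    s1 = GeneSet("membrane", kept1)
    fragment.add(
        "membrane_localization",
        f"membrane flag per rule {cfg.membrane_rule}",
        genes,
        s1,
        membrane_both=len(both),
        membrane_one=len(one),
    )

    kept2 = frozenset(
        g for g in s1.genes if not (annot.flag(g, "immune_db1") or annot.flag(g, "immune_db2"))
    )
    s2 = GeneSet("non_immune", kept2)
    fragment.add("immune_exclusion", "not expressed by immune cells (either database)", s1, s2)

    kept3 = frozenset(
        g
        for g in s2.genes
        if _ihc_pass(annot.ihc_levels(g), cfg.ihc_min_level, cfg.ihc_min_fraction)
    )
    s3 = GeneSet("ihc_expressed", kept3)
    fragment.add(
        "ihc_expression",
        f">= {cfg.ihc_min_level} IHC in >= {cfg.ihc_min_fraction:.0%} of tumor samples",
        s2,
        s3,
    )
    return s3, fragment


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    bulk: ExpressionMatrix,
    design: GroupDesign,
    lines_matrix: ExpressionMatrix,
    sc_matrix: ExpressionMatrix,
    annot: GeneAnnotation,
    proteins,
    head,
    cfg: CascadeConfig | None = None,
) -> CascadeReport:
    """Run the full marker-prioritisation cascade and return its ledger.

    Stages: tumor-vs-adjacent upregulation (moderated t, BH-FDR) →
    GO plasma-membrane filter → intersection with the cell-line
    expressed-and-variable (overmean) set → antigenicity score filter →
    expressed-in-CTC filter → three-criterion in silico sorting.

    ``proteins`` are Biopython SeqRecords covering the candidate genes;
    ``head`` is a trained antigenicity :class:`~ctcmark.antigenicity.LinearHead`.
    """
    from .antigenicity import score_sequences
    from .diffexp import moderated_t, select_upregulated

    cfg = cfg or CascadeConfig()
    cfg.validate()
    _check_gene_ids(bulk, lines_matrix, sc_matrix)

    report = CascadeReport()
    all_genes = GeneSet("all", frozenset(bulk.gene_ids))

    deg = moderated_t(bulk, design, fdr_threshold=cfg.fdr_threshold)
    up = select_upregulated(deg)
    report.add(
        "upregulated_in_tumor",
        f"log2fc > 0 and BH-FDR < {cfg.fdr_threshold}",
        all_genes,
        up,
    )

    membrane = filter_plasma_membrane(up, annot)
    report.add("plasma_membrane", "GO cellular-component plasma membrane flag", up, membrane)

    lines_set, _ = overmean(lines_matrix, refvar=cfg.refvar)
    common, regions = intersect([membrane, lines_set])
    report.add(
        "cell_line_overlap",
        "intersection with expressed-and-variable cell-line genes (overmean)",
        membrane,
        GeneSet("overlap", common.genes),
        venn_regions=regions,
        cell_line_overmean=len(lines_set),
    )

    by_id = {r.id: r for r in proteins}
    missing = sorted(g for g in common.genes if g not in by_id)
    if missing:
        raise InputError(f"no protein sequence for genes: {missing[:5]}")
    scored = score_sequences(
        [by_id[g] for g in sorted(common.genes)], head, threshold=cfg.antigenicity_threshold
    )
    antigenic = GeneSet(
        "antigenic", frozenset(scored.loc[scored["antigenic"], "id"])
    )
    report.add(
        "antigenicity",
        f"ACC-descriptor score >= {cfg.antigenicity_threshold}",
        common,
        antigenic,
    )

    in_ctc = filter_expressed_in_ctc(antigenic, sc_matrix, refvar=cfg.refvar)
    report.add(
        "expressed_in_ctc", "expressed-and-variable in single-CTC matrix", antigenic, in_ctc
    )

    _, fragment = insilico_sort(in_ctc, annot, cfg)
    report.stages.extend(fragment.stages)
    return report


def _check_gene_ids(*matrices: ExpressionMatrix) -> None:
    base = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        diff = base.symmetric_difference(m.gene_ids)
        if diff:
            raise InputError(
                f"gene ids differ across input matrices; offending ids include {sorted(diff)[:5]}"
            )
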