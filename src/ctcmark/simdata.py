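"""Synthetic-data generators for every input the marker-discovery pipeline
consumes: a bulk tumor/adjacent expression matrix with planted differentially
expressed genes, a heterogeneous cell-line panel with a planted
expressed-and-variable subset, a sparse single-cell FPKM matrix with dropout,
per-gene database annotations, protein sequences, and per-cell cohort
feature tables.

Every generator is deterministic given its configuration: identical
``(config, seed)`` pairs yield byte-identical serialised outputs.  Planted
truth sets are returned alongside each dataset so recovery can be measured.

The statistical structure emulated is that of the study inputs: normalised
log-intensity arrays with a tumor-vs-adjacent group shift, a cell-line panel
in which a subset of genes is both expressed above the array mean and more
variable than average, single-cell FPKM with Bernoulli dropout and per-cell
library-size heterogeneity, and blood-filtration supports carrying a few
large leukocytes plus a Poisson number of atypical cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    GroupDesign,
    IHC_LEVELS,
)
from .errors import ConfigurationError, InputError

# Distinct per-generator stream keys so each simulate_* call draws from an
# independent, reproducible stream of the same base seed.
_STREAMS = {
    "bulk": 1,
    "lines": 2,
    "sc": 3,
    "annot": 4,
    "proteins": 5,
    "cohort": 6,
    "planted": 7,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CohortSimConfig:
    """Clinical-cohort simulation parameters.

    Atypical-cell (AC) burdens are Poisson means per 3 mL isolation support;
    defaults echo the study cohort: 40 node-invaded patients averaging
    ~27 ACs per support and 18 healthy donors averaging <1, with per-cell
    staining sensitivities of ~0.66 for the conventional EpCAM+CK panel and
    ~0.996 for the MARCKSL1+SLC9A3R1+RHOD cocktail.
    """

    n_patients: int = 40
    n_donors: int = 18
    patient_ac_mean: float = 27.14
    donor_ac_mean: float = 0.77
    conventional_sensitivity: float = 0.6582
    cocktail_sensitivity: float = 0.9959
    leukocytes_per_support: int = 40
    #: P(high | positive) when assigning a stain level to a detected cell.
    high_given_positive: float = 0.7

    def validate(self) -> None:
        for name in ("n_patients", "n_donors", "leukocytes_per_support"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("patient_ac_mean", "donor_ac_mean"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("conventional_sensitivity", "cocktail_sensitivity", "high_given_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass
class SimConfig:
    """Master configuration for all synthetic datasets.

    Counts are modest relative to genome scale so a full pipeline run stays
    interactive; fractions control how many genes receive each planted
    property.  ``deg_log2_shift`` is the tumor-over-adjacent effect size in
    log2 units, added to the planted genes' tumor samples.
    """

    seed: int = 0
    n_genes: int = 2000
    n_tumor: int = 20
    n_adjacent: int = 20
    n_true_deg: int = 200
    deg_log2_shift: float = 2.0
    bulk_noise_sd: float = 0.5
    n_cell_lines: int = 50
    frac_expressed_variable: float = 0.1
    sc_n_cells: int = 80
    sc_dropout: float = 0.6
    frac_membrane_both: float = 0.15
    frac_membrane_one: float = 0.1
    frac_immune: float = 0.3
    frac_ihc_high: float = 0.4
    n_ihc_samples: int = 8
    protein_length_range: tuple[int, int] = (80, 300)
    frac_antigenic: float = 0.5
    acc_lag: int = 8
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)

    def validate(self) -> None:
        for f in fields(self):
            name = f.name
            if name.startswith("n_") and name != "n_true_deg":
                if getattr(self, name) < 1:
                    raise ConfigurationError(f"{name} must be >= 1")
        if self.n_true_deg < 0:
            raise ConfigurationError("n_true_deg must be >= 0")
        if self.n_true_deg > self.n_genes:
            raise ConfigurationError("n_true_deg must not exceed n_genes")
        for name in (
            "frac_expressed_variable",
            "sc_dropout",
            "frac_membrane_both",
            "frac_membrane_one",
            "frac_immune",
            "frac_ihc_high",
            "frac_antigenic",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.frac_membrane_both + self.frac_membrane_one > 1.0:
            raise ConfigurationError("frac_membrane_both + frac_membrane_one must be <= 1")
        if self.bulk_noise_sd <= 0:
            raise ConfigurationError("bulk_noise_sd must be > 0")
        lo, hi = self.protein_length_range
        if lo > hi:
            raise ConfigurationError("protein_length_range must be (low, high) with low <= high")
        if lo < self.acc_lag + 1:
            raise ConfigurationError(
                "protein_length_range lower bound must be >= acc_lag + 1 "
                "(auto/cross-covariance undefined for shorter sequences)"
            )
        self.cohort.validate()

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def _planted_order(cfg: SimConfig) -> np.ndarray:
    """Shared permutation of gene indices from which every generator takes
    its planted subset as a prefix.

    Real marker genes carry all the planted properties at once (upregulated
    in tumors, heterogeneously expressed across cell lines, expressed in
    CTCs), so the generators plant nested subsets of one shared pool rather
    than independent draws — otherwise the cascade's intersection stages
    would be near-empty by construction.
    """
    return cfg.rng("planted").permutation(cfg.n_genes)


# ---------------------------------------------------------------------------
# Bulk tumor vs adjacent matrix
# ---------------------------------------------------------------------------

def simulate_bulk(cfg: SimConfig) -> tuple[ExpressionMatrix, GroupDesign, GeneSet]:
    """Simulate a normalised log2-intensity matrix of tumor (BT) vs adjacent
    (BNT) samples with ``n_true_deg`` genes upregulated by ``deg_log2_shift``.

    Returns the matrix, the sample->group design, and the planted truth set.
    """
    cfg.validate()
    rng = cfg.rng("bulk")
    genes = gene_ids(cfg.n_genes)
    n = cfg.n_tumor + cfg.n_adjacent
    baseline = rng.normal(7.0, 1.5, size=cfg.n_genes)  # typical array log2 levels
    values = baseline[:, None] + rng.normal(0.0, cfg.bulk_noise_sd, size=(cfg.n_genes, n))
    deg_idx = _planted_order(cfg)[: cfg.n_true_deg]
    values[np.ix_(deg_idx, np.arange(cfg.n_tumor))] += cfg.deg_log2_shift
    samples = [f"BT{i:03d}" for i in range(cfg.n_tumor)] + [
        f"BNT{i:03d}" for i in range(cfg.n_adjacent)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), platform="bulk_log"
    )
    design = GroupDesign(
        pd.Series(["BT"] * cfg.n_tumor + ["BNT"] * cfg.n_adjacent, index=samples)
    )
    truth = GeneSet("true_deg", frozenset(genes[i] for i in deg_idx))
    return matrix, design, truth


# ---------------------------------------------------------------------------
# Cell-line panel with planted expressed-and-variable subset
# ---------------------------------------------------------------------------

def simulate_cell_lines(cfg: SimConfig) -> tuple[ExpressionMatrix, GeneSet]:
    """Simulate a heterogeneous cell-line panel in which a planted fraction of
    genes is expressed above the array mean AND more variable between lines
    than the average gene — the subset the overmean selector should recover.
    """
    cfg.validate()
    rng = cfg.rng("lines")
    genes = gene_ids(cfg.n_genes)
    n_planted = int(round(cfg.frac_expressed_variable * cfg.n_genes))
    planted_idx = _planted_order(cfg)[:n_planted]
    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[planted_idx] = True

    # Planted genes: high level AND wide spread across lines.  Background is
    # bimodal the way arrays are — stably expressed genes (high mean, low
    # variance) and noisy low-expressed genes (low mean, higher variance) —
    # so no null gene jointly exceeds both overmean references.
    housekeeping = rng.random(cfg.n_genes) < 0.5
    base = np.where(planted, 10.0, np.where(housekeeping, 8.0, 4.0))
    base = base + rng.normal(0.0, 0.3, size=cfg.n_genes)
    sd = np.where(planted, 2.5, np.where(housekeeping, 0.3, 1.0))
    values = base[:, None] + rng.normal(size=(cfg.n_genes, cfg.n_cell_lines)) * sd[:, None]
    samples = [f"LINE{i:03d}" for i in range(cfg.n_cell_lines)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), platform="bulk_log"
    )
    truth = GeneSet("expressed_variable", frozenset(np.asarray(genes)[planted]))
    return matrix, truth


# ---------------------------------------------------------------------------
# Single-cell CTC FPKM matrix
# ---------------------------------------------------------------------------

def simulate_ctc_singlecell(cfg: SimConfig) -> tuple[ExpressionMatrix, GeneSet]:
    """Simulate a sparse FPKM-like single-CTC matrix: lognormal signal for an
    expressed subset, multiplicative per-cell library-size factors, and a
    ``sc_dropout`` fraction of entries forced to exactly zero.

    Returns the matrix and the planted expressed-gene truth set.
    """
    cfg.validate()
    rng = cfg.rng("sc")
    genes = gene_ids(cfg.n_genes)
    n_expr = int(round(cfg.frac_expressed_variable * cfg.n_genes))
    expr_idx = _planted_order(cfg)[:n_expr]
    expressed = np.zeros(cfg.n_genes, dtype=bool)
    expressed[expr_idx] = True

    log_mean = np.where(expressed, 4.0, 0.5)
    log_sd = np.where(expressed, 1.2, 0.6)
    values = rng.lognormal(
        mean=log_mean[:, None], sigma=log_sd[:, None], size=(cfg.n_genes, cfg.sc_n_cells)
    )
    libsize = rng.lognormal(mean=0.0, sigma=0.4, size=cfg.sc_n_cells)
    values *= libsize[None, :]
    dropout = rng.random(size=values.shape) < cfg.sc_dropout
    values[dropout] = 0.0
    samples = [f"CTC{i:03d}" for i in range(cfg.sc_n_cells)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), platform="fpkm"
    )
    truth = GeneSet("sc_expressed", frozenset(np.asarray(genes)[expressed]))
    return matrix, truth


# ---------------------------------------------------------------------------
# Database annotations
# ---------------------------------------------------------------------------

def simulate_annotations(genes: Sequence[str], cfg: SimConfig) -> GeneAnnotation:
    """Draw per-gene membrane/immune flags and ordinal IHC levels.

    Membership in the two membrane databases is drawn jointly so that a
    ``frac_membrane_both`` fraction is flagged by both and ``frac_membrane_one``
    by exactly one; the GO plasma-membrane flag is set for any
    membrane-flagged gene.  ``frac_ihc_high`` controls the fraction of genes
    whose IHC profile is biased towards medium/high levels.
    """
    cfg.validate()
    if len(set(genes)) != len(genes):
        raise InputError("gene ids must be unique")
    rng = cfg.rng("annot")
    n = len(genes)
    u = rng.random(n)
    both = u < cfg.frac_membrane_both
    one = (~both) & (u < cfg.frac_membrane_both + cfg.frac_membrane_one)
    which = rng.random(n) < 0.5  # which single database flags the "one" genes
    membrane_db1 = both | (one & which)
    membrane_db2 = both | (one & ~which)
    immune_db1 = rng.random(n) < cfg.frac_immune
    immune_db2 = rng.random(n) < cfg.frac_immune / 2.0
    go_pm = membrane_db1 | membrane_db2

    high_biased = rng.random(n) < cfg.frac_ihc_high
    # Per-sample ordinal levels: high-biased genes mostly medium/high.
    p_high = np.array([[0.05, 0.15, 0.40, 0.40]])
    p_low = np.array([[0.55, 0.30, 0.10, 0.05]])
    probs = np.where(high_biased[:, None], p_high, p_low)
    cum = np.cumsum(probs, axis=1)
    draws = rng.random((n, cfg.n_ihc_samples))
    level_idx = (draws[:, :, None] > cum[:, None, :]).sum(axis=2)
    ihc = [tuple(IHC_LEVELS[j] for j in row) for row in level_idx]

    return GeneAnnotation.from_records(
        genes, membrane_db1, membrane_db2, immune_db1, immune_db2, go_pm, ihc
    )


def annotation_with_counts(
    genes: Sequence[str],
    n_membrane_both: int = 26,
    n_membrane_one: int = 4,
    n_immune_among_membrane: int = 11,
    n_ihc_pass: int = 12,
    n_ihc_samples: int = 4,
) -> GeneAnnotation:
    """Construct a deterministic annotation table realising an exact in
    silico sorting count sequence.

    With the defaults, applied to 50 genes, the three sorting sub-stages keep
    30 (26 flagged by both membrane databases + 4 by exactly one), then 19
    (11 of the 30 are immune-expressed), then 12 (of the 19 survivors, 12
    show medium-or-high IHC in at least half the samples).
    """
    genes = [str(g) for g in genes]
    if len(set(genes)) != len(genes):
        raise InputError("gene ids must be unique")
    n_membrane = n_membrane_both + n_membrane_one
    if n_membrane > len(genes):
        raise InputError("membrane counts exceed number of genes")
    n_kept_after_immune = n_membrane - n_immune_among_membrane
    if n_ihc_pass > n_kept_after_immune:
        raise InputError("n_ihc_pass exceeds genes surviving immune exclusion")

    membrane_db1 = [i < n_membrane for i in range(len(genes))]
    membrane_db2 = [i < n_membrane_both for i in range(len(genes))]
    # Flag the tail of the membrane block as immune so the both/one split of
    # survivors is unconstrained.
    immune_db1 = [n_kept_after_immune <= i < n_membrane for i in range(len(genes))]
    immune_db2 = [False] * len(genes)
    go_pm = [True] * len(genes)
    high = ("high",) * n_ihc_samples
    low = ("not_detected",) * n_ihc_samples
    ihc = [high if i < n_ihc_pass else low for i in range(len(genes))]
    return GeneAnnotation.from_records(
        genes, membrane_db1, membrane_db2, immune_db1, immune_db2, go_pm, ihc
    )


# ---------------------------------------------------------------------------
# Protein sequences
# ---------------------------------------------------------------------------

#: Residue pools for the antigenic-biased sequence class.  Antigenic
#: sequences are built from alternating charged/polar and hydrophobic
#: patches (epitope-like segments), which leaves positive short-lag
#: autocovariance in the centred z-descriptors; background sequences are
#: i.i.d. over all 20 residues and carry no lag structure.  Composition
#: alone would not separate the classes because the ACC transform centres
#: each descriptor per sequence.
_CHARGED_POOL = "DEKRNQH"
_HYDROPHOBIC_POOL = "AVLIFMW"
_PATCH_MEAN_LENGTH = 6


def _antigenic_sequence(rng: np.random.Generator, length: int) -> str:
    out: list[str] = []
    state = bool(rng.integers(0, 2))
    while len(out) < length:
        pool = _CHARGED_POOL if state else _HYDROPHOBIC_POOL
        run = int(rng.geometric(1.0 / _PATCH_MEAN_LENGTH))
        out.extend(pool[i] for i in rng.integers(0, len(pool), size=run))
        state = not state
    return "".join(out[:length])


def simulate_proteins(
    genes: Sequence[str],
    cfg: SimConfig,
    mode: str = "mixed",
) -> tuple[list, GeneSet]:
    """Simulate one amino-acid sequence per gene over the 20-residue alphabet.

    ``mode='mixed'`` builds a ``frac_antigenic`` fraction of genes from
    alternating charged/hydrophobic patches (labelled antigenic in the
    returned truth set) and the remainder as i.i.d. background sequences.
    ``mode='homopolymer'`` emits single-residue sequences (useful because the
    centred ACC transform maps them to the zero vector).

    Returns ``(records, truth)`` where records are Biopython ``SeqRecord``
    objects writable as FASTA with the gene id as header.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    cfg.validate()
    genes = [str(g) for g in genes]
    if len(set(genes)) != len(genes):
        raise InputError("gene ids must be unique")
    rng = cfg.rng("proteins")
    lo, hi = cfg.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=len(genes))
    aa = np.array(list(AMINO_ACIDS))

    records = []
    antigenic: set[str] = set()
    if mode == "homopolymer":
        for gene, length in zip(genes, lengths):
            residue = aa[rng.integers(0, len(aa))]
            records.append(SeqRecord(Seq(str(residue) * int(length)), id=gene, description=""))
        return records, GeneSet("antigenic_truth", frozenset())
    if mode != "mixed":
        raise ConfigurationError(f"unknown protein simulation mode {mode!r}")

    is_antigenic = rng.random(len(genes)) < cfg.frac_antigenic
    for gene, length, flag in zip(genes, lengths, is_antigenic):
        if flag:
            seq = _antigenic_sequence(rng, int(length))
            antigenic.add(gene)
        else:
            seq = "".join(aa[rng.integers(0, len(aa), size=int(length))])
        records.append(SeqRecord(Seq(seq), id=gene, description=""))
    return records, GeneSet("antigenic_truth", frozenset(antigenic))


# ---------------------------------------------------------------------------
# Clinical-cohort cell records
# ---------------------------------------------------------------------------

CONVENTIONAL_PANEL = ("EPCAM", "CK")
COCKTAIL_PANEL = ("MARCKSL1", "SLC9A3R1", "RHOD")


def _draw_stains(
    rng: np.random.Generator,
    panel: tuple[str, ...],
    sensitivity: float,
    high_given_positive: float,
) -> dict[str, str]:
    """Draw a marker->level map for one atypical cell under a panel.

    The cell is detected by the panel with probability ``sensitivity``; a
    detected cell has one uniformly-chosen member marker positive (high with
    probability ``high_given_positive``, else low), each other marker
    independently positive with a reduced probability.
    """
    stains = {m: "negative" for m in panel}
    if rng.random() < sensitivity:
        primary = panel[rng.integers(0, len(panel))]
        stains[primary] = "high" if rng.random() < high_given_positive else "low"
        for m in panel:
            if m != primary and rng.random() < 0.3:
                stains[m] = "high" if rng.random() < high_given_positive else "low"
    return stains


def simulate_cohort_cells(cfg: CohortSimConfig, seed: int) -> pd.DataFrame:
    """Simulate per-cell feature tables for a patient and a donor cohort.

    Each subject contributes two isolation supports (one stained with the
    conventional EpCAM+CK panel, one with the three-marker cocktail).  Each
    support carries ``leukocytes_per_support`` leukocyte-morphology cells
    (intense homogeneous CD45, small, regular, N/C <= 0.75) and a Poisson
    number of atypical cells (no intense homogeneous CD45, larger than the
    leukocyte mean, irregular nucleus, N/C > 0.75) whose marker staining is
    drawn with the panel's sensitivity.
    """
    cfg.validate()
    rng = np.random.default_rng([int(seed), _STREAMS["cohort"]])
    rows: list[dict] = []
    supports = (
        ("conv", CONVENTIONAL_PANEL, cfg.conventional_sensitivity),
        ("cocktail", COCKTAIL_PANEL, cfg.cocktail_sensitivity),
    )
    subjects = [("patient", f"P{i:03d}", cfg.patient_ac_mean) for i in range(cfg.n_patients)]
    subjects += [("donor", f"D{i:03d}", cfg.donor_ac_mean) for i in range(cfg.n_donors)]

    for cohort, subject, ac_mean in subjects:
        for panel_name, panel, sensitivity in supports:
            support_id = f"{subject}-{panel_name}"
            for k in range(cfg.leukocytes_per_support):
                rows.append(
                    {
                        "cell_id": f"{support_id}-L{k:03d}",
                        "subject_id": subject,
                        "support_id": support_id,
                        "cohort": cohort,
                        "panel": panel_name,
                        "diameter": max(float(rng.normal(9.0, 1.0)), 5.0),
                        "nc_ratio": float(rng.uniform(0.40, 0.75)),
                        "nuclear_irregular": False,
                        "cd45_intensity": "intense",
                        "cd45_homogeneous": True,
                        "marker_stains": ";".join(f"{m}=negative" for m in sorted(panel)),
                    }
                )
            n_ac = int(rng.poisson(ac_mean))
            for k in range(n_ac):
                stains = _draw_stains(rng, panel, sensitivity, cfg.high_given_positive)
                rows.append(
                    {
                        "cell_id": f"{support_id}-A{k:03d}",
                        "subject_id": subject,
                        "support_id": support_id,
                        "cohort": cohort,
                        "panel": panel_name,
                        "diameter": max(float(rng.normal(16.0, 2.0)), 12.5),
                        "nc_ratio": float(rng.uniform(0.76, 0.98)),
                        "nuclear_irregular": True,
                        "cd45_intensity": "negative" if rng.random() < 0.8 else "weak",
                        "cd45_homogeneous": False,
                        "marker_stains": ";".join(
                            f"{m}={stains[m]}" for m in sorted(stains)
                        ),
                    }
                )
    df = pd.DataFrame(rows)
    from .containers import validate_cells

    return validate_cells(df)
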