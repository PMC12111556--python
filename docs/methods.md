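# Methods

This note documents the models and procedures implemented in `ctcmark`, the
assumptions behind them, the parameters that matter, and what the synthetic
data do and do not establish.

## Differential expression (`diffexp`)

Each gene is modelled as a two-group linear model on log2-scale intensities:
tumor (BT) vs adjacent tissue (BNT), no covariates. The per-gene residual
variance s²_g has d = n₁ + n₂ − 2 degrees of freedom and is shrunk towards a
common prior by empirical Bayes,

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),

with (d₀, s₀²) estimated by the method of moments on log s²_g: under the
scaled-F hierarchy, e_g = log s²_g − ψ(d/2) + log(d/2) has mean
log s₀² + ψ(d₀/2) − log(d₀/2) and excess variance ψ′(d₀/2) beyond ψ′(d/2), so
d₀ solves a trigamma equation (Newton iteration; when the observed excess
variance is non-positive, d₀ = ∞ and every gene gets s₀²). The moderated t is
referred to a t distribution with d₀ + d df (normal when d₀ = ∞). Setting
`prior_df=0` disables shrinkage and reproduces the classical pooled-variance
t exactly — this limit is the main numerical cross-check.

Degenerate inputs: genes with zero residual variance are assigned the
smallest positive s²_g before prior estimation (logged); if *every* gene has
zero variance the estimator is undefined and the routine falls back to a
degenerate ordinary t (t = ±∞, p ∈ {0, 1}) with a warning.

BH adjustment is the standard step-up procedure (sort, scale by m/i,
right-to-left running minimum, clip at 1) and is tested against an O(n²)
brute-force definition. Upregulation requires log₂FC > 0 *and* FDR below the
threshold (default 0.05, config-exposed); no fold-change cutoff is applied
beyond the sign.

## The overmean selector (`geneselect.overmean`)

A gene is "expressed and variable" iff its across-sample mean strictly
exceeds the grand mean of all matrix entries **and** its unbiased
between-sample variance strictly exceeds a reference variance. The reference
defaults to the mean of the per-gene variances; the pooled variance of all
entries is available via `refvar='total_var'` because the prose definition of
this style of filter admits both readings (the two coincide in expectation
for complete, balanced matrices). Strict inequalities mean a constant matrix
selects nothing. The rule is invariant to adding a constant to the whole
matrix and to positive rescaling — both are tested properties, alongside
exact set equality with a per-gene brute-force loop.

## Antigenicity (`antigenicity`)

Sequences are featurised by the auto/cross-covariance (ACC) transform of
three per-residue z-scale descriptors (z1 hydrophobicity, z2 steric bulk,
z3 polarity; the classical 3-component principal-property scales, embedded
as a versioned constant). For descriptor pair (j, k) and lag l ∈ 1..L,

    A_jk(l) = Σ_{i=1}^{n−l} (z_j(i) − z̄_j)(z_k(i+l) − z̄_k) / (n − l),

with per-sequence mean-centering, giving a 9·L vector (L = 8 by default,
so 72 components; sequences must be longer than L). Centering forces
homopolymers to the zero vector and makes the transform invariant to
constant shifts of a descriptor column — both tested.

The discriminant on top of the ACC space is a standardised, L2-regularised
logistic regression (`LinearHead`), trained on labelled synthetic sequences
and serialised as JSON (weights, intercept, standardisation, lag, scale-table
version). The published server-side discriminant for this kind of scoring is
not available, so the head is deliberately pluggable: externally derived
weights in the same JSON schema can be dropped in. Scores are probabilities;
the cascade keeps sequences with score ≥ 0.5 (config-exposed). Consequently
the *count* of genes surviving the antigenicity stage on synthetic data is
not comparable to any external tool's output; only the stage's shape
(a score-threshold filter that never increases the gene count) and the
transform itself are validated.

Ambiguous residues are rejected by default; `strip_x=True` removes X before
the transform.

## CTC calling (`ctc_call`)

Four conjunctive criteria define an atypical cell (AC), evaluated against
the leukocytes on the same isolation support (IS; the membrane retaining
size-selected cells after 3 mL blood filtration):

1. CD45 not (intense AND homogeneous) — weak or heterogeneous CD45 does not
   bar AC status;
2. diameter strictly greater than the support's mean leukocyte diameter
   (arithmetic mean of CD45-intense+homogeneous cells; supports without
   leukocytes fall back to a 12 µm default, logged);
3. irregular nuclear outline (a pre-extracted boolean; image analysis is out
   of scope);
4. nuclear/cytoplasmic ratio strictly greater than 0.75 — a cell at exactly
   0.75 is not atypical.

An AC is a **CTC** when any panel marker stains low or high (`panel_mode
'any'`; an `'all'` mode exists for sensitivity analysis), otherwise a
**potential CTC**. The implementation is tested for exact equivalence with a
32-case truth-table enumeration, for monotonicity (making one feature more
atypical never switches a positive call off), and for panel monotonicity
(adding a marker never lowers the CTC count).

## Cohort statistics (`cohort_stats`)

Positivity columns report the percentage of evaluated cells in each staining
category; a cocktail's category is the max of its members' categories
(high > low > negative), so single markers and cocktails share one rule and
cocktail positivity is never below the best member. `positive = low + high`
and `negative + low + high = 100` hold by construction for tables computed
from cells; `PositivityTable.from_percentages` applies the same positive-row
arithmetic to externally supplied category rows. Percent stained is averaged
per subject then across subjects (matching per-patient dot-plot
presentation); subjects without any AC are excluded from that average and
logged. SEM = sd/√n; for a single subject SEM is undefined and reported as 0
with an explicit flag.

Paired and unpaired Student t-tests use the textbook closed forms (paired on
differences; unpaired pooled-variance), two-sided, no multiple-testing
correction (single planned comparisons). Zero-variance inputs are flagged
degenerate with p = 1 (no shift) or the 0-limit. Null calibration is tested:
over 10⁴ Gaussian null replicates the empirical type-I error of both tests
must lie in [0.04, 0.06] at α = 0.05.

## Synthetic data (`simdata`)

All generators are deterministic given (config, seed); each consumer-facing
dataset ships with its planted truth. Per-generator substreams are derived
from the base seed so datasets can be regenerated independently.

- **Bulk matrix**: per-gene Gaussian baselines (mean 7, sd 1.5 on a log2-like
  scale) plus i.i.d. noise (sd 0.5, typical of normalised arrays); planted
  DEGs get +2 log2 units in tumor samples. Defaults: 2000 genes, 20+20
  samples, 200 DEGs.
- **Cell-line panel**: planted genes are high-mean/high-variance; the null
  background is bimodal — stably expressed genes (high mean, low variance)
  and noisy low-expressed genes (low mean, higher variance) — mirroring the
  mean–variance structure of real arrays. This makes the planted subset the
  only joint mean-and-variance outliers, so the overmean selector is nearly
  exact on the simulation; on real data, where the mean–variance relation is
  continuous, its false-positive rate will be higher.
- **Single-CTC matrix**: lognormal FPKM signal for an expressed subset,
  per-cell lognormal library-size factors, Bernoulli dropout (default 0.6)
  zeroing entries exactly.
- **Shared planted pool**: the bulk, cell-line and single-cell generators
  take their planted subsets as prefixes of one shared permutation, because
  real marker genes carry all three properties at once; independent draws
  would make the cascade's intersections empty by construction.
- **Proteins**: antigenic-class sequences are built from alternating
  charged/polar and hydrophobic patches (geometric run length, mean 6),
  leaving positive short-lag autocovariance in the centred descriptors;
  background sequences are i.i.d. Composition differences alone would be
  removed by ACC centering, so patchiness is the planted signal. This is a
  stand-in for real antigenicity structure, not a model of epitopes.
- **Cohort cells**: each subject contributes two isolation supports (one per
  staining panel), each with a fixed number of leukocytes (default 40;
  reported only as "a small fraction" in the motivating study, so a constant
  is used) and a Poisson number of ACs per 3 mL (patients mean 27.14, donors
  0.77 — the motivating cohort's aggregates; no per-patient table exists, so
  the defaults are calibrated to those means). AC staining is drawn per
  panel with per-cell sensitivities 0.6582 (EpCAM+CK) and 0.9959
  (MARCKSL1+SLC9A3R1+RHOD), echoing the reported staining efficiencies; a
  detected cell stains high with probability 0.7.

What passing tests show: the pipeline's logic, statistics and determinism
are correct on data whose generating process matches the filters'
assumptions. What they do not show: performance on real arrays (probe-level
artefacts, batch effects, correlated genes), real single-cell data
(zero-inflation tied to expression level), or real cytomorphology (feature
extraction from images is out of scope).

## Numerical and design choices

- Trigamma inversion by Newton iteration with asymptotic guards
  (y > 10⁷ → 1/√y; y < 10⁻⁶ → 1/y), tolerance 10⁻¹⁰ relative.
- Membrane rule defaults to `at_least_one` database (not discarding
  single-database candidates); `both_dbs` retained for sensitivity analysis.
- The IHC criterion "intermediate or high in several tumor samples" is
  operationalised as ≥ medium in ≥ 50% of annotated samples; both knobs are
  config-exposed because "several" is not quantified.
- Genes missing from the annotation table fail every annotation filter
  (conservative fail-closed), logged.
- Ledgers and reports are serialised with sorted keys and fixed float
  formats so identical (config, seed) runs are byte-identical.
- Problem sizes in the test suite and acceptance script (hundreds to a few
  thousand genes, tens of subjects, 10⁴ null replicates) were chosen so the
  full suite runs in seconds while keeping every statistical check
  well-powered.

## Known limitations

- The antigenicity head is trained on synthetic patch-structured sequences;
  its scores have no external biological calibration.
- The cohort generator draws each support's AC count independently; real
  supports from one blood draw are correlated.
- No survival analysis, enrichment services, ID mapping or image analysis;
  annotation tables stand in for live database queries.
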