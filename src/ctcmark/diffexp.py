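"""Two-group differential expression with an empirical-Bayes moderated
t-statistic and Benjamini-Hochberg FDR control.

The per-gene model is a two-group linear model (tumor BT vs adjacent BNT):
the effect is the log2 mean difference, the residual variance ``s2_g`` has
``d = n1 + n2 - 2`` degrees of freedom, and the gene variances are shrunk
towards a common prior by empirical Bayes:

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)

with the prior ``(d0, s0^2)`` estimated by the method of moments on
``log s2_g`` (matching a scaled-F / log-chi-square hierarchy).  The moderated
t is the effect over its shrunk standard error, referred to a t distribution
with ``d0 + d`` degrees of freedom (normal when ``d0`` is infinite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, GeneSet, GroupDesign
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class DEGTable:
    """Per-gene differential-expression results.

    ``table`` columns: ``log2fc`` (BT - BNT), ``t_mod``, ``df_total``, ``p``,
    ``fdr``, ``upregulated``.  ``prior_df``/``prior_var`` are the estimated
    empirical-Bayes hyperparameters (``inf`` prior_df means full shrinkage).
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    fdr_threshold: float = 0.05

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts, multiplies p_(i) by m/i, enforces monotonicity by a right-to-left
    running minimum, clips at 1, and restores the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * abs(x):
            break
    return float(x)


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment estimation of the variance prior (d0, s0^2) on log s2."""
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    fdr_threshold: float = 0.05,
    prior_df: float | None = None,
    group_test: str = "BT",
    group_ref: str = "BNT",
) -> DEGTable:
    """Moderated two-group t-test per gene with BH-FDR adjustment.

    Parameters
    ----------
    prior_df : float, optional
        Override the estimated prior degrees of freedom.  ``0`` disables
        shrinkage entirely, reducing the statistic to the ordinary
        pooled-variance two-sample t.
    """
    design.validate_against(matrix, min_per_group=2)
    for g in (group_test, group_ref):
        if g not in design.groups:
            raise InputError(f"design has no group {g!r}")
    x1 = matrix.values[[s for s in matrix.sample_ids if design.labels[s] == group_test]]
    x2 = matrix.values[[s for s in matrix.sample_ids if design.labels[s] == group_ref]]
    n1, n2 = x1.shape[1], x2.shape[1]
    a1, a2 = x1.to_numpy(float), x2.to_numpy(float)
    df_resid = n1 + n2 - 2

    log2fc = a1.mean(axis=1) - a2.mean(axis=1)
    s2 = (a1.var(axis=1, ddof=1) * (n1 - 1) + a2.var(axis=1, ddof=1) * (n2 - 1)) / df_resid

    zero = s2 <= 0
    if zero.all():
        logger.warning(
            "all genes have zero residual variance; prior estimation impossible, "
            "falling back to an ordinary t on degenerate variances"
        )
        t = np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.inf)
        p = np.where(log2fc == 0, 1.0, 0.0)
        fdr = bh_adjust(p)
        table = _assemble(matrix.gene_ids, log2fc, t, float(df_resid), p, fdr, fdr_threshold)
        return DEGTable(table, prior_df=0.0, prior_var=0.0, fdr_threshold=fdr_threshold)
    if zero.any():
        smallest = s2[~zero].min()
        logger.warning(
            "%d genes with zero residual variance; substituting smallest positive s2=%g",
            int(zero.sum()),
            smallest,
        )
        s2 = np.where(zero, smallest, s2)

    if prior_df is None:
        d0, s02 = _fit_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s02 = float(np.mean(s2)) if d0 > 0 else 0.0

    if d0 == 0:
        s2_post = s2
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = log2fc / se
    df_total = d0 + df_resid
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    fdr = bh_adjust(p)
    table = _assemble(matrix.gene_ids, log2fc, t, float(df_total), p, fdr, fdr_threshold)
    return DEGTable(table, prior_df=float(d0), prior_var=float(s02), fdr_threshold=fdr_threshold)


def _assemble(genes, log2fc, t, df_total, p, fdr, threshold) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "fdr": fdr,
            "upregulated": (log2fc > 0) & (fdr < threshold),
        },
        index=pd.Index(genes, name="gene_id"),
    )


def select_upregulated(deg: DEGTable, fdr_threshold: float | None = None) -> GeneSet:
    """Genes with positive effect and FDR below the threshold."""
    thr = deg.fdr_threshold if fdr_threshold is None else fdr_threshold
    mask = (deg.table["log2fc"] > 0) & (deg.table["fdr"] < thr)
    return GeneSet("upregulated", frozenset(deg.table.index[mask]))
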