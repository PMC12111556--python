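"""Marker and cocktail positivity tables, cohort summaries (mean, SEM,
median) and paired/unpaired Student t-tests for the clinical comparison of
staining panels.

A positivity column reports the percentage of evaluated cells staining
negative, low and high for a marker or a cocktail; positive = low + high.
A cocktail column aggregates member markers with high > low > negative
precedence (a cell is high if any member is high, else low if any member is
low, else negative), which makes any-member positivity and the single-marker
rule one computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import parse_stains
from .errors import InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Positivity tables
# ---------------------------------------------------------------------------

@dataclass
class PositivityTable:
    """Per marker-or-cocktail staining category percentages.

    ``table`` rows: ``pct_negative``, ``pct_low``, ``pct_high``,
    ``pct_positive``; one column per marker or cocktail.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="category", float_format="%.4f")

    @classmethod
    def from_percentages(cls, columns: Mapping[str, tuple[float, float, float]]) -> "PositivityTable":
        """Build a table from published-style (negative, low, high) rows;
        the positive row is computed as low + high."""
        data = {}
        for name, (neg, low, high) in columns.items():
            data[name] = {
                "pct_negative": float(neg),
                "pct_low": float(low),
                "pct_high": float(high),
                "pct_positive": float(low) + float(high),
            }
        return cls(pd.DataFrame(data))


def _cocktail_level(stains: dict[str, str], members: Sequence[str], cell_id: str) -> str:
    levels = []
    for m in members:
        if m not in stains:
            raise InputError(f"cell {cell_id!r}: no stain recorded for marker {m!r}")
        levels.append(stains[m])
    if "high" in levels:
        return "high"
    if "low" in levels:
        return "low"
    return "negative"


def positivity_table(
    cells: pd.DataFrame,
    markers: Sequence[str] = (),
    cocktails: Mapping[str, Sequence[str]] | None = None,
) -> PositivityTable:
    """Category percentages over evaluated cells for single markers and
    cocktails.

    ``cells`` must carry a ``marker_stains`` column covering every requested
    marker.  Raises on an empty cell set.
    """
    if len(cells) == 0:
        raise InputError("positivity table requires at least one cell")
    cocktails = dict(cocktails or {})
    stain_maps = [
        (cid, parse_stains(s)) for cid, s in zip(cells["cell_id"], cells["marker_stains"])
    ]
    columns: dict[str, dict[str, float]] = {}
    specs = [(m, (m,)) for m in markers] + list(cocktails.items())
    n = len(stain_maps)
    for name, members in specs:
        counts = {"negative": 0, "low": 0, "high": 0}
        for cid, stains in stain_maps:
            counts[_cocktail_level(stains, members, cid)] += 1
        pct = {k: 100.0 * v / n for k, v in counts.items()}
        columns[name] = {
            "pct_negative": pct["negative"],
            "pct_low": pct["low"],
            "pct_high": pct["high"],
            "pct_positive": pct["low"] + pct["high"],
        }
    return PositivityTable(pd.DataFrame(columns))


def pct_unlabeled(pct_positive: float) -> float:
    """Percentage of cells a panel leaves unlabeled: 100 - positive."""
    return 100.0 - pct_positive


def efficiency_gap(pct_a: float, pct_b: float) -> float:
    """How many percentage points more efficient panel a is than panel b."""
    return pct_a - pct_b


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def _summarise(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        return {"mean": np.nan, "sem": np.nan, "median": np.nan, "n": 0}
    out = {
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "n": int(n),
    }
    if n == 1:
        # SEM undefined for a single subject; reported as 0 with a flag.
        out["sem"] = 0.0
        out["sem_defined"] = False
    else:
        out["sem"] = float(np.std(values, ddof=1) / np.sqrt(n))
        out["sem_defined"] = True
    return out


def cohort_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-subject calls to cohort x panel summaries.

    Input: the ``per_subject`` frame of :class:`~ctcmark.ctc_call.CohortCalls`
    (columns subject_id, cohort, panel, n_ac, n_ctc, pct_stained).  Subjects
    without any atypical cell are excluded from the percent-stained average
    (logged) but still counted for AC/CTC means.
    """
    rows = []
    for (cohort, panel), grp in per_subject.groupby(["cohort", "panel"], sort=True):
        n_zero = int((grp["n_ac"] == 0).sum())
        if n_zero:
            logger.info(
                "%s/%s: %d subjects with no atypical cell excluded from "
                "percent-stained averaging",
                cohort,
                panel,
                n_zero,
            )
        for stat_name, values in (
            ("n_ac", grp["n_ac"].to_numpy(float)),
            ("n_ctc", grp["n_ctc"].to_numpy(float)),
            ("pct_stained", grp["pct_stained"].to_numpy(float)),
        ):
            summary = _summarise(values)
            rows.append({"cohort": cohort, "panel": panel, "quantity": stat_name, **summary})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Student t-tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    paired: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "paired": self.paired,
            "degenerate": self.degenerate,
        }


def paired_t(x, y) -> TestResult:
    """Classical paired Student t-test (two-sided) on the differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired test requires equal-length 1-D vectors")
    if x.size < 2:
        raise InputError("paired test requires at least 2 pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        # Zero variance of differences: p = 1 when there is no shift,
        # otherwise the 0-limit, flagged as degenerate.
        mean = float(d.mean())
        return TestResult(
            statistic=0.0 if mean == 0 else np.sign(mean) * np.inf,
            df=float(df),
            p=1.0 if mean == 0 else 0.0,
            paired=True,
            degenerate=True,
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(statistic=t, df=float(df), p=min(p, 1.0), paired=True)


def unpaired_t(x, y) -> TestResult:
    """Classical pooled-variance two-sample Student t-test (two-sided)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise InputError("unpaired test requires two 1-D vectors of length >= 2")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = float(x.mean() - y.mean())
    if sp2 == 0:
        return TestResult(
            statistic=0.0 if diff == 0 else np.sign(diff) * np.inf,
            df=float(df),
            p=1.0 if diff == 0 else 0.0,
            paired=False,
            degenerate=True,
        )
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=float(df), p=min(p, 1.0), paired=False)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(
    out_dir: str | Path,
    cascade_ledger: dict | None = None,
    positivity: PositivityTable | None = None,
    summary: pd.DataFrame | None = None,
    tests: Mapping[str, TestResult] | None = None,
) -> tuple[Path, Path]:
    """Write a machine-readable JSON report and a human-readable text
    summary; byte-identical across runs given identical inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload: dict = {}
    payload["cascade"] = cascade_ledger if cascade_ledger else {"stages": []}
    if positivity is not None:
        payload["positivity"] = {
            col: {k: round(float(v), 6) for k, v in positivity.table[col].items()}
            for col in positivity.table.columns
        }
    else:
        payload["positivity"] = {}
    if summary is not None and len(summary):
        payload["cohort_summary"] = [
            {k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
            for row in summary.to_dict(orient="records")
        ]
    else:
        payload["cohort_summary"] = []
        payload["note"] = "no subjects"
    payload["tests"] = {name: t.to_dict() for name, t in (tests or {}).items()}

    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    lines = ["CTC marker report", "=" * 40, ""]
    if payload["cascade"]["stages"]:
        lines.append("Cascade stages (input -> output):")
        for st in payload["cascade"]["stages"]:
            lines.append(f"  {st['name']}: {st['n_in']} -> {st['n_out']}  [{st['criterion']}]")
        lines.append("")
    if payload["positivity"]:
        lines.append("Staining positivity (% of cells):")
        for col, vals in payload["positivity"].items():
            lines.append(
                f"  {col}: negative {vals['pct_negative']:.2f}  low {vals['pct_low']:.2f}  "
                f"high {vals['pct_high']:.2f}  positive {vals['pct_positive']:.2f}"
            )
        lines.append("")
    if payload["cohort_summary"]:
        lines.append("Cohort summaries (mean +/- SEM, median, n):")
        for row in payload["cohort_summary"]:
            lines.append(
                f"  {row['cohort']}/{row['panel']} {row['quantity']}: "
                f"{row['mean']:.2f} +/- {row['sem']:.2f} (median {row['median']:.2f}, n={row['n']})"
            )
        lines.append("")
    else:
        lines.append("No subjects in cohort.")
        lines.append("")
    if payload["tests"]:
        lines.append("Student t-tests:")
        for name, t in payload["tests"].items():
            kind = "paired" if t["paired"] else "unpaired"
            lines.append(f"  {name} ({kind}): t={t['statistic']:.4g}, df={t['df']:.4g}, p={t['p']:.4g}")
    text_path = out_dir / "report.txt"
    text_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return json_path, text_path
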