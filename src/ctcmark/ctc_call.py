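"""Rule-based classification of isolated cells.

A captured cell is an atypical cell (AC) when all four cytomorphological
criteria hold relative to the leukocytes on the same isolation support:
(1) no intense AND homogeneous CD45 staining, (2) diameter strictly larger
than the support's mean leukocyte diameter, (3) irregular nuclear outline,
and (4) nuclear/cytoplasmic ratio strictly above 0.75.  An AC positive for
any panel marker (low or high stain) is a CTC; a marker-negative AC is a
potential CTC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import parse_stains, validate_cells
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

POSITIVE_LEVELS = ("low", "high")


@dataclass
class CTCDecisionRules:
    """Thresholds and panel for atypical-cell and CTC calling."""

    nc_ratio_min: float = 0.75
    panel: tuple[str, ...] = ("MARCKSL1", "SLC9A3R1", "RHOD")
    positive_levels: tuple[str, ...] = POSITIVE_LEVELS
    #: 'any' calls CTC when any panel marker is positive; 'all' requires all.
    panel_mode: str = "any"
    #: fallback mean leukocyte diameter (um) for supports without leukocytes.
    default_leukocyte_diameter: float = 12.0

    def validate(self) -> None:
        if not 0 < self.nc_ratio_min < 1:
            raise ConfigurationError("nc_ratio_min must lie in (0, 1)")
        if self.panel_mode not in ("any", "all"):
            raise ConfigurationError("panel_mode must be 'any' or 'all'")
        if not self.panel:
            raise ConfigurationError("panel must list at least one marker")


def is_leukocyte_morphology(cd45_intensity: str, cd45_homogeneous: bool) -> bool:
    """Intense AND homogeneous CD45 marks a leukocyte."""
    return cd45_intensity == "intense" and bool(cd45_homogeneous)


def leukocyte_mean_diameter(
    cells: pd.DataFrame, rules: CTCDecisionRules | None = None
) -> float:
    """Mean diameter of leukocyte-morphology cells on one support.

    Falls back to ``rules.default_leukocyte_diameter`` (logged) when the
    support carries no leukocyte.
    """
    rules = rules or CTCDecisionRules()
    mask = [
        is_leukocyte_morphology(i, h)
        for i, h in zip(cells["cd45_intensity"], cells["cd45_homogeneous"])
    ]
    diameters = cells.loc[mask, "diameter"]
    if diameters.empty:
        logger.warning(
            "support without leukocytes; using default leukocyte diameter %.1f um",
            rules.default_leukocyte_diameter,
        )
        return float(rules.default_leukocyte_diameter)
    return float(diameters.mean())


def call_atypical(cell: pd.Series | dict, rules: CTCDecisionRules, leuko_mean: float) -> dict:
    """Evaluate the four atypicality criteria for one cell.

    Returns ``{"cell_id", "atypical", "reasons"}`` where reasons maps each
    criterion to its truth value.  All four must hold; size and N/C ratio use
    strict inequalities.
    """
    rules.validate()
    reasons = {
        "cd45_not_leukocytic": not is_leukocyte_morphology(
            cell["cd45_intensity"], cell["cd45_homogeneous"]
        ),
        "larger_than_leukocytes": float(cell["diameter"]) > leuko_mean,
        "irregular_nucleus": bool(cell["nuclear_irregular"]),
        "high_nc_ratio": float(cell["nc_ratio"]) > rules.nc_ratio_min,
    }
    return {
        "cell_id": cell["cell_id"],
        "atypical": all(reasons.values()),
        "reasons": reasons,
    }


def call_ctc(stains: dict[str, str], rules: CTCDecisionRules, cell_id: str = "?") -> str:
    """Label an atypical cell ``CTC`` or ``potential_CTC`` from its panel
    staining; raises :class:`InputError` when a panel marker is missing."""
    rules.validate()
    flags = []
    for marker in rules.panel:
        if marker not in stains:
            raise InputError(f"cell {cell_id!r}: no stain recorded for marker {marker!r}")
        flags.append(stains[marker] in rules.positive_levels)
    positive = any(flags) if rules.panel_mode == "any" else all(flags)
    return "CTC" if positive else "potential_CTC"


def call_support(cells: pd.DataFrame, rules: CTCDecisionRules) -> pd.DataFrame:
    """Call every cell on one isolation support."""
    leuko_mean = leukocyte_mean_diameter(cells, rules)
    rows = []
    for _, cell in cells.iterrows():
        at = call_atypical(cell, rules, leuko_mean)
        if at["atypical"]:
            label = call_ctc(parse_stains(cell["marker_stains"]), rules, cell["cell_id"])
        else:
            label = "leukocyte"
        rows.append(
            {
                "cell_id": cell["cell_id"],
                "subject_id": cell["subject_id"],
                "support_id": cell["support_id"],
                "cohort": cell["cohort"],
                "panel": cell.get("panel", ""),
                "atypical": at["atypical"],
                "label": label,
                "reasons": ";".join(f"{k}={v}" for k, v in at["reasons"].items()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortCalls:
    """Per-cell calls plus per-support and per-subject aggregates."""

    calls: pd.DataFrame
    per_support: pd.DataFrame  # support_id, subject_id, cohort, panel, n_ac, n_ctc
    per_subject: pd.DataFrame  # subject_id, cohort, panel, n_ac, n_ctc, pct_stained


def call_cohort(cells: pd.DataFrame, rules: CTCDecisionRules | None = None) -> CohortCalls:
    """Call all cells of a cohort, grouped per isolation support.

    Per support: AC count (atypical cells per 3 mL) and CTC count.  Per
    subject (within a staining panel): summed counts and percent stained =
    100 * n_ctc / n_ac (NaN when the subject has no AC).
    """
    rules = rules or CTCDecisionRules()
    validate_cells(cells)
    call_frames = [
        call_support(group, rules) for _, group in cells.groupby("support_id", sort=True)
    ]
    calls = pd.concat(call_frames, ignore_index=True)

    per_support = (
        calls.groupby(["support_id", "subject_id", "cohort", "panel"], sort=True)
        .agg(
            n_ac=("atypical", "sum"),
            n_ctc=("label", lambda s: int((s == "CTC").sum())),
        )
        .reset_index()
    )
    per_subject = (
        per_support.groupby(["subject_id", "cohort", "panel"], sort=True)[["n_ac", "n_ctc"]]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_subject["pct_stained"] = np.where(
            per_subject["n_ac"] > 0,
            100.0 * per_subject["n_ctc"] / per_subject["n_ac"],
            np.nan,
        )
    return CohortCalls(calls=calls, per_support=per_support, per_subject=per_subject)
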