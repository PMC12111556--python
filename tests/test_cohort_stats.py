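"""Positivity tables, cohort summaries and Student t-tests: closed-form
hand examples, category-arithmetic invariants, and null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcmark import (
    CohortSimConfig,
    CTCDecisionRules,
    PositivityTable,
    call_cohort,
    cohort_summary,
    paired_t,
    positivity_table,
    render_report,
    unpaired_t,
)
from ctcmark.cohort_stats import efficiency_gap, pct_unlabeled
from ctcmark.containers import format_stains
from ctcmark.errors import InputError
from ctcmark.simdata import COCKTAIL_PANEL, simulate_cohort_cells


def _cells_from_levels(levels_per_cell, markers):
    rows = []
    for i, levels in enumerate(levels_per_cell):
        rows.append(
            {
                "cell_id": f"c{i}",
                "marker_stains": format_stains(dict(zip(markers, levels))),
            }
        )
    return pd.DataFrame(rows)


class TestPositivityTable:
    def test_single_marker_percentages(self):
        cells = _cells_from_levels(
            [("negative",)] * 2 + [("low",)] * 3 + [("high",)] * 5, ["M"]
        )
        tab = positivity_table(cells, markers=["M"]).table
        assert tab.loc["pct_negative", "M"] == 20.0
        assert tab.loc["pct_low", "M"] == 30.0
        assert tab.loc["pct_high", "M"] == 50.0
        assert tab.loc["pct_positive", "M"] == 80.0

    def test_categories_partition_and_positive_is_low_plus_high(self, rng):
        markers = ["A", "B"]
        levels = ["negative", "low", "high"]
        cells = _cells_from_levels(
            [tuple(rng.choice(levels, size=2)) for _ in range(137)], markers
        )
        tab = positivity_table(cells, markers=markers, cocktails={"AB": markers}).table
        for col in tab.columns:
            assert tab.loc["pct_negative", col] + tab.loc["pct_low", col] + tab.loc[
                "pct_high", col
            ] == pytest.approx(100.0, abs=0.01)
            assert tab.loc["pct_positive", col] == pytest.approx(
                tab.loc["pct_low", col] + tab.loc["pct_high", col], abs=0.01
            )

    def test_cocktail_uses_high_over_low_precedence(self):
        cells = _cells_from_levels(
            [("high", "low"), ("low", "negative"), ("negative", "negative")], ["A", "B"]
        )
        tab = positivity_table(cells, cocktails={"AB": ["A", "B"]}).table
        assert tab.loc["pct_high", "AB"] == pytest.approx(100 / 3)
        assert tab.loc["pct_low", "AB"] == pytest.approx(100 / 3)
        assert tab.loc["pct_negative", "AB"] == pytest.approx(100 / 3)

    def test_cocktail_positivity_at_least_max_member(self, rng):
        markers = ["A", "B", "C"]
        levels = ["negative", "low", "high"]
        cells = _cells_from_levels(
            [tuple(rng.choice(levels, size=3)) for _ in range(211)], markers
        )
        tab = positivity_table(cells, markers=markers, cocktails={"ABC": markers}).table
        member_max = max(tab.loc["pct_positive", m] for m in markers)
        assert tab.loc["pct_positive", "ABC"] >= member_max

    def test_all_negative_cells(self):
        cells = _cells_from_levels([("negative",)] * 4, ["M"])
        tab = positivity_table(cells, markers=["M"]).table
        assert tab.loc["pct_positive", "M"] == 0.0
        assert tab.loc["pct_negative", "M"] == 100.0

    def test_empty_cell_set_rejected(self):
        with pytest.raises(InputError):
            positivity_table(pd.DataFrame(columns=["cell_id", "marker_stains"]), markers=["M"])

    def test_missing_marker_rejected(self):
        cells = _cells_from_levels([("low",)], ["A"])
        with pytest.raises(InputError, match="'B'"):
            positivity_table(cells, markers=["B"])

    def test_from_percentages_computes_positive_row(self):
        tab = PositivityTable.from_percentages({"M": (34.4, 16.4, 49.2)}).table
        assert tab.loc["pct_positive", "M"] == pytest.approx(65.6)

    def test_complement_helpers(self):
        assert pct_unlabeled(69.2) == pytest.approx(30.8)
        assert efficiency_gap(99.59, 65.82) == pytest.approx(33.77)


class TestCohortSummary:
    def test_mean_and_sem_hand_example(self):
        per_subject = pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3"],
                "cohort": "patient",
                "panel": "cocktail",
                "n_ac": [1, 2, 3],
                "n_ctc": [1, 2, 3],
                "pct_stained": [100.0, 100.0, 100.0],
            }
        )
        summary = cohort_summary(per_subject)
        row = summary[(summary["quantity"] == "n_ac")].iloc[0]
        assert row["mean"] == 2.0
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-12)  # sd=1
        assert row["median"] == 2.0

    def test_single_subject_sem_flagged(self):
        per_subject = pd.DataFrame(
            {
                "subject_id": ["s1"],
                "cohort": "donor",
                "panel": "conv",
                "n_ac": [4],
                "n_ctc": [2],
                "pct_stained": [50.0],
            }
        )
        summary = cohort_summary(per_subject)
        row = summary[summary["quantity"] == "n_ac"].iloc[0]
        assert row["sem"] == 0.0
        assert not row["sem_defined"]

    def test_zero_ac_subjects_excluded_from_pct_average(self):
        per_subject = pd.DataFrame(
            {
                "subject_id": ["s1", "s2"],
                "cohort": "donor",
                "panel": "conv",
                "n_ac": [0, 2],
                "n_ctc": [0, 1],
                "pct_stained": [np.nan, 50.0],
            }
        )
        summary = cohort_summary(per_subject)
        row = summary[summary["quantity"] == "pct_stained"].iloc[0]
        assert row["n"] == 1
        assert row["mean"] == 50.0

    def test_panel_sensitivity_gap_reproduced_in_cohort_means(self):
        """With per-cell sensitivities echoing the two panels' reported
        efficiencies, the cohort percent-stained gap lands near 33.8 points."""
        cfg = CohortSimConfig(n_patients=40, n_donors=2)
        cells = simulate_cohort_cells(cfg, seed=21)
        pats = cells[cells["cohort"] == "patient"]
        means = {}
        for panel_name, panel in (("conv", ("CK", "EPCAM")), ("cocktail", COCKTAIL_PANEL)):
            sub = pats[pats["panel"] == panel_name]
            res = call_cohort(sub, CTCDecisionRules(panel=tuple(sorted(panel))))
            means[panel_name] = res.per_subject["pct_stained"].mean()
        gap = means["cocktail"] - means["conv"]
        assert abs(gap - 33.8) < 5.0


class TestStudentT:
    def test_identical_pairs_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_constant_shift_is_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.p == 0.0
        assert res.statistic == -np.inf

    def test_paired_matches_textbook_closed_form(self):
        x = np.array([3.0, 5.0, 4.0])
        y = np.array([1.0, 2.0, 2.0])
        # differences [2, 3, 2]: mean 7/3, sd sqrt(1/3), t = (7/3)/sqrt(1/9) = 7
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(7.0, abs=1e-12)
        assert res.df == 2
        ref = stats.ttest_rel(x, y)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_unpaired_matches_textbook_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        res = unpaired_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 4

    def test_input_contracts(self):
        with pytest.raises(InputError):
            paired_t([1.0], [2.0])
        with pytest.raises(InputError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            unpaired_t([1.0], [1.0, 2.0])


class TestRenderReport:
    def test_byte_identical_across_repeats(self, tmp_path):
        per_subject = pd.DataFrame(
            {
                "subject_id": ["s1", "s2"],
                "cohort": "patient",
                "panel": "cocktail",
                "n_ac": [3, 5],
                "n_ctc": [3, 4],
                "pct_stained": [100.0, 80.0],
            }
        )
        summary = cohort_summary(per_subject)
        tab = PositivityTable.from_percentages({"M": (20.0, 30.0, 50.0)})
        tests = {"demo": paired_t([1.0, 2.0, 4.0], [0.5, 1.0, 2.0])}
        blobs = []
        for i in range(2):
            d = tmp_path / f"r{i}"
            jp, tp = render_report(d, positivity=tab, summary=summary, tests=tests)
            blobs.append(jp.read_bytes() + tp.read_bytes())
        assert blobs[0] == blobs[1]

    def test_empty_cohort_notes_no_subjects(self, tmp_path):
        jp, tp = render_report(tmp_path)
        import json

        payload = json.loads(jp.read_text())
        assert payload["note"] == "no subjects"
        assert "No subjects" in tp.read_text()

    def test_rendered_positivity_satisfies_category_arithmetic(self, tmp_path, rng):
        markers = ["A", "B"]
        cells = _cells_from_levels(
            [tuple(rng.choice(["negative", "low", "high"], size=2)) for _ in range(97)],
            markers,
        )
        tab = positivity_table(cells, markers=markers, cocktails={"AB": markers})
        jp, _ = render_report(tmp_path, positivity=tab)
        import json

        payload = json.loads(jp.read_text())
        for col, vals in payload["positivity"].items():
            assert vals["pct_negative"] + vals["pct_low"] + vals["pct_high"] == pytest.approx(100, abs=0.01)
            assert vals["pct_positive"] == pytest.approx(vals["pct_low"] + vals["pct_high"], abs=0.01)
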