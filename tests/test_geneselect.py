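"""overmean selector, set filters, in silico sorting and cascade ledger:
exact agreement with brute-force per-gene oracles and set-theoretic
invariants."""

import json

import numpy as np
import pandas as pd
import pytest

from ctcmark import (
    CascadeConfig,
    ExpressionMatrix,
    GeneSet,
    filter_expressed_in_ctc,
    filter_plasma_membrane,
    insilico_sort,
    intersect,
    overmean,
)
from ctcmark.containers import IHC_LEVELS
from ctcmark.errors import InputError
from ctcmark.simdata import annotation_with_counts, gene_ids
from conftest import random_matrix


def overmean_bruteforce(matrix, refvar="mean_gene_var"):
    """Direct per-gene loop implementation of the selection rule."""
    values = matrix.values.to_numpy(float)
    n_genes, n_samples = values.shape
    grand_mean = values.sum() / values.size
    gene_means, gene_vars = [], []
    for g in range(n_genes):
        row = values[g]
        mu = sum(row) / n_samples
        var = sum((x - mu) ** 2 for x in row) / (n_samples - 1)
        gene_means.append(mu)
        gene_vars.append(var)
    if refvar == "mean_gene_var":
        ref_var = sum(gene_vars) / n_genes
    else:
        mu_all = grand_mean
        ref_var = sum((x - mu_all) ** 2 for x in values.ravel()) / (values.size - 1)
    return {
        matrix.gene_ids[g]
        for g in range(n_genes)
        if gene_means[g] > grand_mean and gene_vars[g] > ref_var
    }


class TestOvermean:
    @pytest.mark.parametrize("refvar", ["mean_gene_var", "total_var"])
    def test_matches_bruteforce_oracle(self, rng, refvar):
        for _ in range(10):
            n_genes = int(rng.integers(5, 120))
            n_samples = int(rng.integers(2, 20))
            m = random_matrix(rng, n_genes, n_samples)
            selected, sub = overmean(m, refvar=refvar)
            assert selected.genes == frozenset(overmean_bruteforce(m, refvar))
            assert set(sub.gene_ids) == selected.genes

    def test_constant_matrix_selects_nothing(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.full((10, 5), 3.0), index=[f"G{i}" for i in range(10)],
                         columns=[f"S{i}" for i in range(5)])
        )
        assert len(overmean(m)[0]) == 0

    def test_translation_invariance(self, rng):
        m = random_matrix(rng, 80, 10)
        s1, _ = overmean(m)
        s2, _ = overmean(ExpressionMatrix(m.values + 17.3))
        assert s1.genes == s2.genes

    def test_positive_scale_invariance(self, rng):
        m = random_matrix(rng, 80, 10)
        s1, _ = overmean(m)
        s2, _ = overmean(ExpressionMatrix(m.values * 0.25))
        assert s1.genes == s2.genes

    def test_single_sample_rejected(self, rng):
        m = random_matrix(rng, 10, 1)
        with pytest.raises(InputError, match="variance"):
            overmean(m)


class TestIntersect:
    def test_self_intersection_is_identity(self):
        a = GeneSet("a", frozenset("abc"))
        common, _ = intersect([a, a])
        assert common.genes == a.genes

    def test_disjoint_sets(self):
        a = GeneSet("a", frozenset("ab"))
        b = GeneSet("b", frozenset("cd"))
        common, regions = intersect([a, b])
        assert len(common) == 0
        assert sum(regions.values()) == 4

    def test_two_set_regions_by_enumeration(self):
        a = GeneSet("a", frozenset("abc"))
        b = GeneSet("b", frozenset("bcd"))
        common, regions = intersect([a, b])
        assert common.genes == frozenset("bc")
        assert regions == {"01": 1, "10": 1, "11": 2}

    def test_three_sets(self):
        a = GeneSet("a", frozenset("abc"))
        b = GeneSet("b", frozenset("bcd"))
        c = GeneSet("c", frozenset("cde"))
        common, regions = intersect([a, b, c])
        assert common.genes == frozenset("c")
        assert regions["111"] == 1

    def test_requires_two_sets(self):
        with pytest.raises(InputError):
            intersect([GeneSet("a", frozenset("a"))])


class TestMembraneAndCTCFilters:
    def test_flag_counts(self):
        genes = gene_ids(100)
        flags = [i < 40 for i in range(100)]
        annot = _annot(genes, go=flags)
        kept = filter_plasma_membrane(GeneSet("all", frozenset(genes)), annot)
        assert len(kept) == 40

    def test_all_false_and_all_true(self):
        genes = gene_ids(10)
        all_genes = GeneSet("all", frozenset(genes))
        assert len(filter_plasma_membrane(all_genes, _annot(genes, go=[False] * 10))) == 0
        assert filter_plasma_membrane(all_genes, _annot(genes, go=[True] * 10)).genes == all_genes.genes

    def test_missing_annotation_fails_closed(self):
        genes = gene_ids(5)
        annot = _annot(genes[:2], go=[True, True])
        kept = filter_plasma_membrane(GeneSet("all", frozenset(genes)), annot)
        assert kept.genes == frozenset(genes[:2])

    def test_all_zero_sc_matrix_gives_empty(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.zeros((5, 4)), index=gene_ids(5), columns=[f"C{i}" for i in range(4)]),
            platform="fpkm",
        )
        kept = filter_expressed_in_ctc(GeneSet("c", frozenset(gene_ids(5))), m)
        assert len(kept) == 0

    def test_platform_must_be_fpkm(self, rng):
        m = random_matrix(rng, 10, 4, platform="bulk_log")
        with pytest.raises(InputError, match="fpkm"):
            filter_expressed_in_ctc(GeneSet("c", frozenset()), m)


def _annot(genes, m1=None, m2=None, i1=None, i2=None, go=None, ihc=None):
    from ctcmark import GeneAnnotation

    n = len(genes)
    false = [False] * n
    return GeneAnnotation.from_records(
        genes,
        m1 or false,
        m2 or false,
        i1 or false,
        i2 or false,
        go or false,
        ihc or [("high", "high")] * n,
    )


def insilico_bruteforce(genes, annot, cfg):
    """Exhaustive per-gene rule evaluation, stage by stage."""
    survivors = []
    for g in sorted(genes.genes):
        m1, m2 = annot.flag(g, "membrane_db1"), annot.flag(g, "membrane_db2")
        if cfg.membrane_rule == "both_dbs":
            if not (m1 and m2):
                continue
        elif not (m1 or m2):
            continue
        if annot.flag(g, "immune_db1") or annot.flag(g, "immune_db2"):
            continue
        levels = annot.ihc_levels(g)
        if not levels:
            continue
        thr = IHC_LEVELS.index(cfg.ihc_min_level)
        frac = sum(IHC_LEVELS.index(lv) >= thr for lv in levels) / len(levels)
        if frac < cfg.ihc_min_fraction:
            continue
        survivors.append(g)
    return set(survivors)


class TestInsilicoSort:
    def test_no_membrane_flags_empties_first_stage(self):
        genes = gene_ids(10)
        final, frag = insilico_sort(GeneSet("all", frozenset(genes)), _annot(genes))
        assert frag.stages[0].n_out == 0
        assert len(final) == 0

    def test_identity_when_everything_passes(self):
        genes = gene_ids(8)
        annot = _annot(genes, m1=[True] * 8, m2=[True] * 8, go=[True] * 8)
        final, _ = insilico_sort(GeneSet("all", frozenset(genes)), annot)
        assert final.genes == frozenset(genes)

    def test_paper_style_count_sequence(self):
        """50 genes with the configured annotation split sort to 30 -> 19 -> 12."""
        genes = gene_ids(50)
        annot = annotation_with_counts(genes)
        final, frag = insilico_sort(GeneSet("all", frozenset(genes)), annot)
        assert [s.n_out for s in frag.stages] == [30, 19, 12]
        assert frag.stages[0].extra == {"membrane_both": 26, "membrane_one": 4}
        assert len(final) == 12

    def test_both_dbs_rule_restricts_to_both(self):
        genes = gene_ids(50)
        annot = annotation_with_counts(genes)
        cfg = CascadeConfig(membrane_rule="both_dbs")
        _, frag = insilico_sort(GeneSet("all", frozenset(genes)), annot, cfg)
        assert frag.stages[0].n_out == 26

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_rule_oracle(self, seed):
        from ctcmark.simdata import simulate_annotations
        from ctcmark import SimConfig

        genes = gene_ids(120)
        annot = simulate_annotations(genes, SimConfig(seed=seed))
        cfg = CascadeConfig()
        final, _ = insilico_sort(GeneSet("all", frozenset(genes)), annot, cfg)
        assert final.genes == frozenset(insilico_bruteforce(GeneSet("all", frozenset(genes)), annot, cfg))


@pytest.fixture(scope="module")
def pipeline_result(tmp_path_factory):
    from ctcmark import SimConfig, run_full_pipeline

    cfg = SimConfig(seed=11, n_genes=400, n_tumor=8, n_adjacent=8, n_true_deg=40,
                    frac_expressed_variable=0.1, sc_n_cells=30,
                    cohort=_small_cohort())
    out = tmp_path_factory.mktemp("cascade")
    return run_full_pipeline(cfg, out_dir=out), out


class TestCascade:
    def test_every_stage_is_non_increasing_subset(self, pipeline_result):
        result, _ = pipeline_result
        stages = result.report.stages
        for st in stages:
            assert st.n_out <= st.n_in
            assert st.n_out == len(st.genes)
        # chained stages: each output feeds the next input
        for a, b in zip(stages, stages[1:]):
            assert set(b.genes) <= set(a.genes)

    def test_ledger_json_round_trip(self, pipeline_result):
        result, out = pipeline_result
        payload = json.loads((out / "cascade_ledger.json").read_text())
        assert [s["n_out"] for s in payload["stages"]] == result.report.counts

    def test_gene_id_mismatch_rejected(self, rng):
        from ctcmark.geneselect import _check_gene_ids

        m1 = random_matrix(rng, 10, 4)
        m2 = random_matrix(rng, 12, 4)
        with pytest.raises(InputError, match="gene ids differ"):
            _check_gene_ids(m1, m2)


def _small_cohort():
    from ctcmark import CohortSimConfig

    return CohortSimConfig(n_patients=6, n_donors=4, leukocytes_per_support=10)
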