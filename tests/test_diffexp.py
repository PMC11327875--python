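"""Dual-criterion DE: size factors, BH, NB Wald engine, intersection calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncdisc.diffexp import (
    DEConfig,
    bh_adjust,
    call_de,
    estimate_size_factors,
    fc_call,
    nb_wald,
    prefilter,
    simple_fc,
)
from lncdisc.simulate import SimConfig, gen_counts


class TestPrefilter:
    def test_gene_below_floor_everywhere_removed(self):
        tpm = pd.DataFrame([[0.2, 0.4, 0.9]], index=["g"])
        assert list(prefilter(tpm)) == []

    def test_single_qualifying_sample_kept(self):
        tpm = pd.DataFrame([[0.0, 0.0, 1.0]], index=["g"])
        assert list(prefilter(tpm)) == ["g"]

    def test_empty_matrix(self):
        assert len(prefilter(pd.DataFrame())) == 0


class TestSimpleFC:
    def test_exact_threshold_is_called(self):
        fc = simple_fc(np.array([10.0]), np.array([17.0]), pseudocount=0.0)
        assert fc[0] == pytest.approx(1.7)
        assert fc_call(fc)[0]

    def test_equal_means_not_called(self):
        fc = simple_fc(np.array([5.0]), np.array([5.0]), pseudocount=0.0)
        assert fc[0] == 1.0 and not fc_call(fc)[0]

    def test_pseudocount_saturates_zeros(self):
        fc = simple_fc(np.array([0.0]), np.array([0.0]), pseudocount=0.1)
        assert fc[0] == 1.0

    def test_strict_comparator_option(self):
        fc = np.array([1.7])
        assert fc_call(fc, inclusive=True)[0]
        assert not fc_call(fc, inclusive=False)[0]

    def test_downregulation_reciprocal(self):
        fc = simple_fc(np.array([17.0]), np.array([10.0]), pseudocount=0.0)
        assert fc_call(fc)[0]


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame([[2, 4], [4, 8]], columns=["a", "b"])
        sf = estimate_size_factors(counts)
        assert sf.round(4).tolist() == [0.7071, 1.4142]

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame([[5, 5], [9, 9], [100, 100]], columns=["a", "b"])
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame([[5], [9]], columns=["a"])
        assert estimate_size_factors(counts).tolist() == [1.0]

    def test_scaling_one_sample_scales_its_relative_factor(self):
        """Tripling one sample's counts triples its size factor relative to
        the others (the geometric-mean reference itself rescales, so only
        factor ratios are identifiable)."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(10, 1000, size=(50, 4)), columns=list("abcd")
        )
        sf = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] *= 3
        sf2 = estimate_size_factors(scaled)
        rel_before = sf["c"] / sf["a"]
        rel_after = sf2["c"] / sf2["a"]
        assert rel_after / rel_before == pytest.approx(3.0)

    def test_no_allpositive_gene_needs_pseudo_reference(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            estimate_size_factors(counts)
        sf = estimate_size_factors(counts, pseudo_reference=True)
        assert (sf > 0).all()


class TestBH:
    def test_hand_computed_stepup(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(padj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_monotone_padj_geq_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 200)
        assert (bh_adjust(p) >= p).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = pd.Series(rng.uniform(1e-6, 1, 100))
        perm = p.sample(frac=1, random_state=3)
        padj = bh_adjust(p)
        padj_perm = bh_adjust(perm).sort_index()
        np.testing.assert_allclose(padj, padj_perm)

    def test_nan_passthrough(self):
        padj = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(padj[1]) and not np.isnan(padj[0])

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_adjust(np.array([0.0, 0.5]))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1, max_size=50,
        )
    )
    def test_stepup_properties_hold_for_any_input(self, pvals):
        """BH output dominates the raw p-values, stays in (0, 1], and is
        monotone along the sorted order."""
        p = np.asarray(pvals)
        padj = bh_adjust(p)
        assert (padj >= p - 1e-12).all()
        assert (padj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def null_counts():
    """Homogeneous-dispersion NB null: equal means, n = 3+3, 2000 genes."""
    rng = np.random.default_rng(7)
    n = 2000
    mu = np.exp(rng.uniform(np.log(100), np.log(1000), n))
    r = 1 / 0.1
    m = mu[:, None] * np.ones(6)
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + m)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"s{i}" for i in range(6)],
    )
    return counts


class TestNBWald:
    def test_null_type_one_error_near_nominal(self, null_counts):
        """Monte-Carlo with a known null: empirical alpha within 0.05 +/- 0.02."""
        sf = pd.Series(np.ones(6), index=null_counts.columns)
        res = nb_wald(null_counts, sf, [0, 0, 0, 1, 1, 1])
        rate = (res.wald_p < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_log2fc_recovered(self):
        """log2FC = 2 at mean 100, dispersion 0.05: mean estimate within 0.3."""
        rng = np.random.default_rng(8)
        n = 500
        r = 1 / 0.05
        mu = np.full((n, 6), 100.0)
        mu[:, 3:] *= 4.0
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(6)],
        )
        sf = pd.Series(np.ones(6), index=counts.columns)
        res = nb_wald(counts, sf, [0, 0, 0, 1, 1, 1])
        assert abs(res.log2fc.mean() - 2.0) < 0.3

    def test_interaction_design_finds_interaction_only_effects(self):
        """Condition-only contrast on wild type stays near-null while the
        interaction term recovers a majority of planted cell-specific genes."""
        cfg = SimConfig(seed=2, n_genes_counts=600, de_fraction=0.1,
                        fc_grid=(4.0,))
        counts, tpm, meta, truth = gen_counts(cfg, design="interaction")
        meta = meta.set_index("sample_id")
        sf = estimate_size_factors(counts)
        res = nb_wald(
            counts, sf,
            (meta.condition == "regeneration").astype(int).values,
            genotype=(meta.genotype == "mutant").astype(int).values,
            design="interaction",
        )
        padj = bh_adjust(res.wald_p)
        called = set(counts.index[(padj < 0.05)
                                  & (res.log2fc.abs() >= np.log2(1.7))])
        planted = set(truth.loc[truth.is_de, "gene_id"])
        assert len(called & planted) / len(planted) > 0.5

        wt = meta.index[meta.genotype == "control"]
        cwt = counts[list(wt)]
        res_wt = nb_wald(
            cwt, estimate_size_factors(cwt),
            (meta.loc[wt, "condition"] == "regeneration").astype(int).values,
        )
        padj_wt = bh_adjust(res_wt.wald_p)
        n_wt = ((padj_wt < 0.05) & (res_wt.log2fc.abs() >= np.log2(1.7))).sum()
        assert n_wt <= 0.02 * len(cwt)

    def test_design_cell_size_validation(self, null_counts):
        sf = pd.Series(np.ones(6), index=null_counts.columns)
        with pytest.raises(ValueError, match="at least 2"):
            nb_wald(null_counts, sf, [0, 0, 0, 0, 0, 1])


@pytest.fixture(scope="module")
def de_run():
    cfg = SimConfig(seed=1, n_genes_counts=800, de_fraction=0.1,
                    time_points=("early", "mid"))
    counts, tpm, meta, truth = gen_counts(cfg)
    table, summary = call_de(counts, tpm, meta.set_index("sample_id"))
    return table, summary, truth


class TestCallDE:
    def test_de_call_is_intersection(self, de_run):
        table, _, _ = de_run
        assert (table.de_call == (table.fc_call & table.stat_call)).all()
        assert not table.loc[~table.fc_call, "de_call"].any()
        assert not table.loc[~table.stat_call, "de_call"].any()

    def test_summary_counts_match_table(self, de_run):
        table, summary, _ = de_run
        early = table[(table.time_point == "early") & table.de_call]
        assert summary["per_stage"]["early"]["up"] == (
            early.direction == "up").sum()
        union = set(table.loc[table.de_call, "gene_id"])
        assert summary["n_union"] == len(union)

    def test_direction_matches_planted_truth(self, de_run):
        table, _, truth = de_run
        m = table.merge(truth, on=["gene_id", "time_point"])
        hit = m[m.de_call & m.is_de]
        assert len(hit) > 0
        assert (hit.direction_x == hit.direction_y).all()

    def test_exclusion_list_semantics(self):
        cfg = SimConfig(seed=3, n_genes_counts=400, de_fraction=0.1,
                        fc_grid=(4.0,), time_points=("early",))
        counts, tpm, meta, truth = gen_counts(cfg)
        meta = meta.set_index("sample_id")
        table, summary = call_de(counts, tpm, meta)
        called = table.loc[table.de_call, "gene_id"].iloc[0]
        table2, summary2 = call_de(counts, tpm, meta, exclude=[called])
        row = table2[table2.gene_id == called]
        assert row.excluded.all() and row.de_call.all()
        assert called not in summary2["union_de"]
        assert summary2["n_union"] == summary["n_union"] - 1

    def test_missing_condition_raises(self):
        cfg = SimConfig(seed=4, n_genes_counts=50, time_points=("early",))
        counts, tpm, meta, _ = gen_counts(cfg)
        meta = meta.set_index("sample_id")
        bad = meta.copy()
        bad["condition"] = "control"
        with pytest.raises(ValueError, match="lacks"):
            call_de(counts, tpm, bad)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DEConfig(fc_threshold=0.9)
        with pytest.raises(ValueError):
            DEConfig(alpha=1.5)


def test_fc_exactly_1_7_straddles_threshold():
    """A fold change planted exactly at the 1.7 threshold lands the observed
    TPM ratio on the boundary: with sampling noise roughly half the genes
    pass the (inclusive) screen, and planted genes pass far more often than
    true nulls."""
    cfg = SimConfig(seed=6, n_genes_counts=1000, de_fraction=0.2,
                    fc_grid=(1.7,), time_points=("early",))
    counts, tpm, meta, truth = gen_counts(cfg)
    meta = meta.set_index("sample_id")
    a = meta.index[meta.condition == "control"]
    b = meta.index[meta.condition == "regeneration"]
    ratio = simple_fc(tpm[list(a)].mean(1), tpm[list(b)].mean(1), 0.1)
    flags = fc_call(ratio)
    planted = truth.set_index("gene_id").is_de
    assert 0.3 < flags[planted].mean() < 0.7
    assert flags[planted].mean() > 3 * flags[~planted].mean()
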