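"""NB testing, dispersion workflow, TE interaction, classification rules."""

import warnings

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sgribo import riboclass as rc
from sgribo import simdata
from sgribo.simdata import CountDesign

warnings.filterwarnings("ignore")

CONTRAST = ("condition", "treated", "control")


def _meta(n, condition_of):
    return pd.DataFrame({
        "assay": "RNA", "genotype": "WT",
        "condition": [condition_of(i) for i in range(n)],
        "replicate": list(range(1, n + 1)),
    }, index=[f"s{i}" for i in range(n)])


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        npt.assert_allclose(rc.size_factors(counts), [1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        a = np.array([10, 50, 100, 7])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        sf = rc.size_factors(counts)
        npt.assert_allclose(sf["b"] / sf["a"], 2.0)

    def test_scaling_one_column_scales_only_its_factor(self, rng):
        base = pd.DataFrame(rng.integers(5, 100, size=(50, 4)).astype(float),
                            columns=list("abcd"))
        sf1 = rc.size_factors(base)
        scaled = base.copy()
        scaled["c"] = scaled["c"] * 3.0
        sf2 = rc.size_factors(scaled)
        # median-of-ratios factors are relative: scaling a column by 3
        # scales its factor by 3 relative to every other column
        for other in "abd":
            npt.assert_allclose((sf2["c"] / sf2[other])
                                / (sf1["c"] / sf1[other]), 3.0, rtol=1e-10)

    def test_error_without_all_positive_gene(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="positive"):
            rc.size_factors(counts)

    def test_matches_pydeseq2(self):
        from pydeseq2.dds import DeseqDataSet
        design = CountDesign(n_genes=120, dispersion=0.05, seed=5,
                             class_fractions={})
        counts, meta, _ = simdata.generate_counts(design)
        rna = meta.index[meta["assay"] == "RNA"]
        dds = DeseqDataSet(counts=counts[rna].T, metadata=meta.loc[rna],
                           design="~condition", quiet=True)
        dds.fit_size_factors()
        npt.assert_allclose(rc.size_factors(counts[rna]).to_numpy(),
                            dds.obs["size_factors"].to_numpy(), rtol=1e-10)


class TestDispersions:
    def test_poisson_counts_give_near_zero_alpha(self):
        design = CountDesign(n_genes=2000, n_replicates=4, dispersion=1e-6,
                             class_fractions={}, seed=3)
        counts, meta, _ = simdata.generate_counts(design)
        rna = meta.index[meta["assay"] == "RNA"]
        d = rc.estimate_dispersions(counts[rna], rc.size_factors(counts[rna]),
                                    meta.loc[rna], ["condition"])
        assert np.nanmedian(d["alpha"]) <= 0.01

    def test_nb_alpha_point_two_recovered(self):
        design = CountDesign(n_genes=2000, n_replicates=4, dispersion=0.2,
                             class_fractions={}, seed=3)
        counts, meta, _ = simdata.generate_counts(design)
        rna = meta.index[meta["assay"] == "RNA"]
        d = rc.estimate_dispersions(counts[rna], rc.size_factors(counts[rna]),
                                    meta.loc[rna], ["condition"])
        assert 0.1 <= np.nanmedian(d["alpha"]) <= 0.4

    def test_constant_gene_has_zero_genewise(self):
        counts = pd.DataFrame(
            np.vstack([np.full(6, 50), np.arange(10, 70, 10)]),
            index=["flat", "varying"], columns=[f"s{i}" for i in range(6)])
        meta = _meta(6, lambda i: "control")
        sf = pd.Series(1.0, index=counts.columns)
        d = rc.estimate_dispersions(counts, sf, meta, ["condition"],
                                    shrink_weight=0.35)
        assert d.loc["flat", "genewise"] == 0.0

    def test_all_zero_gene_flagged_nan(self):
        counts = pd.DataFrame({"s0": [0, 10, 30], "s1": [0, 12, 28],
                               "s2": [0, 9, 31], "s3": [0, 11, 29]},
                              index=["zero", "a", "b"])
        sf = pd.Series(1.0, index=counts.columns)
        d = rc.estimate_dispersions(counts, sf)
        assert np.isnan(d.loc["zero", "alpha"])


class TestNbWaldTest:
    def test_identical_groups_lfc_zero(self):
        row = [40, 50, 60, 40, 50, 60]
        counts = pd.DataFrame([row] * 30,
                              index=[f"g{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(6)])
        meta = _meta(6, lambda i: "treated" if i >= 3 else "control")
        res = rc.nb_wald_test(counts, meta, CONTRAST)
        npt.assert_allclose(res.table["log2FC"], 0.0, atol=1e-6)

    def test_planted_lfc_recovery(self):
        # low-dispersion setting: the Wald SE (~0.14 log2) leaves ~95% of
        # estimates within +-0.3 of the planted value
        design = CountDesign(n_genes=1000, dispersion=0.005, effect_lfc=2.0,
                             seed=19, baseline_mean=(np.log(100.0), 0.0),
                             class_fractions={"RNA_ABUNDANCE_UP": 0.2})
        counts, meta, truth = simdata.generate_counts(design)
        rna = meta.index[meta["assay"] == "RNA"]
        res = rc.nb_wald_test(counts[rna], meta.loc[rna], CONTRAST)
        planted = truth.index[truth["label"] == "RNA_ABUNDANCE_UP"]
        err = (res.table.loc[planted, "log2FC"] - 2.0).abs()
        assert (err < 0.3).mean() >= 0.9

    def test_padj_not_below_p(self, null_counts):
        counts, meta, _ = null_counts
        rna = meta.index[meta["assay"] == "RNA"]
        res = rc.nb_wald_test(counts[rna], meta.loc[rna], CONTRAST)
        t = res.table.dropna(subset=["p"])
        assert (t["padj"] >= t["p"] - 1e-12).all()
        assert (t["baseMean"] >= 0).all()


class TestShrinkLfc:
    def _table(self, lfc, se):
        return pd.DataFrame({"log2FC": lfc, "lfcSE": se})

    def test_precise_estimates_untouched(self):
        t = self._table([2.0] + [1.0, -1.0] * 25, [0.001] + [0.3] * 50)
        s = rc.shrink_lfc(t)
        assert abs(s.iloc[0] - 2.0) < 0.01

    def test_noisy_estimates_pulled_to_zero(self):
        t = self._table([2.0] + [1.0, -1.0] * 25, [100.0] + [0.3] * 50)
        s = rc.shrink_lfc(t)
        assert abs(s.iloc[0]) < 0.01

    def test_shrinkage_monotone_in_se(self):
        ses = [0.01, 0.1, 0.5, 1.0, 5.0]
        t = self._table([2.0] * len(ses), ses)
        s = rc.shrink_lfc(t, prior_sd=1.0)
        deltas = 2.0 - s.to_numpy()
        assert (np.diff(deltas) > 0).all()
        assert (s.abs() <= 2.0 + 1e-9).all()


@pytest.fixture(scope="module")
def te_setup():
    design = CountDesign(n_genes=600, dispersion=0.002, n_replicates=6,
                         effect_lfc=2.0, seed=23,
                         baseline_mean=(np.log(200.0), 0.0),
                         class_fractions={"TE_UP": 0.1,
                                          "RNA_ABUNDANCE_UP": 0.1})
    counts, meta, truth = simdata.generate_counts(design)
    rna = meta.index[meta["assay"] == "RNA"]
    ribo = meta.index[meta["assay"] == "RIBO"]
    return counts, meta, truth, rna, ribo


class TestTeInteraction:

    def test_swapping_assays_negates_te(self, te_setup):
        counts, meta, truth, rna, ribo = te_setup
        sub = truth.index[:80]
        a = rc.te_interaction_test(counts.loc[sub, rna], counts.loc[sub, ribo],
                                   meta.loc[rna], meta.loc[ribo], CONTRAST)
        b = rc.te_interaction_test(counts.loc[sub, ribo], counts.loc[sub, rna],
                                   meta.loc[ribo], meta.loc[rna], CONTRAST)
        npt.assert_allclose(a.table["te_log2FC"], -b.table["te_log2FC"],
                            atol=1e-6)

    def test_pure_rna_abundance_has_null_te(self, te_setup):
        counts, meta, truth, rna, ribo = te_setup
        res = rc.te_interaction_test(counts[rna], counts[ribo],
                                     meta.loc[rna], meta.loc[ribo], CONTRAST)
        ab = truth.index[truth["label"] == "RNA_ABUNDANCE_UP"]
        assert (res.table.loc[ab, "te_log2FC"].abs() < 0.2).mean() >= 0.9

    def test_planted_te_recovered(self, te_setup):
        counts, meta, truth, rna, ribo = te_setup
        res = rc.te_interaction_test(counts[rna], counts[ribo],
                                     meta.loc[rna], meta.loc[ribo], CONTRAST)
        te_up = truth.index[truth["label"] == "TE_UP"]
        err = (res.table.loc[te_up, "te_log2FC"] - 2.0).abs()
        assert (err < 0.4).mean() >= 0.85

    def test_missing_condition_rejected(self, te_setup):
        counts, meta, truth, rna, ribo = te_setup
        ctrl_only = meta.loc[rna][meta.loc[rna, "condition"] == "control"]
        with pytest.raises(ValueError):
            rc.te_interaction_test(counts[ctrl_only.index], counts[ribo],
                                   ctrl_only, meta.loc[ribo], CONTRAST)


def _result_tables(rows):
    """Build aligned RNA/Ribo/TE tables from per-gene dicts."""
    idx = [r["gene"] for r in rows]
    rna = pd.DataFrame({"baseMean": [r.get("rna_bm", 100.0) for r in rows],
                        "log2FC": [r.get("rna_lfc", 0.0) for r in rows],
                        "padj": [r.get("rna_padj", 1.0) for r in rows]}, index=idx)
    ribo = pd.DataFrame({"baseMean": [r.get("ribo_bm", 100.0) for r in rows],
                         "log2FC": [r.get("ribo_lfc", 0.0) for r in rows],
                         "padj": [r.get("ribo_padj", 1.0) for r in rows]}, index=idx)
    te = pd.DataFrame({"te_log2FC": [r.get("te_lfc", 0.0) for r in rows],
                       "padj": [r.get("te_padj", 1.0) for r in rows]}, index=idx)
    return rna, ribo, te


class TestClassifyGenes:
    def test_buffering_rule(self):
        rna, ribo, te = _result_tables([
            {"gene": "g1", "rna_padj": 0.005, "rna_lfc": 0.8,
             "ribo_padj": 0.4, "te_padj": 0.6}])
        out = rc.classify_genes(rna, ribo, te)
        assert out.loc["g1", "buffering_up"]
        assert out.loc["g1", "label"] == "Buffering up"

    def test_rna_abundance_rule_with_ribo_flag(self):
        rna, ribo, te = _result_tables([
            {"gene": "g1", "rna_padj": 0.01, "rna_lfc": 1.0,
             "ribo_padj": 0.01, "ribo_lfc": 1.0, "te_padj": 0.5}])
        out = rc.classify_genes(rna, ribo, te)
        assert out.loc["g1", "rna_abundance_up"]
        assert out.loc["g1", "ribo_ocp_up"]
        assert out.loc["g1", "label"] == "RNA abundance up"

    def test_basemean_filter_blocks_all_flags(self):
        rna, ribo, te = _result_tables([
            {"gene": "g1", "rna_bm": 15.0, "rna_padj": 1e-10, "rna_lfc": 5.0,
             "ribo_padj": 1e-10, "ribo_lfc": 5.0, "te_padj": 1e-10,
             "te_lfc": 5.0}])
        out = rc.classify_genes(rna, ribo, te)
        assert not out.loc["g1", "passed_basemean_filter"]
        assert not out.loc["g1", rc.FLAG_COLUMNS].any()
        assert out.loc["g1", "label"] == "NS"

    def test_all_nonsignificant_is_ns(self):
        rna, ribo, te = _result_tables([{"gene": "g1"}])
        out = rc.classify_genes(rna, ribo, te)
        assert out.loc["g1", "label"] == "NS"

    def test_te_rule_and_ribo_ocp(self):
        rna, ribo, te = _result_tables([
            {"gene": "g1", "te_padj": 0.01, "te_lfc": 1.5,
             "ribo_padj": 0.02, "ribo_lfc": 1.5}])
        out = rc.classify_genes(rna, ribo, te)
        assert out.loc["g1", "te_up"] and out.loc["g1", "ribo_ocp_up"]
        assert out.loc["g1", "label"] == "TE up"  # TE outranks Ribo ocp

    def test_gene_order_invariance(self, rng):
        rows = []
        for i in range(40):
            rows.append({"gene": f"g{i}",
                         "rna_padj": rng.uniform(0, 0.1),
                         "rna_lfc": rng.normal(),
                         "ribo_padj": rng.uniform(0, 0.1),
                         "ribo_lfc": rng.normal(),
                         "te_padj": rng.uniform(0, 0.1),
                         "te_lfc": rng.normal()})
        rna, ribo, te = _result_tables(rows)
        out1 = rc.classify_genes(rna, ribo, te)
        perm = rng.permutation(rna.index)
        out2 = rc.classify_genes(rna.loc[perm], ribo.loc[perm], te.loc[perm])
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())

    def test_mismatched_indices_rejected(self):
        rna, ribo, te = _result_tables([{"gene": "g1"}])
        with pytest.raises(ValueError):
            rc.classify_genes(rna, ribo.rename(index={"g1": "g2"}), te)


class TestRegressionAndCorrelation:
    def test_exact_line(self):
        x = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        slope, intercept, r2 = rc.delta_te_rna_regression(x, x)
        npt.assert_allclose([slope, intercept, r2], [1.0, 0.0, 1.0], atol=1e-12)

    def test_independent_has_no_fit(self, rng):
        idx = [f"g{i}" for i in range(1000)]
        te = pd.Series(rng.normal(size=1000), index=idx)
        rna = pd.Series(rng.normal(size=1000), index=idx)
        _, _, r2 = rc.delta_te_rna_regression(te, rna)
        assert r2 < 0.01

    def test_slope_recovery_with_noise(self, rng):
        idx = [f"g{i}" for i in range(500)]
        rna = pd.Series(rng.normal(size=500), index=idx)
        te = 0.5 * rna + rng.normal(scale=0.1, size=500)
        slope, _, _ = rc.delta_te_rna_regression(te, rna)
        assert abs(slope - 0.5) < 0.05

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            rc.delta_te_rna_regression(y, x)

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=50)
        assert rc.spearman_correlation(x, np.exp(x)) == pytest.approx(1.0)
        assert rc.spearman_correlation(x, -x) == pytest.approx(-1.0)

    def test_spearman_ties_match_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 7.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = (np.mean(rx * ry) - rx.mean() * ry.mean()) / (rx.std() * ry.std())
        npt.assert_allclose(rc.spearman_correlation(x, y), expected, atol=1e-12)

    def test_spearman_constant_vector_nan(self):
        assert np.isnan(rc.spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def brute_force_bh(p):
    """Step-up definition: padj_(i) = min over j>=i of p_(j)*m/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        npt.assert_allclose(rc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        npt.assert_allclose(rc.bh_adjust([0.2]), [0.2])
        npt.assert_allclose(rc.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=200)
    def test_matches_exhaustive_definition(self, p):
        npt.assert_allclose(rc.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rc.bh_adjust([0.5, 1.5])
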