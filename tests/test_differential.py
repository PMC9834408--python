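import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ttstall as t
from conftest import make_design, unit_size_factors

import oracles


def sim_counts(seed, n_genes, design, mu, alpha):
    rng = np.random.default_rng(seed)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_genes,)).copy()
    cols = {}
    for s in design.index:
        if alpha == 0:
            cols[s] = rng.poisson(mu)
        else:
            size = 1.0 / alpha
            cols[s] = rng.negative_binomial(size, size / (size + mu))
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])


class TestEstimateDispersion:
    def test_zero_variance_hits_floor(self):
        design = make_design(["WT", "KO"], 3)
        counts = pd.DataFrame(
            {s: [7, 20] for s in design.index}, index=["g0", "g1"]
        )
        disp = t.estimate_dispersion(counts, design, unit_size_factors(design))
        np.testing.assert_allclose(disp, 1e-8)

    def test_poisson_data_gives_near_zero_dispersion(self):
        design = make_design(["WT", "KO"], 3)
        counts = sim_counts(0, 10_000, design, 500.0, alpha=0.0)
        disp = t.estimate_dispersion(counts, design, unit_size_factors(design))
        assert disp.median() < 0.01

    def test_nb_dispersion_recovered(self):
        design = make_design(["WT", "KO"], 3)
        counts = sim_counts(1, 10_000, design, 2000.0, alpha=0.1)
        disp = t.estimate_dispersion(counts, design, unit_size_factors(design))
        assert 0.07 <= disp.median() <= 0.13

    def test_single_replicate_rejected(self):
        design = make_design(["WT", "KO"], 1)
        counts = pd.DataFrame({s: [5] for s in design.index}, index=["g"])
        with pytest.raises(ValueError, match="replicate"):
            t.estimate_dispersion(counts, design, unit_size_factors(design))


class TestNbWald:
    @pytest.fixture
    def design(self):
        return make_design(["WT", "KO"], 3)

    def test_identical_counts_give_null_result(self, design):
        counts = pd.DataFrame({s: [50, 200] for s in design.index}, index=["g0", "g1"])
        disp = pd.Series(0.05, index=counts.index)
        res = t.nb_wald(counts, design, unit_size_factors(design), disp, "WT")
        np.testing.assert_allclose(res["log2FC"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_exact_doubling_gives_unit_lfc(self, design):
        wt = {s: [50] for s in design.index if "WT" in s}
        ko = {s: [100] for s in design.index if "KO" in s}
        counts = pd.DataFrame({**wt, **ko}, index=["g"])[list(design.index)]
        disp = pd.Series(0.05, index=counts.index)
        res = t.nb_wald(counts, design, unit_size_factors(design), disp, "WT")
        assert res.loc["g", "log2FC"] == pytest.approx(1.0)

    def test_zero_mean_genes_flagged_untested(self, design):
        wt = {s: [0, 10] for s in design.index if "WT" in s}
        ko = {s: [10, 10] for s in design.index if "KO" in s}
        counts = pd.DataFrame({**wt, **ko}, index=["g0", "g1"])[list(design.index)]
        disp = pd.Series(0.05, index=counts.index)
        res = t.nb_wald(counts, design, unit_size_factors(design), disp, "WT")
        assert not res.loc["g0", "tested"] and np.isinf(res.loc["g0", "log2FC"])
        assert res.loc["g1", "tested"]

    def test_antisymmetry_under_condition_swap(self, design):
        counts = sim_counts(3, 200, design, 300.0, alpha=0.05)
        s = unit_size_factors(design)
        disp = t.estimate_dispersion(counts, design, s)
        fwd = t.nb_wald(counts, design, s, disp, "WT")
        rev = t.nb_wald(counts, design, s, disp, "KO")
        tested = fwd["tested"] & rev["tested"]
        np.testing.assert_allclose(
            fwd.loc[tested, "log2FC"], -rev.loc[tested, "log2FC"], atol=1e-12
        )
        np.testing.assert_allclose(fwd.loc[tested, "p"], rev.loc[tested, "p"], atol=1e-12)

    def test_three_conditions_rejected(self):
        design = make_design(["WT", "KO", "KI"], 2)
        counts = pd.DataFrame({s: [5] for s in design.index}, index=["g"])
        disp = pd.Series(0.05, index=counts.index)
        with pytest.raises(ValueError, match="two conditions"):
            t.nb_wald(counts, design, unit_size_factors(design), disp, "WT")

    def test_log2fc_agrees_with_deseq2_glm(self):
        """Independent route: on NB data with 4-fold effects, our
        moment-based log2FC matches the DESeq2 GLM estimate (pydeseq2,
        no shrinkage applied to the contrast) to ~0.1 median absolute
        difference."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(0)
        n = 300
        mu = rng.lognormal(np.log(200), 1.0, n)
        fold = np.ones(n)
        fold[:30] = 0.25
        fold[30:60] = 4.0
        conds = ["WT"] * 3 + ["KO"] * 3
        size = 1 / 0.05
        counts = pd.DataFrame(
            {
                f"s{j}": rng.negative_binomial(
                    size, size / (size + mu * (fold if c == "KO" else 1.0))
                )
                for j, c in enumerate(conds)
            },
            index=[f"g{i}" for i in range(n)],
        )
        meta = pd.DataFrame({"condition": conds}, index=counts.columns)
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition",
            refit_cooks=False, quiet=True,
        )
        dds.fit_size_factors()
        dds.obsm["size_factors"] = np.ones(6)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "KO", "WT"], quiet=True)
        stats.summary()

        design = pd.DataFrame(
            {"assay": "RNA", "condition": conds, "replicate": [1, 2, 3, 1, 2, 3]},
            index=counts.columns,
        )
        ours = t.diff_expression(counts, design, pd.Series(1.0, index=counts.columns), "WT")
        diff = (ours["log2FC"] - stats.results_df["log2FoldChange"]).abs()
        assert diff.median() < 0.1

    def test_null_type_one_error_calibrated(self):
        """Null NB simulation (2000 genes, 3v3, alpha=0.05): empirical
        type-I error at nominal 0.05 lies in [0.03, 0.07] with the
        trend-moderated dispersions of the default testing route."""
        design = make_design(["WT", "KO"], 3)
        rng = np.random.default_rng(42)
        mu = rng.lognormal(np.log(300), 1.0, size=2000)
        counts = sim_counts(7, 2000, design, mu, alpha=0.05)
        res = t.diff_expression(counts, design, unit_size_factors(design), "WT")
        frac = (res.loc[res["tested"], "p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(t.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(t.bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            t.bh_adjust([0.5, 1.5])

    @given(
        p=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_bruteforce_definition(self, p):
        np.testing.assert_allclose(t.bh_adjust(p), oracles.bh_oracle(p), rtol=1e-10)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for n in (5, 50, 500):
            p = rng.uniform(size=n)
            np.testing.assert_allclose(
                t.bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-10
            )

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        assert (t.bh_adjust(p) >= p - 1e-15).all()


class TestCallDe:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (1.2, 0.01, "up"),
            (0.9, 1e-6, "ns"),  # effect-size threshold is a hard gate
            (-3.0, 0.05, "ns"),  # strict inequality on padj
            (-1.0, 0.049, "down"),
            (1.0, 0.049, "up"),
            (np.nan, np.nan, "ns"),
        ],
    )
    def test_rule(self, lfc, padj, expected):
        assert t.call_de([lfc], [padj])[0] == expected


class TestStallingIndex:
    @pytest.fixture
    def design(self):
        return make_design(["WT", "KO"], 2)

    def test_plain_ratio_without_pseudocount(self, design):
        tss = pd.DataFrame({s: [50] for s in design.index}, index=["g"])
        body = pd.DataFrame({s: [100] for s in design.index}, index=["g"])
        si = t.stalling_index(tss, body, design, unit_size_factors(design), pseudocount=0)
        assert si.loc["g", "WT"] == pytest.approx(0.5)

    def test_pseudocount_limit_for_empty_gene(self, design):
        tss = pd.DataFrame({s: [0] for s in design.index}, index=["g"])
        body = pd.DataFrame({s: [0] for s in design.index}, index=["g"])
        si = t.stalling_index(tss, body, design, unit_size_factors(design), pseudocount=1)
        assert si.loc["g", "WT"] == pytest.approx(1.0)

    def test_zero_body_with_zero_pseudocount_rejected(self, design):
        tss = pd.DataFrame({s: [5] for s in design.index}, index=["g"])
        body = pd.DataFrame({s: [0] for s in design.index}, index=["g"])
        with pytest.raises(ValueError, match="pseudocount"):
            t.stalling_index(tss, body, design, unit_size_factors(design), pseudocount=0)

    def test_si_ratio_follows_pausing_fractions(self):
        """pi 0.2 vs 0.5 at large noise-free means: SI ratio alt/ref equals
        (0.5/0.5)/(0.2/0.8) = 4 within 5%."""
        cfg = t.SimConfig(
            n_genes=40, depth=2_000_000, dispersion=0.0, spike_dispersion=0.0,
            seed=13, pi_range=(0.2, 0.2), frac_txn_change=0, frac_stab_change=0,
            frac_pause_change=0,
        )
        genes = t.generate_genes(cfg)
        truth = t.generate_truth(genes, cfg)
        truth["pi_KO"] = 0.5
        samples = t.make_samples(truth, cfg)
        counts = t.simulate_counts(truth, samples, cfg)
        design = counts.samples[counts.samples["assay"] == "TT"]
        s = t.size_factors_tt(counts.spike_tt)
        si = t.stalling_index(counts.tss, counts.body, design, s, pseudocount=0)
        ratio = (si["KO"] / si["WT"]).median()
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestDiffStalling:
    def test_identical_counts_give_zero_dsi(self):
        design = make_design(["WT", "KO"], 3)
        tss = pd.DataFrame({s: [40, 10] for s in design.index}, index=["g0", "g1"])
        body = pd.DataFrame({s: [100, 90] for s in design.index}, index=["g0", "g1"])
        res = t.diff_stalling(tss, body, design, unit_size_factors(design), "WT")
        np.testing.assert_allclose(res["dSI"], 0.0)

    def test_null_dsi_centered_at_zero(self):
        cfg = t.SimConfig(
            n_genes=2000, depth=1_000_000, dispersion=0.0, seed=17,
            frac_txn_change=0, frac_stab_change=0, frac_pause_change=0,
        )
        genes = t.generate_genes(cfg)
        truth = t.generate_truth(genes, cfg)
        samples = t.make_samples(truth, cfg)
        counts = t.simulate_counts(truth, samples, cfg)
        design = counts.samples[counts.samples["assay"] == "TT"]
        s = t.size_factors_tt(counts.spike_tt)
        res = t.diff_stalling(counts.tss, counts.body, design, s, "WT")
        assert abs(res["dSI"].median()) < 0.05

    def test_pause_odds_doubling_shifts_dsi_by_one(self):
        """effect_pause=2 at pi_ref=0.5: SI goes from 1 to 2, so the median
        dSI of pause genes is ~1 (within 0.2) at alpha=0."""
        cfg = t.SimConfig(
            n_genes=300, depth=1_000_000, dispersion=0.0, seed=19,
            pi_range=(0.5, 0.5), frac_txn_change=0, frac_stab_change=0,
            frac_pause_change=0.5, effect_pause=2.0,
        )
        genes = t.generate_genes(cfg)
        truth = t.generate_truth(genes, cfg)
        samples = t.make_samples(truth, cfg)
        counts = t.simulate_counts(truth, samples, cfg)
        design = counts.samples[counts.samples["assay"] == "TT"]
        s = t.size_factors_tt(counts.spike_tt)
        res = t.diff_stalling(counts.tss, counts.body, design, s, "WT")
        pause = truth.index[truth["effect_class"] == "pause"]
        assert res.loc[pause, "dSI"].median() == pytest.approx(1.0, abs=0.2)

    def test_antisymmetry_under_condition_swap(self):
        design = make_design(["WT", "KO"], 3)
        tss = sim_counts(23, 100, design, 80.0, alpha=0.05)
        body = sim_counts(24, 100, design, 300.0, alpha=0.05)
        s = unit_size_factors(design)
        fwd = t.diff_stalling(tss, body, design, s, "WT")
        rev = t.diff_stalling(tss, body, design, s, "KO")
        np.testing.assert_allclose(fwd["dSI"], -rev["dSI"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)


class TestStabilityShift:
    @staticmethod
    def fake_diff(genes, lfc):
        return pd.DataFrame({"log2FC": lfc}, index=genes)

    def test_difference_arithmetic(self):
        shift = t.stability_shift(
            self.fake_diff(["g"], [1.0]), self.fake_diff(["g"], [0.0])
        )
        assert shift.loc["g", "delta"] == pytest.approx(1.0)

    def test_inner_join_drops_unshared_genes(self):
        shift = t.stability_shift(
            self.fake_diff(["g1", "g2"], [1.0, 2.0]), self.fake_diff(["g2"], [0.5])
        )
        assert list(shift.index) == ["g2"]

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            t.stability_shift(self.fake_diff(["a"], [1.0]), self.fake_diff(["b"], [1.0]))

    @staticmethod
    def run_arms(cfg):
        genes = t.generate_genes(cfg)
        truth = t.generate_truth(genes, cfg)
        samples = t.make_samples(truth, cfg)
        counts = t.simulate_counts(truth, samples, cfg)
        tt_design = counts.samples[counts.samples["assay"] == "TT"]
        rna_design = counts.samples[counts.samples["assay"] == "RNA"]
        s_tt = t.size_factors_tt(counts.spike_tt)
        s_rna = t.size_factors_rna(counts.spike_rna)
        diff_tt = t.diff_expression(counts.tss + counts.body, tt_design, s_tt, "WT")
        diff_rna = t.diff_expression(counts.gene, rna_design, s_rna, "WT")
        return truth, t.stability_shift(diff_rna, diff_tt)

    def test_pure_transcription_change_leaves_delta_null(self):
        """kappa halved, delta unchanged: both arms move together, median
        stability shift ~0."""
        cfg = t.SimConfig(
            n_genes=300, depth=600_000, dispersion=0.0, seed=29,
            frac_txn_change=1.0, frac_stab_change=0, frac_pause_change=0,
            effect_txn=0.5,
        )
        truth, shift = self.run_arms(cfg)
        assert abs(shift["delta"].median()) < 0.1

    def test_pure_stability_change_shifts_delta(self):
        """delta doubled, kappa unchanged: nascent arm flat, steady-state
        halves, median delta ~ -1."""
        cfg = t.SimConfig(
            n_genes=300, depth=600_000, dispersion=0.0, seed=31,
            frac_txn_change=0, frac_stab_change=1.0, frac_pause_change=0,
            effect_stab=2.0,
        )
        truth, shift = self.run_arms(cfg)
        assert shift["delta"].median() == pytest.approx(-1.0, abs=0.2)
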