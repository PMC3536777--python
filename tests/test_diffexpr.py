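import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import trsubtype.diffexpr as de
import trsubtype.matrixio as mio
import trsubtype.simulate as sim
from conftest import make_designs


def matrix_from(rows: dict[str, list[float]], sample_ids: list[str]):
    return mio.ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    )


class TestFitCellMeans:
    def test_hand_arithmetic_two_cells(self):
        designs = make_designs(
            {("parental", "vehicle"): ["p1", "p2"], ("TRA", "vehicle"): ["a1", "a2"]}
        )
        matrix = matrix_from({"g": [0.0, 2.0, 4.0, 6.0]}, ["p1", "p2", "a1", "a2"])
        fit = de.fit_cell_means(matrix, designs)
        assert fit.means.loc["g", "parental|vehicle"] == 1.0
        assert fit.means.loc["g", "TRA|vehicle"] == 5.0
        assert fit.s2[0] == pytest.approx(2.0)
        assert fit.df == 2

    def test_noiseless_simulation_gives_zero_variance(self):
        config = sim.SimulationConfig(n_genes=20, sigma_fixed=0.0, times=(3.0,), seed=1)
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_timecourse(specs, config)
        fit = de.fit_cell_means(matrix, designs)
        np.testing.assert_allclose(fit.s2, 0.0, atol=1e-20)

    def test_matches_oneway_anova_decomposition(self, rng):
        designs = make_designs(
            {
                ("parental", "vehicle"): ["p1", "p2", "p3"],
                ("TRA", "vehicle"): ["a1", "a2"],
                ("TRA", "T3"): ["t1", "t2", "t3", "t4"],
            }
        )
        ids = [d.sample_id for d in designs]
        values = rng.normal(size=(30, len(ids)))
        matrix = mio.ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(30)], columns=ids)
        )
        fit = de.fit_cell_means(matrix, designs)
        # oracle: per-gene total SS minus between-group SS
        groups = [["p1", "p2", "p3"], ["a1", "a2"], ["t1", "t2", "t3", "t4"]]
        for i, probe in enumerate(matrix.probe_ids):
            row = matrix.data.loc[probe]
            total_ss = ((row - row.mean()) ** 2).sum()
            between = sum(
                len(g) * (row[g].mean() - row.mean()) ** 2 for g in groups
            )
            df = len(ids) - len(groups)
            assert fit.s2[i] == pytest.approx((total_ss - between) / df)

    def test_all_singleton_cells_rejected(self):
        designs = make_designs(
            {("parental", "vehicle"): ["p1"], ("TRA", "vehicle"): ["a1"]}
        )
        matrix = matrix_from({"g": [0.0, 1.0]}, ["p1", "a1"])
        with pytest.raises(de.DesignError, match="degrees of freedom"):
            de.fit_cell_means(matrix, designs)


class TestModerateVariances:
    def test_identical_variances_are_degenerate_prior(self):
        s2 = np.full(200, 0.3)
        mod = de.moderate_variances(s2, df=4)
        assert mod.s0_2 == pytest.approx(0.3, rel=1e-6)
        np.testing.assert_allclose(mod.s2_tilde, 0.3, rtol=1e-6)

    def test_prior_df_zero_disables_shrinkage(self, rng):
        s2 = rng.chisquare(4, size=100) / 4 * 0.05
        mod = de.moderate_variances(s2, df=4, prior_df=0)
        np.testing.assert_array_equal(mod.s2_tilde, s2)

    def test_hyperparameters_recovered_from_hierarchy(self, rng):
        # s2 ~ s0^2 * F(df, d0) with d0 = 4, s0^2 = 0.04
        d0_true, s0_true, df = 4.0, 0.04, 6
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(df, size=5000) / df
        mod = de.moderate_variances(s2, df=df)
        assert 2.5 <= mod.d0 <= 6.5
        assert abs(mod.s0_2 - s0_true) / s0_true < 0.25

    def test_shrinkage_interpolates_and_is_monotone(self, rng):
        s2 = np.sort(rng.chisquare(4, size=500) / 4 * 0.05)
        mod = de.moderate_variances(s2, df=4)
        assert np.all(np.diff(mod.s2_tilde) >= 0)
        lo, hi = min(s2.min(), mod.s0_2), max(s2.max(), mod.s0_2)
        assert np.all(mod.s2_tilde >= lo - 1e-12)
        assert np.all(mod.s2_tilde <= hi + 1e-12)

    def test_too_few_genes_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            mod = de.moderate_variances(np.array([0.1, 0.2]), df=2)
        assert mod.d0 == 0.0

    def test_trigamma_inverse_roundtrip(self):
        from scipy import special

        y = np.array([0.1, 0.5, 2.0, 7.0])
        x = special.polygamma(1, y)
        np.testing.assert_allclose(de.trigamma_inverse(x), y, rtol=1e-8)


class TestContrasts:
    def test_noiseless_unliganded_effect_is_exact(self):
        config = sim.SimulationConfig(
            n_genes=10,
            archetype_proportions={a: (1.0 if a == "RO" else 0.0) for a in sim.ARCHETYPES},
            effect_sd_log=0.0, sigma_fixed=0.0, times=(3.0,), seed=1,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_timecourse(specs, config)
        res = de.run_de(matrix, designs, de.unliganded_contrast("TRA"))
        np.testing.assert_allclose(res["log2fc"], -1.0, atol=1e-12)

    def test_interaction_zero_when_t3_response_shared_with_parental(self):
        # same +1 T3 response in parental and receptor cells: no interaction
        designs = make_designs(
            {
                ("parental", "vehicle"): ["pv1", "pv2"],
                ("parental", "T3"): ["pt1", "pt2"],
                ("TRA", "vehicle"): ["av1", "av2"],
                ("TRA", "T3"): ["at1", "at2"],
            }
        )
        matrix = matrix_from(
            {"g": [5.0, 5.0, 6.0, 6.0, 5.5, 5.5, 6.5, 6.5]},
            ["pv1", "pv2", "pt1", "pt2", "av1", "av2", "at1", "at2"],
        )
        res = de.run_de(matrix, designs, de.interaction_contrast("TRA"), prior_df=0)
        assert res.loc["g", "log2fc"] == pytest.approx(0.0, abs=1e-12)

    def test_null_raw_pvalues_are_uniform(self):
        config = sim.SimulationConfig(
            n_genes=5000,
            archetype_proportions={a: (1.0 if a == "OO" else 0.0) for a in sim.ARCHETYPES},
            times=(3.0,), seed=13,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_timecourse(specs, config)
        res = de.run_de(matrix, designs, de.interaction_contrast("TRA"))
        assert stats.kstest(res["p_raw"], "uniform").pvalue > 0.01

    def test_missing_cell_named_in_error(self):
        designs = make_designs(
            {("parental", "vehicle"): ["p1", "p2"], ("TRA", "vehicle"): ["a1", "a2"]}
        )
        matrix = matrix_from({"g": [0.0, 1.0, 2.0, 3.0]}, ["p1", "p2", "a1", "a2"])
        fit = de.fit_cell_means(matrix, designs)
        mod = de.moderate_variances(fit.s2, fit.df, prior_df=0)
        with pytest.raises(de.DesignError, match="TRA\\|T3"):
            de.test_contrast(fit, mod, de.t3_contrast("TRA"))

    def test_t_sign_matches_fold_change_sign(self, rng):
        designs = make_designs(
            {("parental", "vehicle"): ["p1", "p2", "p3"], ("TRA", "vehicle"): ["a1", "a2", "a3"]}
        )
        ids = [d.sample_id for d in designs]
        matrix = mio.ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(100, 6)), index=[f"g{i}" for i in range(100)],
                         columns=ids)
        )
        res = de.run_de(matrix, designs, de.unliganded_contrast("TRA"))
        nonzero = res[res["log2fc"] != 0]
        assert np.all(np.sign(nonzero["t_mod"]) == np.sign(nonzero["log2fc"]))

    def test_contrast_weights_must_sum_to_zero(self):
        with pytest.raises(de.DesignError, match="sum"):
            de.ContrastSpec("bad", {"TRA|T3": 1.0, "TRA|vehicle": -0.5})


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            de.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert de.adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(de.adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_bh([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_permutation_consistent(self, p):
        p = np.asarray(p)
        adj = de.adjust_bh(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(de.adjust_bh(p[perm]), adj[perm])


class TestGate:
    def _results(self, log2fc, p_adj):
        return pd.DataFrame(
            {"log2fc": log2fc, "p_adj": p_adj},
            index=[f"g{i}" for i in range(len(log2fc))],
        )

    def test_boundary_inclusive_both_ways(self):
        res = self._results([1.0], [0.05])
        assert len(de.gate_significant(res)) == 1

    def test_fold_gate_excludes_just_below(self):
        res = self._results([0.99], [0.001])
        assert len(de.gate_significant(res)) == 0

    def test_matches_bruteforce_predicate(self, rng):
        res = self._results(rng.normal(0, 1.5, 300), rng.uniform(0, 1, 300))
        got = set(de.gate_significant(res, 2.0, 0.05).index)
        want = {
            probe
            for probe, row in res.iterrows()
            if abs(row["log2fc"]) >= 1.0 and row["p_adj"] <= 0.05
        }
        assert got == want

    def test_direction_labels(self):
        res = self._results([2.0, -2.0], [0.01, 0.01])
        gated = de.gate_significant(res)
        assert list(gated["direction"]) == ["induced", "repressed"]
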