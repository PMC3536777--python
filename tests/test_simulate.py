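import dataclasses

import numpy as np
import pytest
from scipy import stats

import trsubtype.diffexpr as de
import trsubtype.simulate as sim


def only(archetype):
    return {a: (1.0 if a == archetype else 0.0) for a in sim.ARCHETYPES}


def columns_for(designs, **conditions):
    out = []
    for d in designs:
        if all(getattr(d, k) == v for k, v in conditions.items()):
            out.append(d.sample_id)
    return out


class TestDrawGeneEffects:
    def test_null_configuration_has_zero_effects(self):
        config = sim.SimulationConfig(n_genes=50, archetype_proportions=only("OO"), seed=3)
        specs = sim.draw_gene_effects(config)
        assert len(specs) == 50
        for s in specs:
            assert all(s.u_effect[r] == 0 for r in ("TRA", "TRB"))
            assert all(s.l_effect[r] == 0 for r in ("TRA", "TRB"))

    def test_deterministic_under_fixed_seed(self):
        config = sim.SimulationConfig(n_genes=40, seed=11)
        assert sim.draw_gene_effects(config) == sim.draw_gene_effects(config)

    def test_archetype_frequencies_match_binomial_sampling(self):
        n = 10_000
        config = sim.SimulationConfig(
            n_genes=n, archetype_proportions={a: 1 / 9 for a in sim.ARCHETYPES}, seed=5
        )
        specs = sim.draw_gene_effects(config)
        counts = {a: 0 for a in sim.ARCHETYPES}
        for s in specs:
            counts[s.archetype] += 1
        p = 1 / 9
        se = np.sqrt(n * p * (1 - p))
        for a in sim.ARCHETYPES:
            assert abs(counts[a] - n * p) < 3 * se

    def test_invalid_proportions_rejected(self):
        bad = {a: 0.2 for a in sim.ARCHETYPES}
        config = sim.SimulationConfig(n_genes=10, archetype_proportions=bad)
        with pytest.raises(sim.ConfigError, match="sum"):
            sim.draw_gene_effects(config)

    def test_constitutive_patterns_have_no_t3_response(self):
        for archetype in ("RR", "II"):
            config = sim.SimulationConfig(
                n_genes=20, archetype_proportions=only(archetype), seed=2
            )
            for s in sim.draw_gene_effects(config):
                assert s.l_effect["TRA"] == 0
                assert s.u_effect["TRA"] != 0

    def test_late_beta_weight_exceeds_alpha_by_boost(self):
        config = sim.SimulationConfig(
            n_genes=300, archetype_proportions=only("OI"), late_beta_fraction=0.5, seed=4
        )
        specs = sim.draw_gene_effects(config)
        flagged = [s for s in specs if s.late_beta]
        assert flagged, "no late-beta genes drawn at fraction 0.5"
        for s in flagged:
            assert s.kinetic_weights["TRB"][24.0] == pytest.approx(
                config.late_beta_boost * s.kinetic_weights["TRA"][24.0]
            )

    def test_sigma_prior_recovered_by_ks(self):
        # pooled sample variances should follow s0^2 * F(df, d0)
        config = sim.SimulationConfig(
            n_genes=1000, archetype_proportions=only("OO"), times=(3.0,), seed=9
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_timecourse(specs, config)
        fit = de.fit_cell_means(matrix, designs)
        dist = stats.f(fit.df, config.noise_prior_df)
        res = stats.kstest(fit.s2 / config.noise_prior_scale, dist.cdf)
        assert res.pvalue > 0.01


class TestSimulateTimecourse:
    def test_noiseless_entries_equal_expected_values(self):
        config = sim.SimulationConfig(
            n_genes=10, archetype_proportions=only("RO"), effect_sd_log=0.0,
            sigma_fixed=0.0, late_beta_fraction=0.0, seed=1,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_timecourse(specs, config)
        baseline = np.array([s.baseline for s in specs])
        # RO: unliganded level -1, liganded level back at baseline (weight 1)
        veh = columns_for(designs, receptor="TRA", ligand="vehicle", time_hr=3.0)
        t3 = columns_for(designs, receptor="TRA", ligand="T3", time_hr=3.0)
        par = columns_for(designs, receptor="parental", ligand="T3", time_hr=3.0)
        np.testing.assert_allclose(matrix.data[veh].mean(axis=1), baseline - 1.0)
        np.testing.assert_allclose(matrix.data[t3].mean(axis=1), baseline, atol=1e-12)
        np.testing.assert_allclose(matrix.data[par].mean(axis=1), baseline)

    def test_kinetic_weight_scales_t3_response(self):
        config = sim.SimulationConfig(
            n_genes=5, archetype_proportions=only("OI"), effect_sd_log=0.0,
            sigma_fixed=0.0, late_beta_fraction=0.0, seed=1,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_timecourse(specs, config)
        baseline = np.array([s.baseline for s in specs])
        t3b = columns_for(designs, receptor="TRB", ligand="T3", time_hr=3.0)
        # TRB weight at 3 h is 0.5: half the asymptotic response
        np.testing.assert_allclose(matrix.data[t3b].mean(axis=1), baseline + 0.5)

    def test_bit_identical_under_same_seed(self, small_config):
        specs = sim.draw_gene_effects(small_config)
        m1, d1 = sim.simulate_timecourse(specs, small_config)
        m2, d2 = sim.simulate_timecourse(specs, small_config)
        assert np.array_equal(m1.values, m2.values)
        assert d1 == d2

    def test_design_covers_full_factorial(self, small_config):
        specs = sim.draw_gene_effects(small_config)
        _, designs = sim.simulate_timecourse(specs, small_config)
        assert len(designs) == 3 * 2 * 3 * small_config.replicates


class TestSimulateChxArm:
    def _noiseless(self, direct_fraction, seed=1, attenuation=0.0):
        config = sim.SimulationConfig(
            n_genes=8, archetype_proportions=only("OI"), effect_sd_log=0.0,
            sigma_fixed=0.0, direct_fraction=direct_fraction,
            indirect_attenuation=attenuation, chx_derepressed_fraction=0.0,
            late_beta_fraction=0.0, seed=seed,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_chx_arm(specs, config)
        return specs, matrix, designs

    def test_direct_genes_keep_full_t3_effect_under_chx(self):
        specs, matrix, designs = self._noiseless(direct_fraction=1.0)
        t3 = columns_for(designs, receptor="TRA", ligand="T3", chx=False)
        t3chx = columns_for(designs, receptor="TRA", ligand="T3", chx=True)
        np.testing.assert_allclose(
            matrix.data[t3].mean(axis=1), matrix.data[t3chx].mean(axis=1)
        )

    def test_indirect_gene_t3chx_equals_chx_alone(self):
        specs, matrix, designs = self._noiseless(direct_fraction=0.0)
        chx = columns_for(designs, receptor="TRA", ligand="vehicle", chx=True)
        t3chx = columns_for(designs, receptor="TRA", ligand="T3", chx=True)
        np.testing.assert_allclose(
            matrix.data[chx].mean(axis=1), matrix.data[t3chx].mean(axis=1)
        )

    def test_chx_alone_derepression_applied_to_one_receptor(self):
        config = sim.SimulationConfig(
            n_genes=30, archetype_proportions=only("OO"), sigma_fixed=0.0,
            chx_derepressed_fraction=1.0, seed=6,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_chx_arm(specs, config)
        for s in specs:
            assert sorted(s.chx_effect.values()) == [0.0, config.chx_effect_log2]
            side = max(s.chx_effect, key=s.chx_effect.get)
            chx = columns_for(designs, receptor=side, ligand="vehicle", chx=True)
            ctl = columns_for(designs, receptor=side, ligand="vehicle", chx=False)
            delta = (matrix.data.loc[s.probe_id, chx].mean()
                     - matrix.data.loc[s.probe_id, ctl].mean())
            assert delta == pytest.approx(config.chx_effect_log2)


class TestSimulateDoseSeries:
    def test_hand_computed_hill_fractions(self):
        config = sim.SimulationConfig(n_genes=1, sigma_fixed=0.0, seed=1,
                                      dose_grid=(0.0, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0))
        spec = sim.GeneEffectSpec(
            probe_id="g0", archetype="OI",
            u_effect={"TRA": 0.0, "TRB": 0.0}, l_effect={"TRA": 2.0, "TRB": 2.0},
            kinetic_weights={r: dict(config.kinetic_weights[r]) for r in ("TRA", "TRB")},
            direct=True, late_beta=False, chx_effect={"TRA": 0.0, "TRB": 0.0},
            ec50={"TRA": 1.0, "TRB": 1.0}, hill=1.0, sigma=0.0, baseline=8.0,
        )
        matrix, designs = sim.simulate_dose_series([spec], config)
        plateau = spec.kinetic_weights["TRA"][24.0] * 2.0
        for d in config.dose_grid:
            cols = columns_for(designs, receptor="TRA", dose_nM=d)
            expected = 8.0 + plateau * (d / (d + 1.0) if d > 0 else 0.0)
            assert matrix.data.loc["g0", cols].mean() == pytest.approx(expected)

    def test_midpoint_is_half_of_plateau(self):
        # at d = ec50 the induction is half the plateau, any hill slope
        config = sim.SimulationConfig(
            n_genes=6, archetype_proportions=only("OI"), sigma_fixed=0.0,
            dose_grid=(0.0, 1.0), ec50_log10_range=(0.0, 0.0),
            hill_range=(0.7, 2.5), late_beta_fraction=0.0, seed=2,
        )
        specs = sim.draw_gene_effects(config)
        matrix, designs = sim.simulate_dose_series(specs, config)
        at_ec50 = columns_for(designs, receptor="TRA", dose_nM=1.0)
        at_zero = columns_for(designs, receptor="TRA", dose_nM=0.0)
        induction = (matrix.data[at_ec50].mean(axis=1)
                     - matrix.data[at_zero].mean(axis=1)).to_numpy()
        plateau = np.array(
            [s.kinetic_weights["TRA"][24.0] * s.l_effect["TRA"] for s in specs]
        )
        np.testing.assert_allclose(induction, plateau / 2.0, rtol=1e-12)


class TestGroundTruthRoundTrip:
    def test_specs_roundtrip_through_tsv(self, small_config, tmp_path):
        specs = sim.draw_gene_effects(small_config)
        path = tmp_path / "truth.tsv"
        sim.write_gene_specs(specs, path)
        back = sim.read_gene_specs(path)
        assert len(back) == len(specs)
        for a, b in zip(specs, back):
            assert a.probe_id == b.probe_id
            assert a.archetype == b.archetype
            assert a.direct == b.direct
            assert a.ec50["TRB"] == pytest.approx(b.ec50["TRB"], rel=1e-12)
            for r in ("TRA", "TRB"):
                for t, w in a.kinetic_weights[r].items():
                    assert b.kinetic_weights[r][t] == pytest.approx(w, rel=1e-11)


class TestConfigReplacement:
    def test_times_subset_keeps_weights(self, small_config):
        sub = dataclasses.replace(small_config, times=(3.0,))
        sub.validate()
        specs = sim.draw_gene_effects(sub)
        matrix, designs = sim.simulate_timecourse(specs, sub)
        assert {d.time_hr for d in designs} == {3.0}
        assert matrix.shape[0] == sub.n_genes
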