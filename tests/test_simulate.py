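import numpy as np
import pandas as pd
import pytest

from crossprot.simulate import (SCENARIOS, SimConfig, ProteinBlock, VariantSpec,
                                draw_subpop_freqs, expected_cross_platform_r,
                                scenario_a, scenario_d, simulate_cohort,
                                write_cohort)


class TestSubpopFreqs:
    def test_zero_fst_degenerate(self, rng):
        np.testing.assert_array_equal(draw_subpop_freqs(0.3, 0.0, 4, rng),
                                      np.full(4, 0.3))

    def test_beta_mean(self):
        rng = np.random.default_rng(5)
        draws = draw_subpop_freqs(0.3, 0.1, 10_000, rng)
        assert abs(draws.mean() - 0.300) < 0.01

    def test_beta_variance_identity(self):
        rng = np.random.default_rng(6)
        draws = draw_subpop_freqs(0.3, 0.1, 20_000, rng)
        assert np.isclose(draws.var(), 0.1 * 0.3 * 0.7, rtol=0.1)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            draw_subpop_freqs(0.0, 0.1, 4, rng)
        with pytest.raises(ValueError):
            draw_subpop_freqs(0.5, 1.0, 4, rng)


class TestSimulateCohort:
    def test_same_seed_identical_outputs(self):
        cfg = scenario_d(300)
        sims = [simulate_cohort(cfg, seed=11) for _ in range(2)]
        pd.testing.assert_frame_equal(sims[0].genotypes.dosages, sims[1].genotypes.dosages)
        pd.testing.assert_frame_equal(sims[0].mat_a.values, sims[1].mat_a.values)
        pd.testing.assert_frame_equal(sims[0].samples, sims[1].samples)
        pd.testing.assert_frame_equal(sims[0].controls, sims[1].controls)

    def test_written_files_identical_across_runs(self, tmp_path):
        cfg = scenario_a(120)
        for d in ("run1", "run2"):
            write_cohort(simulate_cohort(cfg, seed=4), tmp_path / d)
        for name in ("genotypes.vcf", "protein_a.tsv", "samples.tsv", "truth.tsv"):
            assert (tmp_path / "run1" / name).read_bytes() == \
                   (tmp_path / "run2" / name).read_bytes()

    def test_group_eaf_tracks_drawn_frequency(self):
        """Empirical per-group EAF within 3 binomial SEs of the planted frequency."""
        cfg = scenario_d(2000)
        sim = simulate_cohort(cfg, seed=9)
        labels = sim.samples["ancestry"]
        pav = sim.genotypes.dosages["pav1"]
        from crossprot.simulate import SCENARIO_D_PAV_FREQS
        for g, p in SCENARIO_D_PAV_FREQS.items():
            sel = (labels == g).to_numpy()
            n2 = 2 * sel.sum()
            eaf = pav[sel].sum() / n2
            se = np.sqrt(p * (1 - p) / n2)
            assert abs(eaf - p) < 3 * se + 1e-12

    def test_hwe_dosage_variance(self):
        """At fst=0 the dosage variance matches 2q(1-q)."""
        cfg = SimConfig(groups={"G1": 4000}, n_unassigned=0,
                        variants=[VariantSpec("v1", "1", 100, 0.3, fst=0.0)],
                        proteins=[ProteinBlock("P1", "G", "a1", "b1", "1", 1000)])
        sim = simulate_cohort(cfg, seed=2)
        var = sim.genotypes.dosages["v1"].var()
        assert np.isclose(var, 2 * 0.3 * 0.7, rtol=0.08)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="variances"):
            SimConfig(proteins=[ProteinBlock("P1", "G", "a", "b", "1", 100,
                                             sigma_u2=0.0)])

    def test_ld_pairs_induce_correlation(self):
        cfg = SimConfig(groups={"G1": 3000}, n_unassigned=0,
                        variants=[VariantSpec("v1", "1", 100, 0.4, fst=0.0),
                                  VariantSpec("v2", "1", 200, 0.4, fst=0.0)],
                        proteins=[ProteinBlock("P1", "G", "a1", "b1", "1", 1000)],
                        ld_pairs=[("v1", "v2", 0.9)])
        sim = simulate_cohort(cfg, seed=3)
        r2 = np.corrcoef(sim.genotypes.dosages["v1"], sim.genotypes.dosages["v2"])[0, 1] ** 2
        assert r2 > 0.5


class TestExpectedR:
    def test_no_epitope_effect_adjustment_is_noop(self):
        args = dict(sigma_u2=1.0, delta_a=0.0, delta_b=0.0, v_g=0.5,
                    sigma_ea2=1.0, sigma_eb2=1.0)
        assert np.isclose(expected_cross_platform_r(**args),
                          expected_cross_platform_r(**args, adjusted=True))

    def test_reference_values(self):
        r_pre = expected_cross_platform_r(1.0, -1.0, 0.5, 0.5, 1.0, 1.0)
        r_post = expected_cross_platform_r(1.0, -1.0, 0.5, 0.5, 1.0, 1.0, adjusted=True)
        assert np.isclose(r_pre, 0.3254, atol=5e-5)
        assert np.isclose(r_post, 0.5000, atol=1e-12)

    def test_monte_carlo_matches_formula(self):
        """Empirical r of the latent platform measures at n=20,000 within
        +/-0.02 of the closed form."""
        cfg = SimConfig(
            groups={"G1": 20_000}, n_unassigned=0,
            variants=[VariantSpec("pav", "1", 100, 0.5, fst=0.0,
                                  consequence_class="missense",
                                  consequence_gene="G")],
            proteins=[ProteinBlock("P1", "G", "a1", "b1", "1", 1000,
                                   pav_variant="pav", delta_a=-1.0, delta_b=0.5)],
            covariate_effects={})
        sim = simulate_cohort(cfg, seed=8)
        # undo the monotone raw-scale maps to recover the latent measures
        m_a = (np.log(sim.mat_a.values["a1"]) - 7.0) / 0.5
        m_b = sim.mat_b.values["b1"] - 5.0
        r_emp = np.corrcoef(m_a, m_b)[0, 1]
        assert abs(r_emp - expected_cross_platform_r(1.0, -1.0, 0.5, 0.5, 1.0, 1.0)) < 0.02


class TestScenarioCatalogue:
    def test_all_scenarios_simulate(self):
        for name, builder in SCENARIOS.items():
            sim = simulate_cohort(builder(150), seed=1)
            assert len(sim.samples) >= 140
            assert sim.truth.shape[0] == len(sim.config.proteins)

    def test_scenario_d_truth_records_oracle(self):
        sim = simulate_cohort(scenario_d(500), seed=1)
        row = sim.truth.iloc[0]
        assert row["delta_a"] == -1.0 and row["delta_b"] == 0.5
        assert np.isclose(row["r_expected_post"], 0.5)
        assert 0.30 < row["r_expected_pre"] < 0.37
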