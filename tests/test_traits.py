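"""Trait architecture: correlation structure, effect sampling, calibration."""

import numpy as np
import pytest

from crossbreedsim.genome import build_genome_map, simulate_founders
from crossbreedsim.traits import (
    BW_E,
    BW_L,
    DEFAULT_TRAITS,
    TC_E,
    TC_L,
    EffectMatrix,
    build_correlation_matrix,
    build_trait_architecture,
    calibrate_residuals_and_accept,
    expected_f1_heterosis,
    genetic_values,
    sample_dominance,
    sample_qtl_effects,
    set_intercepts,
)

GRID = [(rg, rgxe) for rg in (-0.4, 0.0, 0.4) for rgxe in (0.4, 0.6, 0.8)]


class TestCorrelationMatrix:
    def test_entries_follow_separable_structure(self):
        c = build_correlation_matrix(0.4, 0.6)
        m = c.matrix
        assert m[BW_L, TC_L] == pytest.approx(0.4)
        assert m[BW_E, TC_E] == pytest.approx(0.4)
        assert m[BW_L, BW_E] == pytest.approx(0.6)
        assert m[TC_L, TC_E] == pytest.approx(0.6)
        assert m[BW_L, TC_E] == pytest.approx(0.24)
        assert m[TC_L, BW_E] == pytest.approx(0.24)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_identity_when_uncorrelated(self):
        assert np.allclose(build_correlation_matrix(0.0, 0.0).matrix, np.eye(4))

    @pytest.mark.parametrize("rg,rgxe", GRID)
    def test_grid_combinations_psd(self, rg, rgxe):
        eig = np.linalg.eigvalsh(build_correlation_matrix(rg, rgxe).matrix)
        assert eig.min() >= -1e-12

    @pytest.mark.parametrize("rg,rgxe", [(1.5, 0.5), (0.0, -0.1), (0.0, 1.2)])
    def test_out_of_range_rejected(self, rg, rgxe):
        with pytest.raises(ValueError):
            build_correlation_matrix(rg, rgxe)


@pytest.fixture(scope="module")
def founders():
    gmap = build_genome_map(seed=1)  # full 9000-QTL map
    local, exotic = simulate_founders(gmap, seed=5, n_females=120, n_males=30)
    return gmap, local, exotic


class TestEffectSampling:

    def test_realized_variance_hits_targets(self, founders):
        gmap, local, exotic = founders
        corr = build_correlation_matrix(0.0, 0.6)
        eff = sample_qtl_effects(gmap, corr, DEFAULT_TRAITS, local, exotic, seed=3)
        add_l, _, _ = genetic_values(local, eff)
        add_e, _, _ = genetic_values(exotic, eff)
        assert np.var(add_l[:, BW_L]) == pytest.approx(390.0, rel=1e-9)
        assert np.var(add_l[:, TC_L]) == pytest.approx(0.02, rel=1e-9)
        assert np.var(add_e[:, BW_E]) == pytest.approx(187.5, rel=1e-9)

    @pytest.mark.parametrize("rg,rgxe", [(0.0, 0.0), (0.4, 0.6), (-0.4, 0.8)])
    def test_effect_correlations_recovered(self, founders, rg, rgxe):
        """Sampled effect correlations match the requested 4x4 structure
        within sampling tolerance at 9000 QTL."""
        gmap, local, exotic = founders
        corr = build_correlation_matrix(rg, rgxe)
        eff = sample_qtl_effects(gmap, corr, DEFAULT_TRAITS, local, exotic, seed=7)
        realized = np.corrcoef(eff.a.T)
        assert np.abs(realized - corr.matrix).max() < 0.05

    def test_column_scaling_preserves_correlations(self, founders):
        gmap, local, exotic = founders
        corr = build_correlation_matrix(0.4, 0.6)
        eff = sample_qtl_effects(gmap, corr, DEFAULT_TRAITS, local, exotic, seed=9)
        before = np.corrcoef(eff.a.T)
        scaled = eff.a * np.array([3.0, 0.1, 7.0, 2.0])
        assert np.allclose(np.corrcoef(scaled.T), before)


class TestDominance:
    def test_degree_moments_and_product_rule(self, small_map, small_founders):
        local, exotic = small_founders
        corr = build_correlation_matrix(0.0, 0.6)
        eff = sample_qtl_effects(
            small_map, corr, DEFAULT_TRAITS, local, exotic, seed=11
        )
        eff = sample_dominance(eff, corr, DEFAULT_TRAITS, seed=13)
        assert np.array_equal(eff.d, np.abs(eff.a) * eff.delta)
        # mean dominance degree ~ 0.2 per trait (150 QTL -> ~3 SE tolerance)
        se = np.sqrt(np.array([1.0, 1.2, 1.0, 1.2]) / eff.delta.shape[0])
        assert np.all(np.abs(eff.delta.mean(axis=0) - 0.2) < 3.5 * se)

    def test_zero_degrees_kill_dominance_variance(self, small_map, small_founders):
        local, _ = small_founders
        corr = build_correlation_matrix(0.0, 0.6)
        eff = sample_qtl_effects(
            small_map, corr, DEFAULT_TRAITS, local, local, seed=15
        )
        eff.delta = np.zeros_like(eff.a)
        eff.d = np.abs(eff.a) * eff.delta
        _, dom, _ = genetic_values(local, eff)
        assert np.all(dom == 0)

    def test_founder_dominance_variance_positive(self, small_founders, small_effects):
        local, _ = small_founders
        _, dom, _ = genetic_values(local, small_effects)
        v = dom.var(axis=0)
        assert np.all(v > 0) and np.all(np.isfinite(v))


class TestGeneticValues:
    def test_single_qtl_hand_example(self):
        eff = EffectMatrix(
            qtl_idx=np.array([0]),
            a=np.full((1, 4), 2.0),
            delta=np.full((1, 4), 0.25),
            d=np.full((1, 4), 0.5),
        )
        add, dom, tot = genetic_values(np.array([[1.0], [2.0], [0.0]]), eff)
        assert add[:, 0] == pytest.approx([0.0, 2.0, -2.0])
        assert dom[:, 0] == pytest.approx([0.5, 0.0, 0.0])
        assert tot[:, 0] == pytest.approx([0.5, 2.0, -2.0])

    def test_fully_homozygous_animal_has_zero_dominance(self, small_map):
        n_qtl = small_map.qtl_idx.size
        eff = EffectMatrix(
            qtl_idx=small_map.qtl_idx,
            a=np.ones((n_qtl, 4)),
            d=np.ones((n_qtl, 4)),
        )
        _, dom, _ = genetic_values(np.full((1, n_qtl), 2.0), eff)
        assert np.all(dom == 0)

    def test_intercept_shift_is_linear(self, small_founders, small_effects):
        local, _ = small_founders
        from dataclasses import replace

        _, _, tot = genetic_values(local, small_effects)
        shifted = replace(
            small_effects, intercept=small_effects.intercept + 7.5
        )
        _, _, tot2 = genetic_values(local, shifted)
        assert np.allclose(tot2 - tot, 7.5)

    def test_invalid_genotype_rejected(self):
        eff = EffectMatrix(qtl_idx=np.array([0]), a=np.ones((1, 4)))
        with pytest.raises(ValueError):
            genetic_values(np.array([[3.0]]), eff)


class TestCalibration:
    def test_accepted_draw_heritabilities_in_band(self, small_founders, small_map):
        local, exotic = small_founders
        effects, h2 = build_trait_architecture(
            small_map, local, exotic, 0.0, 0.6, seed=31
        )
        assert abs(h2[BW_L] - 0.3) <= 0.03
        assert abs(h2[BW_E] - 0.3) <= 0.03
        assert abs(h2[TC_L] - 0.1) <= 0.01
        assert abs(h2[TC_E] - 0.1) <= 0.01
        assert np.all(effects.ve > 0)

    def test_reference_founder_means_match_targets(self, small_founders, small_effects):
        local, exotic = small_founders
        _, _, tot_l = genetic_values(local, small_effects)
        _, _, tot_e = genetic_values(exotic, small_effects)
        assert tot_l[:, BW_L].mean() == pytest.approx(325.0)
        assert tot_l[:, TC_L].mean() == pytest.approx(-1.0)
        assert tot_e[:, BW_E].mean() == pytest.approx(450.0)
        assert tot_e[:, TC_E].mean() == pytest.approx(-1.5)

    def test_additive_plus_residual_variance_hits_vp(self, small_founders, small_effects):
        """The calibration identity Va_realized + Ve = Vp holds exactly;
        the realized total phenotypic variance additionally carries the
        dominance variance implied by the dominance-degree spread, so it
        exceeds the nominal Vp by that amount."""
        local, exotic = small_founders
        for herd, t, vp in ((local, BW_L, 1300.0), (exotic, BW_E, 625.0)):
            add, dom, tot = genetic_values(herd, small_effects)
            assert add[:, t].var() + small_effects.ve[t] == pytest.approx(vp, rel=1e-6)
            a_c = add[:, t] - add[:, t].mean()
            d_c = dom[:, t] - dom[:, t].mean()
            nonadditive = tot[:, t].var() - add[:, t].var() - 2 * (a_c * d_c).mean()
            assert tot[:, t].var() + small_effects.ve[t] >= vp
            assert nonadditive == pytest.approx(dom[:, t].var(), rel=1e-6)

    def test_unit_heritability_means_no_residual(self, small_founders, small_map):
        from dataclasses import replace as dreplace

        local, exotic = small_founders
        specs = tuple(
            dreplace(s, h2_target=1.0, h2_tolerance=0.01) for s in DEFAULT_TRAITS
        )
        corr = build_correlation_matrix(0.0, 0.6)
        eff = sample_qtl_effects(small_map, corr, specs, local, exotic, seed=41)
        eff = sample_dominance(eff, corr, specs, seed=43)
        eff = set_intercepts(eff, specs, local, exotic)
        accepted, h2 = calibrate_residuals_and_accept(eff, specs, local, exotic, seed=45)
        assert accepted is not None
        assert np.allclose(accepted.ve, 0.0)
        assert np.allclose(h2, 1.0)


class TestHeterosisOracle:
    def test_f1_mean_matches_dominance_oracle(self, small_map, small_founders, small_effects):
        """Simulated F1 mean minus midparent mean equals the analytic
        dominance heterosis sum within Monte-Carlo error."""
        from crossbreedsim.core import MatingPlan, make_offspring
        from crossbreedsim.evaluate import f1_heterosis
        from crossbreedsim.population import IdAllocator

        local, exotic = small_founders
        dams = local.females()
        sires = exotic.males()
        rng = np.random.default_rng(51)
        n = 800
        plan = MatingPlan(
            dam_index=rng.integers(0, dams.n, n).astype(np.intp),
            sire_index=rng.integers(0, sires.n, n).astype(np.intp),
        )
        f1 = make_offspring(dams, sires, plan, small_map, 1, IdAllocator(10_000), rng)
        realized = f1_heterosis(dams, sires, f1, small_effects)
        p_l = dams.allele_freq(small_effects.qtl_idx)
        p_e = sires.allele_freq(small_effects.qtl_idx)
        expected = expected_f1_heterosis(small_effects, p_l, p_e)
        _, _, tot_f1 = genetic_values(f1, small_effects)
        _, dom_d, _ = genetic_values(dams, small_effects)
        _, dom_s, _ = genetic_values(sires, small_effects)
        for t in range(4):
            se = np.sqrt(
                tot_f1[:, t].var() / n
                + 0.25 * dom_d[:, t].var() / dams.n
                + 0.25 * dom_s[:, t].var() / sires.n
            )
            assert abs(realized[t] - expected[t]) < 3.5 * se

    def test_heterosis_zero_without_dominance(self, small_effects):
        from dataclasses import replace

        eff = replace(small_effects, d=np.zeros_like(small_effects.d))
        p = np.linspace(0.1, 0.9, eff.qtl_idx.size)
        assert np.allclose(expected_f1_heterosis(eff, p, 1 - p), 0.0)
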