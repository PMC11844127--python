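"""Structural behaviour of the breeding programs at miniature scale:
farm construction, bull allocation rules, window bookkeeping, and the
pedigree constraints of each crossbreeding strategy."""

import numpy as np
import pytest

from crossbreedsim.population import BREED_CROSS, BREED_EXOTIC, BREED_LOCAL, FEMALE
from crossbreedsim.runner import Scenario, prepare_replicate, run_strategy


@pytest.fixture(scope="module")
def state(mini_profile):
    return prepare_replicate(
        Scenario(0.0, 0.6, "SI_TCL50%"), 0, mini_profile, master_seed=3,
        exotic_to=mini_profile.final_generation,
    )


@pytest.fixture(scope="module")
def strategy_pops(state):
    pops = {}
    for name in ("FB", "IVB", "EVB", "PWB", "ROT", "F1"):
        pops.update(run_strategy(state, name))
    return pops


class TestBurnins:
    def test_local_cohorts_reach_and_hold_cap(self, state, mini_profile):
        sizes = {
            g: (state.local.gen == g).sum()
            for g in range(mini_profile.burnin_generations + 1)
        }
        assert sizes[0] == mini_profile.founder_females + mini_profile.founder_males
        # expansion phase grows the population, then the cap holds
        assert sizes[1] == mini_profile.founder_females
        for g in range(6, 21):
            assert sizes[g] == mini_profile.local_cohort

    def test_exotic_cohort_sizes_constant(self, state, mini_profile):
        for g in range(1, mini_profile.final_generation + 1):
            assert (state.exotic.gen == g).sum() == mini_profile.exotic_cohort

    def test_local_selection_raises_tick_resistance(self, state):
        from crossbreedsim.traits import TC_L

        loc = state.local
        early = np.nanmean(loc.subset(loc.gen == 2).phenotypes[:, TC_L])
        late = np.nanmean(loc.subset(loc.gen == 20).phenotypes[:, TC_L])
        assert late > early

    def test_exotic_selection_raises_body_weight(self, state):
        from crossbreedsim.traits import BW_E

        exo = state.exotic
        early = np.nanmean(exo.subset(exo.gen == 2).phenotypes[:, BW_E])
        late = np.nanmean(exo.subset(exo.gen == 20).phenotypes[:, BW_E])
        assert late > early


class TestFarms:
    def test_structure_invariants(self, state, mini_profile):
        farms = state.farms
        assert farms.n_farms == mini_profile.n_farms
        assert farms.n_villages == mini_profile.n_villages
        assert np.bincount(farms.village_of).tolist() == [
            mini_profile.farms_per_village
        ] * mini_profile.n_villages
        assert farms.herd_size.min() >= mini_profile.herd_min
        assert farms.herd_size.max() <= mini_profile.herd_max
        assert (
            mini_profile.total_cows_min
            <= farms.total_cows
            <= mini_profile.total_cows_max
        )

    def test_foundresses_match_herd_sizes(self, state):
        farms = state.farms
        counts = np.bincount(farms.foundresses.farm, minlength=farms.n_farms)
        assert np.array_equal(counts, farms.herd_size)
        assert np.all(farms.foundresses.sex == FEMALE)
        assert np.all(farms.foundresses.breed == BREED_LOCAL)


class TestInitialCross:
    def test_cohort_size_equals_total_cows(self, state):
        assert state.g21.n == state.farms.total_cows

    def test_each_bull_serves_exactly_four_farms(self, state, mini_profile):
        farms_of_sire = {}
        for sire, farm in zip(state.g21.sire, state.g21.farm):
            farms_of_sire.setdefault(sire, set()).add(farm)
        assert all(
            len(v) == mini_profile.farms_per_bull for v in farms_of_sire.values()
        )

    def test_sires_are_exotic_dams_local(self, state):
        exotic_ids = set(state.exotic.ids[state.exotic.breed == BREED_EXOTIC])
        assert set(state.g21.sire) <= exotic_ids
        assert set(state.g21.dam) <= set(state.farms.foundresses.ids)
        assert np.all(state.g21.breed == BREED_CROSS)


class TestSyntheticSchemes:
    def test_sire_counts_per_generation(self, strategy_pops, state, mini_profile):
        for name, expected in (
            ("FB", mini_profile.n_farms),
            ("IVB", mini_profile.village_bulls * mini_profile.n_villages),
            ("EVB", mini_profile.village_bulls * mini_profile.n_villages),
        ):
            pop = strategy_pops[name]
            for g in range(22, 41):
                sires = set(pop.sire[pop.gen == g])
                assert len(sires) == expected, (name, g)
        pwb = strategy_pops["PWB"]
        for g in range(22, 41):
            assert len(set(pwb.sire[pwb.gen == g])) <= mini_profile.pwb_bulls

    def test_fb_sires_come_from_own_farm(self, strategy_pops):
        pop = strategy_pops["FB"]
        farm_of = dict(zip(pop.ids, pop.farm))
        for g in range(22, 41):
            mask = pop.gen == g
            for sire, farm in zip(pop.sire[mask], pop.farm[mask]):
                assert farm_of[sire] == farm

    def test_evb_sires_come_from_a_single_different_village(self, strategy_pops):
        """Every generation the source village of each village's bulls is a
        derangement: a single other village."""
        pop = strategy_pops["EVB"]
        village_of = dict(zip(pop.ids, pop.village))
        for g in range(22, 41):
            mask = pop.gen == g
            for v in set(pop.village[mask]):
                sires = set(pop.sire[mask & (pop.village == v)])
                sources = {village_of[s] for s in sires}
                assert len(sources) == 1 and v not in sources

    def test_ivb_sires_come_from_own_village(self, strategy_pops):
        pop = strategy_pops["IVB"]
        village_of = dict(zip(pop.ids, pop.village))
        for g in range(22, 41):
            mask = pop.gen == g
            for sire, v in zip(pop.sire[mask], pop.village[mask]):
                assert village_of[sire] == v

    def test_cows_selected_within_window_and_farm(self, strategy_pops, mini_profile):
        pop = strategy_pops["PWB"]
        gen_of = dict(zip(pop.ids, pop.gen))
        farm_of = dict(zip(pop.ids, pop.farm))
        for g in (25, 40):
            mask = pop.gen == g
            for dam, farm in zip(pop.dam[mask], pop.farm[mask]):
                assert g - mini_profile.cow_window <= gen_of[dam] <= g - 1
                assert farm_of[dam] == farm

    def test_fb_homozygosity_rises_across_generations(self, strategy_pops, state):
        """Closed within-farm matings accumulate homozygosity over the
        synthetic generations."""
        from crossbreedsim.evaluate import inbreeding_coefficient

        pop = strategy_pops["FB"]
        f = {
            g: inbreeding_coefficient(pop.subset(pop.gen == g), state.gmap).mean()
            for g in (21, 28, 34, 40)
        }
        assert f[21] < f[28] < f[34] < f[40]

    def test_farm_cohorts_recover_to_herd_size(self, strategy_pops, state):
        """After the five-generation window fills, each farm again produces
        one offspring per cow of its herd size."""
        pop = strategy_pops["EVB"]
        farms = state.farms
        for g in (30, 40):
            counts = np.bincount(pop.farm[pop.gen == g], minlength=farms.n_farms)
            assert np.array_equal(counts, farms.herd_size)


class TestRotational:
    def test_sire_breed_alternates_with_parity(self, strategy_pops, state):
        """Exotic-nucleus sires at odd generations, local-nucleus sires at
        even generations (the initial exotic cross G21 anchors odd)."""
        pop = strategy_pops["ROT"]
        assert np.all(pop.breed == BREED_CROSS)
        exotic_ids = set(state.exotic.ids)
        for g in range(22, 41):
            sires = set(pop.sire[pop.gen == g])
            if g % 2 == 1:
                assert sires <= exotic_ids
            else:
                assert sires.isdisjoint(exotic_ids)

    def test_exotic_gene_fraction_oscillates(self, state, strategy_pops):
        """The expected exotic-gene fraction follows x' = x/2 + s/2 and
        oscillates towards 1/3 (after local sires) and 2/3 (after exotic)."""
        pop = strategy_pops["ROT"]
        # measure exotic ancestry via allele-frequency regression onto the
        # founder breed difference
        p_l = state.local.subset(state.local.gen == 20).allele_freq()
        p_e = state.exotic.subset(state.exotic.gen == 20).allele_freq()
        diff = p_e - p_l
        denom = float(diff @ diff)
        frac = {}
        for g in (36, 37, 38, 39, 40):
            cohort = pop.subset(pop.gen == g)
            frac[g] = float(diff @ (cohort.allele_freq() - p_l)) / denom
        for g in (37, 39):  # produced by exotic sires (odd)
            assert frac[g] > 0.5
        for g in (36, 38, 40):  # produced by local sires (even)
            assert frac[g] < 0.5


class TestF1Strategy:
    def test_f1_never_used_as_parents(self, strategy_pops):
        f1_ids = set(strategy_pops["F1"].ids)
        for name, pop in strategy_pops.items():
            assert f1_ids.isdisjoint(set(pop.sire))
            assert f1_ids.isdisjoint(set(pop.dam))

    def test_local_line_keeps_farm_sizes(self, strategy_pops, state):
        line = strategy_pops["LOC"]
        for g in range(21, 41):
            counts = np.bincount(
                line.farm[line.gen == g], minlength=state.farms.n_farms
            )
            assert np.array_equal(counts, state.farms.herd_size)

    def test_f1_parents_are_purebred(self, strategy_pops, state):
        f1 = strategy_pops["F1"]
        exotic_ids = set(state.exotic.ids)
        line_and_foundresses = set(strategy_pops["LOC"].ids) | set(
            state.farms.foundresses.ids
        )
        assert set(f1.sire) <= exotic_ids
        assert set(f1.dam) <= line_and_foundresses


class TestSharedState:
    def test_strategies_share_identical_g20_and_farms(self, mini_profile):
        s1 = prepare_replicate(
            Scenario(0.0, 0.6, "SI_TCL50%"), 1, mini_profile, master_seed=5
        )
        s2 = prepare_replicate(
            Scenario(0.0, 0.6, "SI_TCL50%"), 1, mini_profile, master_seed=5
        )
        assert np.array_equal(s1.local.haplo, s2.local.haplo)
        assert np.array_equal(s1.farms.herd_size, s2.farms.herd_size)
        assert np.array_equal(s1.g21.haplo, s2.g21.haplo)

    def test_schemes_differ_only_downstream_of_g21(self, strategy_pops):
        g21_ids = None
        for name in ("FB", "IVB", "EVB", "PWB", "ROT"):
            ids = set(strategy_pops[name].ids[strategy_pops[name].gen == 21])
            if g21_ids is None:
                g21_ids = ids
            assert ids == g21_ids
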