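"""One-stop replicate experiment used by the analysis drivers and the
acceptance machinery: run the shared burn-in pipeline for one replicate,
execute the requested crossbreeding strategies, and distil the headline
metrics (burn-in responses, divergence, inbreeding trajectories, heterosis
bookkeeping, gain slopes) into plain floats."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .evaluate import (
    f1_heterosis,
    gain_slope,
    inbreeding_coefficient,
)
from .genome import compute_fst
from .population import Herd
from .runner import Scenario, prepare_replicate, run_strategy
from .scale import REDUCED, ScaleProfile
from .traits import BW_E, BW_L, TC_L, expected_f1_heterosis, genetic_values

DEFAULT_SCENARIO = Scenario(0.0, 0.6, "SI_TCL50%")


def _phen_series(pop: Herd, trait: int, gens: Sequence[int]) -> np.ndarray:
    return np.array(
        [np.nanmean(pop.subset(pop.gen == g).phenotypes[:, trait]) for g in gens]
    )


def _tbv_series(pop: Herd, effects, trait: int, gens: Sequence[int]) -> np.ndarray:
    add, _, _ = genetic_values(pop, effects)
    return np.array([add[pop.gen == g, trait].mean() for g in gens])


def replicate_metrics(
    replicate: int,
    master_seed: int,
    scenario: Scenario = DEFAULT_SCENARIO,
    profile: ScaleProfile = REDUCED,
    strategies: Sequence[str] = ("FB",),
) -> Dict[str, float]:
    """Run one replicate and return its headline metrics.

    Always computed: burn-in responses (local TC_L gain; exotic BW_E gain
    and G20 mean), G20 between-breed divergence, realized founder
    heritabilities, first-cross inbreeding and heterosis.  Per requested
    strategy: the final-generation inbreeding, phenotypic/genetic gain
    slopes for BW_L and TC_L over G21-G40, and the G21->G22 dominance drop.
    """
    needs_late_exotic = any(s in ("F1", "ROT") for s in strategies)
    state = prepare_replicate(
        scenario, replicate, profile, master_seed,
        exotic_to=profile.final_generation if needs_late_exotic else None,
    )
    g20 = profile.burnin_generations
    burnin_gens = list(range(1, g20 + 1))
    out: Dict[str, float] = {}
    out["h2_BW_L"], out["h2_TC_L"], out["h2_BW_E"], out["h2_TC_E"] = map(
        float, state.h2_realized
    )
    local_tc = _phen_series(state.local, TC_L, burnin_gens)
    out["local_tc_gain"] = gain_slope(burnin_gens, local_tc)
    exotic_bw = _phen_series(state.exotic, BW_E, burnin_gens)
    out["exotic_bw_gain"] = gain_slope(burnin_gens, exotic_bw)
    out["exotic_bw_g20_mean"] = float(exotic_bw[-1])
    out["fst_g20"] = compute_fst(
        state.local.subset(state.local.gen == g20),
        state.exotic.subset(state.exotic.gen == g20),
    ).mean_fst
    out["f_g21"] = float(inbreeding_coefficient(state.g21, state.gmap).mean())

    # realized F1 heterosis of the initial cross, versus its actual parents,
    # and its agreement with the analytic dominance oracle sum(d * (dp)^2)
    sire_ids = np.unique(state.g21.sire)
    sires = state.exotic.subset(np.isin(state.exotic.ids, sire_ids))
    dams = state.farms.foundresses
    het = f1_heterosis(dams, sires, state.g21, state.effects)
    out["heterosis_BW_L"] = float(het[BW_L])
    out["heterosis_TC_L"] = float(het[TC_L])
    expected = expected_f1_heterosis(
        state.effects,
        dams.allele_freq(state.effects.qtl_idx),
        sires.allele_freq(state.effects.qtl_idx),
    )
    _, _, tot_f1 = genetic_values(state.g21, state.effects)
    _, dom_d, _ = genetic_values(dams, state.effects)
    _, dom_s, _ = genetic_values(sires, state.effects)
    for trait, tname in ((BW_L, "BW_L"), (TC_L, "TC_L")):
        # F1 animals cluster by sire (each bull serves four farms), so the
        # Monte-Carlo error of the F1 mean is governed by the between-sire
        # cluster means, not by the per-animal variance
        cluster_means = np.array(
            [tot_f1[state.g21.sire == s, trait].mean() for s in sire_ids]
        )
        se = np.sqrt(
            cluster_means.var(ddof=1) / sire_ids.size
            + 0.25 * dom_d[:, trait].var() / dams.n
            + 0.25 * dom_s[:, trait].var() / sires.n
        )
        out[f"heterosis_err_{tname}"] = float(het[trait] - expected[trait])
        out[f"heterosis_se_{tname}"] = float(se)

    cross_gens = list(range(g20 + 1, profile.final_generation + 1))
    for name in strategies:
        for label, pop in run_strategy(state, name).items():
            _, dom, _ = genetic_values(pop, state.effects)
            last = pop.subset(pop.gen == cross_gens[-1])
            out[f"{label}_f_final"] = float(
                inbreeding_coefficient(last, state.gmap).mean()
            )
            for trait, tname in ((BW_L, "BW_L"), (TC_L, "TC_L")):
                out[f"{label}_phen_gain_{tname}"] = gain_slope(
                    cross_gens, _phen_series(pop, trait, cross_gens)
                )
                out[f"{label}_gen_gain_{tname}"] = gain_slope(
                    cross_gens, _tbv_series(pop, state.effects, trait, cross_gens)
                )
            dom_g21 = dom[pop.gen == g20 + 1, BW_L].mean()
            dom_g22 = dom[pop.gen == g20 + 2, BW_L].mean()
            out[f"{label}_dd_drop_BW_L"] = float(dom_g21 - dom_g22)
    return out


def averaged_metrics(
    n_replicates: int,
    master_seed: int,
    scenario: Scenario = DEFAULT_SCENARIO,
    profile: ScaleProfile = REDUCED,
    strategies: Sequence[str] = ("FB",),
) -> Dict[str, float]:
    """Across-replicate mean of :func:`replicate_metrics`."""
    rows = [
        replicate_metrics(r, master_seed, scenario, profile, strategies)
        for r in range(n_replicates)
    ]
    keys = rows[0].keys()
    return {k: float(np.mean([row[k] for row in rows])) for k in keys}
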