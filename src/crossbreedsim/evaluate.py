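"""Evaluation metrics: phenotypic means, additive variance, genomic
inbreeding, TBV/DD trends, gain slopes, and replicate aggregation.

Conventions:

* the genomic inbreeding coefficient of an animal is the percentage of
  homozygous SNP-array loci, ``F = SNP_hom * 100 / SNP_tot`` (QTL excluded —
  they stand in for unobserved causal loci);
* true breeding value (TBV) and dominance deviation (DD) of an animal are
  its additive and dominance genetic values expressed as deviations from the
  mean of the merged 20-generation crossbreeding population of its strategy;
* phenotypic and genetic gains are ordinary-least-squares slopes of
  per-generation means on the generation index.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .population import Herd
from .traits import TRAIT_NAMES, EffectMatrix, genetic_values


def inbreeding_coefficient(herd_or_dosage: Union[Herd, np.ndarray],
                           gmap: Optional[GenomeMap] = None) -> np.ndarray:
    """Per-animal percentage of homozygous SNP loci.

    Accepts a Herd (with a genome map giving the SNP subset) or a raw
    (n x m) SNP dosage matrix coded 0/1/2.
    """
    if isinstance(herd_or_dosage, Herd):
        if gmap is None:
            raise ValueError("a genome map is required to locate SNP loci")
        dos = herd_or_dosage.dosage(gmap.snp_idx)
    else:
        dos = np.asarray(herd_or_dosage)
    if dos.ndim == 1:
        dos = dos[None, :]
    if dos.shape[1] == 0:
        raise ValueError("no SNP loci")
    return (dos != 1).mean(axis=1) * 100.0


def additive_variance(cohort: Herd, effects: EffectMatrix) -> np.ndarray:
    """Sample variance of additive genetic values per trait (length 4)."""
    if cohort.n < 2:
        raise ValueError("additive variance needs at least two animals")
    add, _, _ = genetic_values(cohort, effects)
    return add.var(axis=0, ddof=1)


def tbv_dd_deviations(
    merged: Herd, effects: EffectMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal TBV and DD of a merged multi-generation population.

    Both are centered on the merged-population mean, so each averages to
    zero over the merge.
    """
    if merged.n == 0:
        raise ValueError("empty merged population")
    add, dom, _ = genetic_values(merged, effects)
    return add - add.mean(axis=0), dom - dom.mean(axis=0)


def gain_slope(generations: Sequence[float], means: Sequence[float]) -> float:
    """OLS slope of per-generation means on generation index."""
    g = np.asarray(generations, dtype=float)
    y = np.asarray(means, dtype=float)
    if g.size < 2:
        raise ValueError("need at least two generations for a gain slope")
    if np.ptp(g) == 0:
        raise ValueError("constant generation index")
    return float(np.polyfit(g, y, 1)[0])


def f1_heterosis(
    local_parents: Herd, exotic_parents: Herd, f1_cohort: Herd, effects: EffectMatrix
) -> np.ndarray:
    """Realized heterosis per trait: F1 mean total genetic value minus the
    midparent mean total genetic value."""
    for pop in (local_parents, exotic_parents, f1_cohort):
        if pop.n == 0:
            raise ValueError("empty cohort in heterosis computation")
    _, _, tot_l = genetic_values(local_parents, effects)
    _, _, tot_e = genetic_values(exotic_parents, effects)
    _, _, tot_f1 = genetic_values(f1_cohort, effects)
    midparent = 0.5 * (tot_l.mean(axis=0) + tot_e.mean(axis=0))
    return tot_f1.mean(axis=0) - midparent


def generation_summary(
    pop: Herd,
    effects: EffectMatrix,
    gmap: GenomeMap,
    strategy: str = "",
    scenario: str = "",
    replicate: int = 0,
    generations: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per-generation metric table for one strategy of one replicate.

    Columns: strategy, scenario, replicate, generation, n, then per trait
    the phenotypic mean, additive variance, mean TBV and mean DD, plus the
    mean genomic inbreeding percentage.  TBV/DD are centered on the merged
    population over the listed generations.
    """
    gens = sorted(set(pop.gen)) if generations is None else sorted(generations)
    merged = pop.in_generations(gens)
    tbv, dd = tbv_dd_deviations(merged, effects)
    f = inbreeding_coefficient(merged, gmap)
    rows = []
    for g in gens:
        mask = merged.gen == g
        cohort = merged.subset(mask)
        row = {
            "strategy": strategy,
            "scenario": scenario,
            "replicate": replicate,
            "generation": g,
            "n": int(cohort.n),
            "mean_F": float(f[mask].mean()),
        }
        av = additive_variance(cohort, effects) if cohort.n > 1 else np.full(4, np.nan)
        for t, name in enumerate(TRAIT_NAMES):
            row[f"phen_mean_{name}"] = float(np.nanmean(cohort.phenotypes[:, t])) if np.isfinite(
                cohort.phenotypes[:, t]).any() else np.nan
            row[f"va_{name}"] = float(av[t])
            row[f"tbv_{name}"] = float(tbv[mask, t].mean())
            row[f"dd_{name}"] = float(dd[mask, t].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_replicates(summaries: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate mean and standard deviation per
    (strategy, scenario, generation, metric)."""
    if summaries.empty:
        raise ValueError("no replicate summaries to aggregate")
    keys = ["strategy", "scenario", "generation"]
    metrics = [
        c for c in summaries.columns if c not in keys + ["replicate", "n"]
    ]
    grouped = summaries.groupby(keys)[metrics]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()


def gains_table(summary: pd.DataFrame, traits: Sequence[str] = ("BW_L", "TC_L")) -> pd.DataFrame:
    """Phenotypic and genetic gain (slopes over the listed generations) per
    strategy from a generation-summary table."""
    rows = []
    for (strategy, scenario, replicate), df in summary.groupby(
        ["strategy", "scenario", "replicate"]
    ):
        df = df.sort_values("generation")
        row = {"strategy": strategy, "scenario": scenario, "replicate": replicate}
        for name in traits:
            row[f"phen_gain_{name}"] = gain_slope(
                df["generation"], df[f"phen_mean_{name}"]
            )
            row[f"gen_gain_{name}"] = gain_slope(df["generation"], df[f"tbv_{name}"])
        rows.append(row)
    return pd.DataFrame(rows)
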