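"""Four-trait genetic architecture: correlated additive and dominance effects.

The simulated traits are mature body weight (BW, kg) and tick-count incidence
(TC, -log10 tick count; higher = fewer ticks = better adapted), each expressed
in a local (L) and an exotic (E) environment:

    index 0: BW_L   index 1: TC_L   index 2: BW_E   index 3: TC_E

All four traits share the same QTL.  Additive effects are drawn from a
multivariate normal whose 4x4 correlation matrix combines the
within-environment genetic correlation ``r_g`` (BW vs TC) with the
cross-environment same-trait correlation ``r_gxe`` (GxE: identical genotype,
different environment).  Dominance effects are ``d_i = |a_i| * delta_i`` with
dominance degrees ``delta`` drawn around mean 0.2.  Per-trait additive effects
are rescaled so the realized additive variance in the trait's reference breed
(local for *_L, exotic for *_E) hits its target, residual variances are set
from the target narrow-sense heritability, and whole draws are rejected when
the realized founder heritability falls outside the accepted band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .genome import GenomeMap
from .population import Herd

TRAIT_NAMES = ("BW_L", "TC_L", "BW_E", "TC_E")
BW_L, TC_L, BW_E, TC_E = range(4)

#: trait indices expressed in each environment
ENV_TRAITS = {"local": (BW_L, TC_L), "exotic": (BW_E, TC_E)}


@dataclass(frozen=True)
class TraitSpec:
    """Target founder parameters of one trait."""

    name: str
    mu: float
    vp: float
    va_target: float
    h2_target: float
    h2_tolerance: float
    dd_mean: float
    dd_var: float
    reference_breed: str  # "local" or "exotic"


#: Founder trait parameters: means, variances, heritabilities and dominance
#: degree moments for the four simulated traits.
DEFAULT_TRAITS: Tuple[TraitSpec, ...] = (
    TraitSpec("BW_L", 325.0, 1300.0, 390.0, 0.3, 0.03, 0.2, 1.0, "local"),
    TraitSpec("TC_L", -1.0, 0.2, 0.02, 0.1, 0.01, 0.2, 1.2, "local"),
    TraitSpec("BW_E", 450.0, 625.0, 187.5, 0.3, 0.03, 0.2, 1.0, "exotic"),
    TraitSpec("TC_E", -1.5, 0.2, 0.02, 0.1, 0.01, 0.2, 1.2, "exotic"),
)


@dataclass(frozen=True)
class CorrelationStructure:
    """Separable trait x environment 4x4 genetic correlation matrix."""

    r_g: float
    r_gxe: float
    matrix: np.ndarray


def build_correlation_matrix(r_g: float, r_gxe: float) -> CorrelationStructure:
    """Kronecker (environment x trait) completion of the stated correlations.

    Within an environment BW and TC correlate at ``r_g``; the same trait
    across environments correlates at ``r_gxe``; the unstated cross terms
    (e.g. BW_L with TC_E) are ``r_g * r_gxe``, the minimal separable
    completion, which is positive semi-definite whenever |r_g| <= 1 and
    |r_gxe| <= 1.
    """
    if not -1.0 <= r_g <= 1.0:
        raise ValueError(f"r_g must lie in [-1, 1], got {r_g}")
    if not 0.0 <= r_gxe <= 1.0:
        raise ValueError(f"r_gxe must lie in [0, 1], got {r_gxe}")
    trait = np.array([[1.0, r_g], [r_g, 1.0]])
    env = np.array([[1.0, r_gxe], [r_gxe, 1.0]])
    # order (BW_L, TC_L, BW_E, TC_E) = (env x trait) Kronecker ordering
    matrix = np.kron(env, trait)
    return CorrelationStructure(r_g=r_g, r_gxe=r_gxe, matrix=matrix)


@dataclass
class EffectMatrix:
    """Per-QTL effects for the four traits plus trait-level constants.

    ``a``, ``delta`` and ``d`` have shape ``(n_qtl, 4)`` and refer to the QTL
    loci of ``qtl_idx`` (SNP-array loci carry no effects).  ``intercept`` and
    ``ve`` are per-trait scalars; ``ve`` is None until residual calibration.
    """

    qtl_idx: np.ndarray
    a: np.ndarray
    delta: Optional[np.ndarray] = None
    d: Optional[np.ndarray] = None
    intercept: Optional[np.ndarray] = None
    ve: Optional[np.ndarray] = None


def _mvn_correlated(
    rng: np.random.Generator, corr: np.ndarray, n: int, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    cov = corr * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    return mean + rng.standard_normal((n, cov.shape[0])) @ chol.T


def sample_qtl_effects(
    gmap: GenomeMap,
    corr: CorrelationStructure,
    specs: Sequence[TraitSpec],
    founders_local: Herd,
    founders_exotic: Herd,
    seed: Union[int, np.random.SeedSequence],
) -> EffectMatrix:
    """Draw correlated additive QTL effects and scale them to target variances.

    Each trait's column is multiplied by a positive scalar so that the
    realized additive variance among the trait's reference-breed founders
    equals its target; scalar column scaling leaves the effect correlation
    matrix untouched.
    """
    rng = np.random.default_rng(seed)
    qtl = gmap.qtl_idx
    a = _mvn_correlated(rng, corr.matrix, qtl.size, np.zeros(4), np.ones(4))
    x_local = founders_local.dosage(qtl).astype(np.float64) - 1.0
    x_exotic = founders_exotic.dosage(qtl).astype(np.float64) - 1.0
    for t, spec in enumerate(specs):
        x = x_local if spec.reference_breed == "local" else x_exotic
        realized = float(np.var(x @ a[:, t]))
        if realized <= 0.0:
            raise ZeroDivisionError(
                f"zero realized additive variance for {spec.name} before scaling"
            )
        a[:, t] *= np.sqrt(spec.va_target / realized)
    return EffectMatrix(qtl_idx=qtl, a=a)


def sample_dominance(
    effects: EffectMatrix,
    corr: CorrelationStructure,
    specs: Sequence[TraitSpec],
    seed: Union[int, np.random.SeedSequence],
) -> EffectMatrix:
    """Draw correlated dominance degrees and form ``d = |a| * delta``.

    Degrees share the additive 4x4 correlation matrix, with per-trait means
    0.2 and variances 1 (BW) / 1.2 (TC).
    """
    rng = np.random.default_rng(seed)
    mean = np.array([s.dd_mean for s in specs])
    sd = np.sqrt([s.dd_var for s in specs])
    delta = _mvn_correlated(rng, corr.matrix, effects.a.shape[0], mean, sd)
    d = np.abs(effects.a) * delta
    return replace(effects, delta=delta, d=d)


def _qtl_dosage(pop: Union[Herd, np.ndarray], effects: EffectMatrix) -> np.ndarray:
    if isinstance(pop, Herd):
        return pop.dosage(effects.qtl_idx).astype(np.float64)
    x = np.asarray(pop, dtype=np.float64)
    if not np.isin(x, (0.0, 1.0, 2.0)).all():
        raise ValueError("QTL genotypes must be coded 0/1/2")
    return x


def genetic_values(
    pop: Union[Herd, np.ndarray], effects: EffectMatrix
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-animal (additive, dominance, total) genetic values, shape (n, 4).

    additive = sum_i a_i (x_i - 1); dominance = sum_i d_i [x_i == 1];
    total = additive + dominance + intercept.
    """
    x = _qtl_dosage(pop, effects)
    additive = (x - 1.0) @ effects.a
    if effects.d is None:
        dominance = np.zeros_like(additive)
    else:
        dominance = (x == 1.0) @ effects.d
    intercept = np.zeros(4) if effects.intercept is None else effects.intercept
    return additive, dominance, additive + dominance + intercept


def set_intercepts(
    effects: EffectMatrix,
    specs: Sequence[TraitSpec],
    founders_local: Herd,
    founders_exotic: Herd,
) -> EffectMatrix:
    """Fix per-trait intercepts so that the mean total genetic value among the
    reference-breed founders equals the trait's phenotypic mean."""
    add_l, dom_l, _ = genetic_values(founders_local, replace(effects, intercept=None))
    add_e, dom_e, _ = genetic_values(founders_exotic, replace(effects, intercept=None))
    intercept = np.zeros(4)
    for t, spec in enumerate(specs):
        add, dom = (add_l, dom_l) if spec.reference_breed == "local" else (add_e, dom_e)
        intercept[t] = spec.mu - float(np.mean(add[:, t] + dom[:, t]))
    return replace(effects, intercept=intercept)


def calibrate_residuals_and_accept(
    effects: EffectMatrix,
    specs: Sequence[TraitSpec],
    founders_local: Herd,
    founders_exotic: Herd,
    seed: Union[int, np.random.SeedSequence],
) -> Tuple[Optional[EffectMatrix], np.ndarray]:
    """Set residual variances from target heritability; accept or reject.

    ``Ve_t = Va_realized * (1 - h2) / h2``.  Residuals are then drawn for the
    reference founders and the realized heritability
    ``Va_realized / (Va_realized + Ve_realized)`` must fall within the
    per-trait acceptance band; otherwise the draw is rejected (None returned)
    and the caller resamples the whole trait architecture.

    Returns (effects-with-Ve or None, realized h2 per trait).
    """
    rng = np.random.default_rng(seed)
    add_l, _, _ = genetic_values(founders_local, effects)
    add_e, _, _ = genetic_values(founders_exotic, effects)
    ve = np.zeros(4)
    h2_realized = np.zeros(4)
    ok = True
    for t, spec in enumerate(specs):
        add = add_l if spec.reference_breed == "local" else add_e
        va = float(np.var(add[:, t]))
        ve[t] = va * (1.0 - spec.h2_target) / spec.h2_target
        if ve[t] > 0:
            resid = rng.normal(0.0, np.sqrt(ve[t]), size=add.shape[0])
        else:
            resid = np.zeros(add.shape[0])
        ve_real = float(np.var(resid))
        h2_realized[t] = va / (va + ve_real) if va + ve_real > 0 else 0.0
        if abs(h2_realized[t] - spec.h2_target) > spec.h2_tolerance:
            ok = False
    if not ok:
        return None, h2_realized
    return replace(effects, ve=ve), h2_realized


def build_trait_architecture(
    gmap: GenomeMap,
    founders_local: Herd,
    founders_exotic: Herd,
    r_g: float,
    r_gxe: float,
    seed: Union[int, np.random.SeedSequence],
    specs: Sequence[TraitSpec] = DEFAULT_TRAITS,
    max_retries: int = 25,
) -> Tuple[EffectMatrix, np.ndarray]:
    """Full trait-sampling pipeline with the heritability rejection rule.

    Returns the accepted, fully calibrated effect matrix and the realized
    founder heritabilities.  Raises RuntimeError if no draw is accepted
    within ``max_retries`` attempts (diagnostics included).
    """
    corr = build_correlation_matrix(r_g, r_gxe)
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = base.spawn(max_retries)
    history = []
    for attempt in range(max_retries):
        s_add, s_dom, s_res = children[attempt].spawn(3)
        try:
            effects = sample_qtl_effects(
                gmap, corr, specs, founders_local, founders_exotic, s_add
            )
        except ZeroDivisionError:
            continue
        effects = sample_dominance(effects, corr, specs, s_dom)
        effects = set_intercepts(effects, specs, founders_local, founders_exotic)
        accepted, h2 = calibrate_residuals_and_accept(
            effects, specs, founders_local, founders_exotic, s_res
        )
        if accepted is not None:
            return accepted, h2
        history.append(h2)
    raise RuntimeError(
        f"no accepted trait draw in {max_retries} attempts; realized h2 history: "
        + "; ".join(np.array2string(h, precision=3) for h in history)
    )


def expected_f1_heterosis(
    effects: EffectMatrix, p_local_qtl: np.ndarray, p_exotic_qtl: np.ndarray
) -> np.ndarray:
    """Analytic F1 heterosis per trait: sum_i d_i * (p_i^local - p_i^exotic)^2."""
    if effects.d is None:
        return np.zeros(4)
    dp2 = (p_local_qtl - p_exotic_qtl) ** 2
    return dp2 @ effects.d


# ---------------------------------------------------------------------------
# Plain-text serialization for replicate reuse
# ---------------------------------------------------------------------------

def write_effects_table(
    path, effects: EffectMatrix, specs: Sequence[TraitSpec] = DEFAULT_TRAITS
) -> None:
    with open(path, "w") as fh:
        fh.write("trait\tintercept\tve\n")
        for t, spec in enumerate(specs):
            ic = "nan" if effects.intercept is None else f"{effects.intercept[t]:.10g}"
            ve = "nan" if effects.ve is None else f"{effects.ve[t]:.10g}"
            fh.write(f"{spec.name}\t{ic}\t{ve}\n")
        fh.write("trait\tlocus\ta\tdelta\td\n")
        for t, spec in enumerate(specs):
            for j, locus in enumerate(effects.qtl_idx):
                delta = effects.delta[j, t] if effects.delta is not None else float("nan")
                d = effects.d[j, t] if effects.d is not None else float("nan")
                fh.write(
                    f"{spec.name}\t{locus}\t{effects.a[j, t]:.10g}\t{delta:.10g}\t{d:.10g}\n"
                )
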