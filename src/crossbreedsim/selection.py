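"""Selection devices: phenotypic truncation, economic selection index, RR-BLUP.

Three ranking criteria drive every breeding decision in the simulated
programs:

* phenotypic truncation on a single trait (the local breed's tick-count
  selection),
* a two-trait selection index ``I = BW_L + v_TC * TC_L`` with economic
  weights in Euro per trait unit (crossbred bulls and cows),
* ridge-regression BLUP (RR-BLUP) genomic breeding values estimated from the
  42,000-locus SNP array, never from QTL (the exotic breed's body-weight
  selection).

Ties are always broken by ascending animal id so that selection is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg import blas

from .genome import GenomeMap
from .population import Herd
from .traits import BW_E, BW_L, TC_L


@dataclass(frozen=True)
class SelectionIndexSpec:
    """Economic weights of the two-trait index (BW_L weight fixed at 1 Euro)."""

    label: str
    v_tc: float
    v_bw: float = 1.0


#: The three index variants: economic value of TC_L chosen to put ~10/30/50%
#: of the index emphasis on tick-count incidence.
INDEX_SPECS = {
    "SI_TCL10%": SelectionIndexSpec("SI_TCL10%", v_tc=10.0),
    "SI_TCL30%": SelectionIndexSpec("SI_TCL30%", v_tc=35.0),
    "SI_TCL50%": SelectionIndexSpec("SI_TCL50%", v_tc=80.0),
}


def select_top(values: np.ndarray, ids: np.ndarray, n: int, context: str = "") -> np.ndarray:
    """Indices of the top-``n`` values (higher is better), ties by ascending id."""
    if n > values.size:
        raise ValueError(
            f"cannot select {n} from {values.size} candidates"
            + (f" ({context})" if context else "")
        )
    if np.isnan(values).any():
        raise ValueError("selection criterion contains missing values")
    order = np.lexsort((ids, -values))
    return order[:n]


def select_on_phenotype(herd: Herd, trait: int, n: int, context: str = "") -> Herd:
    """Top-``n`` animals by phenotype of ``trait`` (higher is better; for
    tick-count incidence higher means fewer ticks)."""
    return herd.subset(select_top(herd.phenotypes[:, trait], herd.ids, n, context))


def index_value(
    phenotype_bw: Union[float, np.ndarray],
    phenotype_tc: Union[float, np.ndarray],
    spec: SelectionIndexSpec,
) -> Union[float, np.ndarray]:
    """Selection-index score ``I = v_bw * BW_L + v_tc * TC_L``."""
    bw = np.asarray(phenotype_bw, dtype=float)
    tc = np.asarray(phenotype_tc, dtype=float)
    if np.isnan(bw).any() or np.isnan(tc).any():
        raise ValueError("index requires both BW_L and TC_L phenotypes")
    out = spec.v_bw * bw + spec.v_tc * tc
    return float(out) if out.ndim == 0 else out


def index_of_herd(herd: Herd, spec: SelectionIndexSpec) -> np.ndarray:
    return index_value(herd.phenotypes[:, BW_L], herd.phenotypes[:, TC_L], spec)


def relative_emphasis(sigma_tc: float, v_tc: float, sigma_bw: float) -> float:
    """Percentage of index emphasis on tick count:
    ``e_TC = (sigma_TC * v_TC) * 100 / (sigma_TC * v_TC + sigma_BW)``."""
    if sigma_tc <= 0 or sigma_bw <= 0:
        raise ValueError("phenotypic standard deviations must be positive")
    return (sigma_tc * v_tc) * 100.0 / (sigma_tc * v_tc + sigma_bw)


# ---------------------------------------------------------------------------
# RR-BLUP genomic breeding values
# ---------------------------------------------------------------------------

@dataclass
class EbvModel:
    """Ridge-regression marker-effect model on the SNP array.

    EBV(candidate) = centered SNP dosages @ marker_effects (+ mean).
    """

    snp_idx: np.ndarray
    marker_effects: np.ndarray
    column_means: np.ndarray
    mean_phenotype: float
    shrinkage: float

    def predict(self, herd: Herd) -> np.ndarray:
        z = herd.dosage(self.snp_idx).astype(np.float64) - self.column_means
        return z @ self.marker_effects


def fit_rrblup(
    training: Herd,
    gmap: GenomeMap,
    trait: int = BW_E,
    h2: float = 0.3,
    lam: Optional[float] = None,
) -> EbvModel:
    """Fit ridge-regression BLUP marker effects from SNP genotypes.

    Marker dosages are column-centered and the ridge solution is
    ``g = (Z'Z + lambda I)^-1 Z' (y - ybar)`` with
    ``lambda = (1 - h2) / h2 * sum_j var(Z_j)`` — i.e. the number of markers
    times the mean marker variance, scaled by the residual-to-genetic
    variance ratio at the (known, simulated) heritability.  The
    mathematically identical n x n dual solve is used when there are fewer
    training animals than markers.
    """
    if training.n < 2:
        raise ValueError(f"need at least 2 training animals, got {training.n}")
    y = training.phenotypes[:, trait]
    if np.isnan(y).any():
        raise ValueError("training animals lack phenotypes for the target trait")
    snp_idx = gmap.snp_idx
    z = training.dosage(snp_idx).astype(np.float64)
    col_means = z.mean(axis=0)
    z -= col_means
    col_var = np.einsum("ij,ij->j", z, z) / z.shape[0]
    total_var = float(col_var.sum())
    ybar = float(y.mean())
    if total_var == 0.0:  # every marker fixed: nothing to estimate
        return EbvModel(snp_idx, np.zeros(snp_idx.size), col_means, ybar, np.inf)
    if lam is None:
        lam = (1.0 - h2) / h2 * total_var
    yc = y - ybar
    n, m = z.shape
    if not np.isfinite(lam):
        g = np.zeros(m)
    elif n < m:
        # K = Z Z' + lam I is symmetric positive definite: build it with a
        # rank-k update (half the flops of a general matmul) and Cholesky-solve
        k = blas.dsyrk(1.0, np.asfortranarray(z))  # upper triangle of Z Z'
        k.flat[:: n + 1] += lam
        g = z.T @ cho_solve(cho_factor(k, lower=False), yc)
    else:
        a = blas.dsyrk(1.0, np.asfortranarray(z), trans=1)  # upper of Z'Z
        a.flat[:: m + 1] += lam
        g = cho_solve(cho_factor(a, lower=False), z.T @ yc)
    return EbvModel(snp_idx, g, col_means, ybar, float(lam))


def write_marker_effects(path, model: EbvModel) -> None:
    """Serialize a fitted marker-effect model as a tab-delimited table."""
    with open(path, "w") as fh:
        fh.write(f"# mean_phenotype\t{model.mean_phenotype:.10g}\n")
        fh.write(f"# shrinkage\t{model.shrinkage:.10g}\n")
        fh.write("locus\teffect\tcolumn_mean\n")
        for locus, eff, cm in zip(
            model.snp_idx, model.marker_effects, model.column_means
        ):
            fh.write(f"{locus}\t{eff:.10g}\t{cm:.10g}\n")


# ---------------------------------------------------------------------------
# Windowed selection
# ---------------------------------------------------------------------------

def window_candidates(
    pop: Herd, sex: int, current_gen: int, window: int
) -> Herd:
    """Animals of ``sex`` born in the last ``window`` generations
    (generations current_gen - window + 1 .. current_gen)."""
    if window < 1:
        raise ValueError("window must span at least one generation")
    lo = current_gen - window + 1
    mask = (pop.sex == sex) & (pop.gen >= lo) & (pop.gen <= current_gen)
    return pop.subset(mask)


def select_with_window(
    pop: Herd,
    criterion: str,
    n: int,
    sex: int,
    current_gen: int,
    window: int,
    trait: Optional[int] = None,
    index_spec: Optional[SelectionIndexSpec] = None,
    model: Optional[EbvModel] = None,
    context: str = "",
) -> Herd:
    """Truncation selection restricted to a sex and a generation window.

    ``criterion`` is one of 'phenotype' (requires ``trait``), 'index'
    (requires ``index_spec``) or 'ebv' (requires ``model``).
    """
    cands = window_candidates(pop, sex, current_gen, window)
    if cands.n < n:
        raise ValueError(
            f"only {cands.n} candidates for {n} slots"
            + (f" ({context})" if context else "")
        )
    if criterion == "phenotype":
        assert trait is not None
        values = cands.phenotypes[:, trait]
    elif criterion == "index":
        assert index_spec is not None
        values = index_of_herd(cands, index_spec)
    elif criterion == "ebv":
        assert model is not None
        values = model.predict(cands)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return cands.subset(select_top(values, cands.ids, n, context))
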