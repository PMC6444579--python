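"""Multinomial likelihood, maximum-likelihood fitting and Wald tests.

The observable data for a study design are counts of family genotype
categories, one multinomial per stratum (case/control x configuration).
Category probabilities arise from the origin-resolved cell table: cell
log-weights are linear in the free parameters (allele-frequency logits and
log relative risks), cells are normalized within a stratum, and observable
categories sum the cells they contain.  Summing over origin-ambiguous cells
gives the observed-data likelihood directly, which is equivalent to
resolving the ambiguity by EM.

Free parameters, on an unconstrained scale:

* ``freq:<allele>`` — multinomial logit of each non-reference allele
  frequency, shared across all strata of a design (cases and controls
  estimate a single set of population frequencies);
* ``RR:<allele>`` / ``RRcm:<allele>``, ``RRcf:<allele>`` /
  ``RRm:<allele>`` — log relative risks, applied in case strata only.

The reference allele's effects are fixed at 0 on the log scale and are not
free parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .triad_model import (
    CellTable,
    DesignSpec,
    EffectSpec,
    LocusSpec,
    enumerate_cells,
    observable_map,
)

__all__ = [
    "ParamLayout",
    "StratumModel",
    "DesignModel",
    "FitResult",
    "build_design_model",
    "category_probs",
    "loglik",
    "fit_mle",
    "wald",
    "build_contrasts",
    "counts_to_arrays",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamLayout:
    """Bijection between free-parameter positions and named symbols."""

    names: tuple[str, ...]
    n_freq: int  # leading frequency parameters

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r}; have {self.names}") from None

    @property
    def n_params(self) -> int:
        return len(self.names)


def _effect_param_names(effect: EffectSpec, locus: LocusSpec) -> list[str]:
    labels = [locus.alleles[i] for i in locus.nonref_indices]
    names: list[str] = []
    if effect.is_poo:
        names += [f"RRcm:{a}" for a in labels]
        names += [f"RRcf:{a}" for a in labels]
    else:
        names += [f"RR:{a}" for a in labels]
    if effect.has_maternal:
        names += [f"RRm:{a}" for a in labels]
    return names


def build_layout(effect: EffectSpec, locus: LocusSpec) -> ParamLayout:
    freq_names = [f"freq:{locus.alleles[i]}" for i in locus.nonref_indices]
    return ParamLayout(tuple(freq_names + _effect_param_names(effect, locus)),
                       n_freq=len(freq_names))


def true_params(locus: LocusSpec, effect: EffectSpec) -> np.ndarray:
    """Parameter vector at the generating (true) values."""
    ref = locus.reference_index
    theta = [np.log(locus.freqs[i] / locus.freqs[ref]) for i in locus.nonref_indices]
    nonref = locus.nonref_indices
    if effect.is_poo:
        theta += [np.log(effect.rr_poo_m[i]) for i in nonref]
        theta += [np.log(effect.rr_poo_f[i]) for i in nonref]
    else:
        theta += [np.log(effect.rr_child[i]) for i in nonref]
    if effect.has_maternal:
        theta += [np.log(effect.rr_maternal[i]) for i in nonref]
    return np.asarray(theta)


# ---------------------------------------------------------------------------
# Stratum models
# ---------------------------------------------------------------------------

@dataclass
class StratumModel:
    """Precomputed structure for one stratum's multinomial.

    ``E_full`` counts each allele among the four parental alleles of a cell
    (cell population probabilities are the monomials ``prod_a q_a^E``);
    ``Z`` is the cell-level design matrix of the log-linear model (effect
    columns are zero in control strata); ``M`` aggregates origin-resolved
    cells into observable categories.
    """

    is_case: bool
    configuration: str
    n_families: int
    categories: list[tuple]
    E_full: np.ndarray          # (n_cells, k) parental allele counts
    Z: np.ndarray               # (n_cells, n_params)
    M: np.ndarray               # (n_categories, n_cells)

    def cell_probs(self, theta: np.ndarray, layout: ParamLayout,
                   nonref: Sequence[int], ref: int) -> np.ndarray:
        k = self.E_full.shape[1]
        logits = np.zeros(k)
        logits[list(nonref)] = theta[: layout.n_freq]
        logq = logits - np.log(np.sum(np.exp(logits)))
        eta = self.E_full @ logq + self.Z[:, layout.n_freq:] @ theta[layout.n_freq:]
        eta -= eta.max()
        w = np.exp(eta)
        return w / w.sum()


@dataclass
class DesignModel:
    """All strata of a design under a common parameter layout."""

    locus: LocusSpec
    effect: EffectSpec
    design: DesignSpec
    layout: ParamLayout
    strata: list[StratumModel]


def _effect_columns(cells: CellTable, effect: EffectSpec, locus: LocusSpec) -> np.ndarray:
    """Exposure counts multiplying each log-RR parameter, per cell."""
    nonref = locus.nonref_indices
    cols: list[list[float]] = []
    for cell in cells.cells:
        am, af = cell.child
        row: list[float] = []
        if effect.is_poo:
            row += [float(am == a) for a in nonref]
            row += [float(af == a) for a in nonref]
        else:
            row += [float((am == a) + (af == a)) for a in nonref]
        if effect.has_maternal:
            row += [float(cell.mother.count(a)) for a in nonref]
        cols.append(row)
    return np.asarray(cols)


def check_identifiable(effect: EffectSpec, design: DesignSpec) -> None:
    """Reject known-overparameterized design/effect combinations up front.

    A pure case-mother-dyad design cannot separate PoO and maternal
    effects: both act through maternal alleles only, so the joint model is
    overparameterized.
    """
    if effect.model == "poo+maternal":
        case_cfgs = {c for c, n in design.case_families.items() if n > 0}
        if case_cfgs <= {"mc"} and not design.control_families:
            raise ValueError(
                "the mc design is overparameterized for the joint PoO + "
                "maternal model; add paternal genotypes or control families")


def build_design_model(locus: LocusSpec, effect: EffectSpec,
                       design: DesignSpec) -> DesignModel:
    check_identifiable(effect, design)
    layout = build_layout(effect, locus)
    cells = enumerate_cells(locus)
    E_full = np.asarray([[c.mother.count(a) + c.father.count(a)
                          for a in range(locus.n_alleles)] for c in cells.cells], float)
    X = _effect_columns(cells, effect, locus)
    E_free = E_full[:, list(locus.nonref_indices)]
    strata = []
    for is_case, cfg, n in design.strata():
        keys, M = observable_map(cells, cfg)
        Z = np.hstack([E_free, X if is_case else np.zeros_like(X)])
        strata.append(StratumModel(is_case, cfg, n, keys, E_full, Z, M))
    return DesignModel(locus, effect, design, layout, strata)


def category_probs(theta: np.ndarray, model: DesignModel,
                   stratum: StratumModel) -> np.ndarray:
    """Observable-category probabilities for one stratum at ``theta``."""
    pi = stratum.cell_probs(theta, model.layout, model.locus.nonref_indices,
                            model.locus.reference_index)
    return stratum.M @ pi


def _probs_and_jacobian(theta: np.ndarray, model: DesignModel,
                        stratum: StratumModel) -> tuple[np.ndarray, np.ndarray]:
    pi = stratum.cell_probs(theta, model.layout, model.locus.nonref_indices,
                            model.locus.reference_index)
    p = stratum.M @ pi
    # d pi / d theta = (diag(pi) - pi pi^T) Z; constant columns cancel.
    ZtPi = pi @ stratum.Z
    J = stratum.M @ (stratum.Z * pi[:, None] - np.outer(pi, ZtPi))
    return p, J


def loglik(theta: np.ndarray, model: DesignModel,
           counts: Mapping[tuple[bool, str], np.ndarray],
           with_grad: bool = False):
    """Multinomial log-likelihood (up to a constant) over all strata.

    ``counts`` maps ``(is_case, configuration)`` to an array aligned with
    the stratum's category list.  Categories with a positive count but zero
    model probability give ``-inf``.
    """
    total = 0.0
    grad = np.zeros(model.layout.n_params)
    for stratum in model.strata:
        n = np.asarray(counts[(stratum.is_case, stratum.configuration)], float)
        p, J = _probs_and_jacobian(theta, model, stratum)
        pos = n > 0
        if np.any(p[pos] <= 0):
            bad = [stratum.categories[i] for i in np.where(pos & (p <= 0))[0]]
            logger.warning("zero model probability for observed categories %s", bad)
            return (-np.inf, grad) if with_grad else -np.inf
        total += float(n[pos] @ np.log(p[pos]))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p > 0, n / np.where(p > 0, p, 1.0), 0.0)
        grad += J.T @ ratio
    return (total, grad) if with_grad else total


def counts_to_arrays(model: DesignModel,
                     counts: Mapping[tuple[bool, str], Mapping[tuple, int]],
                     ) -> dict[tuple[bool, str], np.ndarray]:
    """Align dict-of-dict category counts with each stratum's category order."""
    out = {}
    for stratum in model.strata:
        key = (stratum.is_case, stratum.configuration)
        table = counts.get(key, {})
        arr = np.zeros(len(stratum.categories))
        index = {cat: i for i, cat in enumerate(stratum.categories)}
        for cat, n in table.items():
            if cat not in index:
                raise KeyError(f"unknown category {cat!r} for stratum {key}")
            arr[index[cat]] = n
        out[key] = arr
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """MLE with covariance (inverse observed information) and Wald tests."""

    layout: ParamLayout
    estimates: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.layout.index(name)])

    def se(self, name: str) -> float:
        i = self.layout.index(name)
        return float(np.sqrt(self.covariance[i, i]))


def _start_values(model: DesignModel,
                  counts: Mapping[tuple[bool, str], np.ndarray]) -> np.ndarray:
    """Deterministic start: null effects, sample allele frequencies.

    Allele frequencies are estimated by counting alleles across all observed
    genotypes of all strata, with a half-count smoothing guard so every
    allele gets a positive start.
    """
    k = model.locus.n_alleles
    allele_counts = np.full(k, 0.5)
    for stratum in model.strata:
        n = counts[(stratum.is_case, stratum.configuration)]
        for cat, cnt in zip(stratum.categories, n):
            if cnt == 0:
                continue
            for geno in cat:
                allele_counts[geno[0]] += cnt
                allele_counts[geno[1]] += cnt
    q = allele_counts / allele_counts.sum()
    ref = model.locus.reference_index
    theta0 = np.zeros(model.layout.n_params)
    theta0[: model.layout.n_freq] = [np.log(q[i] / q[ref])
                                     for i in model.locus.nonref_indices]
    return theta0


def fit_mle(counts: Mapping[tuple[bool, str], np.ndarray] | Mapping[tuple[bool, str], Mapping[tuple, int]],
            effect: EffectSpec, design: DesignSpec, locus: LocusSpec | None = None,
            *, model: DesignModel | None = None, gtol: float = 1e-8,
            max_iter: int = 500) -> FitResult:
    """Maximize the observed-data log-likelihood by direct numerical optimization.

    Starts from null effects and sample allele frequencies; the covariance
    is the inverse observed information (numerical Hessian of the negative
    log-likelihood, central differences of the analytic gradient).
    """
    if model is None:
        if locus is None:
            raise ValueError("either locus or a prebuilt model is required")
        model = build_design_model(locus, effect, design)
    first = next(iter(counts.values()))
    if isinstance(first, Mapping):
        counts = counts_to_arrays(model, counts)  # type: ignore[arg-type]

    grad_fn = lambda t: loglik(t, model, counts, with_grad=True)[1]
    theta = _start_values(model, counts)
    ll, g = loglik(theta, model, counts, with_grad=True)
    converged = False
    n_iter = 0
    hess = None
    # Damped Newton ascent: analytic gradient, finite-difference Hessian.
    for n_iter in range(1, max_iter + 1):
        hess = _numerical_hessian(grad_fn, theta)
        hess = 0.5 * (hess + hess.T)
        try:
            step = np.linalg.solve(-hess, g)
        except np.linalg.LinAlgError:
            step = g
        if step @ g <= 0:  # not an ascent direction; fall back to gradient
            step = g
        t, accepted = 1.0, False
        while t > 1e-12:
            cand = theta + t * step
            ll_new, g_new = loglik(cand, model, counts, with_grad=True)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * (1 + abs(ll)):
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        rel_change = abs(ll_new - ll) / (1 + abs(ll))
        theta, ll, g = cand, ll_new, g_new
        if rel_change < 1e-10 or np.max(np.abs(g)) < gtol:
            converged = True
            break
    if not converged:
        logger.warning("fit did not converge after %d iterations "
                       "(gradient max-norm %.2e)", n_iter, np.max(np.abs(g)))
    hess = _numerical_hessian(grad_fn, theta)  # at the final iterate
    info = -0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full_like(info, np.nan)
        converged = False
    return FitResult(model.layout, theta, cov, float(ll), converged, n_iter)


def _numerical_hessian(grad_fn, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    n = len(theta)
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        H[:, i] = (grad_fn(theta + e) - grad_fn(theta - e)) / (2 * step)
    return H


# ---------------------------------------------------------------------------
# Wald tests and contrasts
# ---------------------------------------------------------------------------

def wald(fit: FitResult, contrast: np.ndarray | str) -> tuple[float, float]:
    """Wald chi-square (1 df) for a linear contrast of log-scale parameters.

    A string names a single parameter (tested against 0); an array is a
    contrast vector ``c`` giving the statistic ``(c' theta)^2 / (c' Cov c)``.
    """
    if isinstance(contrast, str):
        c = np.zeros(fit.layout.n_params)
        c[fit.layout.index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, float)
        if c.shape != (fit.layout.n_params,):
            raise ValueError(f"contrast length {c.shape} != {fit.layout.n_params}")
    v = float(c @ fit.covariance @ c)
    if v <= 0:
        raise ValueError("contrast has non-positive variance")
    stat = float(c @ fit.estimates) ** 2 / v
    return stat, float(stats.chi2.sf(stat, df=1))


def build_contrasts(layout: ParamLayout, effect: EffectSpec,
                    locus: LocusSpec) -> dict[str, np.ndarray]:
    """Built-in contrasts: each effect parameter vs 0, plus the PoO ratio.

    The PoO ratio contrast ``RRcm_cf:<allele>`` tests
    ``log RRR = log RR_M - log RR_F = 0`` (no parent-of-origin effect).
    """
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(layout.names[layout.n_freq:], start=layout.n_freq):
        c = np.zeros(layout.n_params)
        c[i] = 1.0
        out[name] = c
    if effect.is_poo:
        for a in (locus.alleles[i] for i in locus.nonref_indices):
            c = np.zeros(layout.n_params)
            c[layout.index(f"RRcm:{a}")] = 1.0
            c[layout.index(f"RRcf:{a}")] = -1.0
            out[f"RRcm_cf:{a}"] = c
    return out
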