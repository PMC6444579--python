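"""Analytic power and sample size via the Wald non-centrality route.

At the true parameter values the Wald statistic for a contrast ``c`` is
asymptotically noncentral chi-square with 1 degree of freedom and
non-centrality ``ncp = (c' theta)^2 / (c' I^-1 c)``, where ``I`` is the
expected Fisher information of the observable-category multinomial model
summed over design strata.  Power is the probability that this noncentral
chi-square exceeds the central chi-square critical value at the chosen
significance level.  Because the information is linear in the family
counts, sample-size calculation inverts the same relationship.

Nuisance allele-frequency parameters are never plugged in: the contrast
variance is read from the full inverse information, so the cost of
estimating frequencies (and any gain from control families sharing them)
is accounted for automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .likelihood import (
    DesignModel,
    build_contrasts,
    build_design_model,
    true_params,
    _probs_and_jacobian,
)
from .triad_model import DesignSpec, EffectSpec, LocusSpec

__all__ = ["PowerResult", "expected_information", "power_asymp", "sample_size"]


@dataclass
class PowerResult:
    """Per-allele, per-effect power values and their non-centralities.

    ``entries`` maps ``"<effect>:<allele>"`` (e.g. ``"RRcm_cf:2"``) to a
    dict with ``power``, ``ncp`` and ``variance``.  The reference allele is
    reported as ``"ref"`` in rendered tables and carries no entry.
    """

    alpha: float
    design: str
    locus: LocusSpec
    effect_model: str
    entries: dict[str, dict[str, float]] = field(default_factory=dict)

    def power(self, effect: str, allele: str | None = None) -> float:
        key = effect if ":" in effect else f"{effect}:{self._default_allele(allele)}"
        return self.entries[key]["power"]

    def ncp(self, effect: str, allele: str | None = None) -> float:
        key = effect if ":" in effect else f"{effect}:{self._default_allele(allele)}"
        return self.entries[key]["ncp"]

    def _default_allele(self, allele: str | None) -> str:
        if allele is not None:
            return allele
        nonref = self.locus.nonref_indices
        if len(nonref) != 1:
            raise ValueError("allele label required for multi-allelic loci")
        return self.locus.alleles[nonref[0]]

    @property
    def effect_names(self) -> list[str]:
        """Distinct effect-test names in display order."""
        seen: dict[str, None] = {}
        for key in self.entries:
            seen.setdefault(key.split(":")[0])
        return list(seen)


def expected_information(locus: LocusSpec, effect: EffectSpec,
                         design: DesignSpec, *,
                         model: DesignModel | None = None,
                         theta: np.ndarray | None = None) -> tuple[np.ndarray, DesignModel]:
    """Expected Fisher information at the true parameters.

    ``I = sum_s N_s sum_i (1/p_si) (dp_si/dtheta)(dp_si/dtheta)'`` over the
    observable categories ``i`` of each stratum ``s``.  Raises if the
    design/effect combination is not identifiable (singular information),
    naming the offending parameters.
    """
    if model is None:
        model = build_design_model(locus, effect, design)
    if theta is None:
        theta = true_params(locus, effect)
    I = np.zeros((model.layout.n_params,) * 2)
    for stratum in model.strata:
        p, J = _probs_and_jacobian(theta, model, stratum)
        I += stratum.n_families * (J.T @ (J / p[:, None]))
    _check_nonsingular(I, model)
    return I, model

def _check_nonsingular(I: np.ndarray, model: DesignModel) -> None:
    scale = np.abs(np.diag(I)).max()
    eigvals, eigvecs = np.linalg.eigh(I)
    bad = eigvals < 1e-10 * max(scale, 1.0)
    if np.any(bad):
        weights = np.abs(eigvecs[:, bad]).sum(axis=1)
        names = [n for n, w in zip(model.layout.names, weights) if w > 1e-3]
        raise ValueError(
            "singular expected information: the design cannot identify "
            f"parameters {names}; the model is overparameterized")


def power_asymp(locus: LocusSpec, effect: EffectSpec, design: DesignSpec,
                alpha: float = 0.05) -> PowerResult:
    """Asymptotic power for every built-in effect contrast.

    For each contrast ``c``: variance ``v = c' I^-1 c``, non-centrality
    ``ncp = (c' theta_true)^2 / v``, and
    ``power = P(chi2_1(ncp) > chi2_1 quantile at 1 - alpha)``.
    A contrast that is exactly zero at the truth gives power ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if effect.has_double_dose:
        raise ValueError(
            "asymptotic power assumes a multiplicative dose-response; "
            "double-dose deviations are supported by the simulation path only")
    I, model = expected_information(locus, effect, design)
    cov = np.linalg.inv(I)
    theta = true_params(locus, effect)
    crit = stats.chi2.ppf(1 - alpha, df=1)
    result = PowerResult(alpha=alpha, design=design.label(), locus=locus,
                         effect_model=effect.model)
    for name, c in build_contrasts(model.layout, effect, locus).items():
        v = float(c @ cov @ c)
        ncp = float(c @ theta) ** 2 / v
        power = float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 \
            else float(alpha)
        result.entries[name] = {"power": power, "ncp": ncp, "variance": v}
    return result


def _default_contrast(effect: EffectSpec) -> str:
    return "RRcm_cf" if effect.is_poo else "RR"


def sample_size(locus: LocusSpec, effect: EffectSpec, design_shape: DesignSpec,
                target_power: float, alpha: float = 0.05,
                contrast: str | None = None, allele: str | None = None,
                max_scale: int = 10_000_000) -> int:
    """Smallest integer design multiple reaching a target power.

    ``design_shape`` holds the relative family counts (e.g. ``mfc=1`` for a
    triads-only design, in which case the result is the number of triads);
    the returned ``N`` scales every count.  Uses the linearity of the
    non-centrality in ``N``: solve for the required ncp, divide, then
    verify minimality on the integer grid.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    contrast = contrast or _default_contrast(effect)
    unit = power_asymp(locus, effect, design_shape, alpha)
    ncp1 = unit.ncp(contrast, allele)
    if ncp1 <= 0:
        raise ValueError(
            f"contrast {contrast!r} is zero under the specified effect; "
            "power never exceeds alpha, no sample size attains the target")
    crit = stats.chi2.ppf(1 - alpha, df=1)
    ncp_req = optimize.brentq(
        lambda nc: stats.ncx2.sf(crit, df=1, nc=nc) - target_power,
        1e-12, 1e6)
    n = max(1, math.ceil(ncp_req / ncp1 - 1e-9))
    power_at = lambda m: stats.ncx2.sf(crit, df=1, nc=m * ncp1)
    while n > 1 and power_at(n - 1) >= target_power:
        n -= 1
    while power_at(n) < target_power:
        n += 1
        if n > max_scale:
            raise ValueError("required sample size exceeds max_scale")
    return n
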