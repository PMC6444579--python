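"""Simulate family genotype data, fit each replicate, estimate power.

The simulate-then-fit route complements the asymptotic approximation: it is
exact for any sample size (up to Monte-Carlo error), supports double-dose
penetrance deviations, and can degrade data with randomly missing family
members.  Each replicate draws family counts (or individual family records)
from the disease-conditional multinomial of the design, fits the model by
maximum likelihood, and records Wald p-values; power is the fraction of
replicates rejecting at the nominal significance level.

Randomness is organised as one root seed spawning per-replicate substreams
keyed by replicate index, so results are independent of how replicates are
scheduled (including parallel execution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .likelihood import (
    DesignModel,
    build_contrasts,
    build_design_model,
    fit_mle,
    wald,
)
from .triad_model import (
    CellTable,
    DesignSpec,
    EffectSpec,
    LocusSpec,
    case_probs,
    control_probs,
    enumerate_cells,
    marginalize,
)

__all__ = [
    "SimConfig",
    "SimPowerResult",
    "FamilyRecord",
    "simulate_counts",
    "simulate_families",
    "apply_missingness",
    "records_to_counts",
    "run_replicates",
    "write_plink",
]

logger = logging.getLogger(__name__)

MEMBERS = ("mother", "father", "child")


@dataclass(frozen=True)
class SimConfig:
    """Specification of one simulation study."""

    locus: LocusSpec
    effect: EffectSpec
    design: DesignSpec
    n_replicates: int = 1000
    seed: int = 0
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        rates = {m: float(self.missing_rates.get(m, 0.0)) for m in MEMBERS}
        unknown = set(self.missing_rates) - set(MEMBERS)
        if unknown:
            raise ValueError(f"unknown members in missing_rates: {sorted(unknown)}")
        if any(not (0.0 <= r < 1.0) for r in rates.values()):
            raise ValueError("missing rates must lie in [0, 1)")
        object.__setattr__(self, "missing_rates", rates)

    @property
    def has_missingness(self) -> bool:
        return any(r > 0 for r in self.missing_rates.values())


@dataclass
class SimPowerResult:
    """Rejection fractions with binomial standard errors per contrast."""

    power: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, np.ndarray]
    n_replicates: int
    n_used: int
    n_fit_failures: int
    n_families_discarded: int
    alpha: float
    seed: int


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Substream for one replicate; independent of scheduling order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def _conditional_cells(config: SimConfig) -> dict[bool, CellTable]:
    cells = enumerate_cells(config.locus)
    return {True: case_probs(cells, config.effect), False: control_probs(cells)}


def true_category_probs(config: SimConfig) -> dict[tuple[bool, str], tuple[list, np.ndarray]]:
    """Observable-category distributions generating the data, per stratum."""
    cond = _conditional_cells(config)
    out = {}
    for is_case, cfg, _n in config.design.strata():
        table = marginalize(cond[is_case], cfg)
        out[(is_case, cfg)] = (table.categories, table.probs)
    return out


def simulate_counts(config: SimConfig, replicate: int = 0
                    ) -> dict[tuple[bool, str], np.ndarray]:
    """One replicate of per-stratum multinomial category counts."""
    rng = _replicate_rng(config.seed, replicate)
    probs = true_category_probs(config)
    out = {}
    for is_case, cfg, n in config.design.strata():
        _keys, p = probs[(is_case, cfg)]
        out[(is_case, cfg)] = rng.multinomial(n, p)
    return out


# ---------------------------------------------------------------------------
# Record-level simulation (needed for missingness and PLINK export)
# ---------------------------------------------------------------------------

@dataclass
class FamilyRecord:
    """One simulated family; ``None`` genotype = member not genotyped.

    Parental genotypes are unordered allele-index pairs; the child genotype
    keeps (maternal, paternal) order internally, though exports erase it.
    """

    family_id: str
    is_case: bool
    mother: tuple[int, int] | None
    father: tuple[int, int] | None
    child: tuple[int, int] | None

    @property
    def configuration(self) -> str | None:
        if self.child is None:
            return None
        cfg = ("m" if self.mother is not None else "") + \
              ("f" if self.father is not None else "") + "c"
        return cfg if cfg in ("mfc", "mc", "fc", "c") else None


def simulate_families(config: SimConfig, replicate: int = 0) -> list[FamilyRecord]:
    """One replicate of individual family records (origin-resolved draws)."""
    rng = _replicate_rng(config.seed, replicate)
    cond = _conditional_cells(config)
    records: list[FamilyRecord] = []
    fam = 0
    for is_case, cfg, n in config.design.strata():
        table = cond[is_case]
        draws = rng.choice(len(table.cells), size=n, p=table.cond_prob)
        for idx in draws:
            fam += 1
            cell = table.cells[idx]
            records.append(FamilyRecord(
                family_id=f"F{fam:06d}",
                is_case=is_case,
                mother=cell.mother if "m" in cfg else None,
                father=cell.father if "f" in cfg else None,
                child=cell.child,
            ))
    return records


def apply_missingness(records: Sequence[FamilyRecord],
                      missing_rates: Mapping[str, float],
                      rng: np.random.Generator) -> tuple[list[FamilyRecord], int]:
    """Drop each genotyped member independently at its missingness rate.

    Families left without any genotyped member, or without a genotyped
    child (no supported configuration describes a child-less family), are
    discarded; the second return value counts them.
    """
    rates = {m: float(missing_rates.get(m, 0.0)) for m in MEMBERS}
    out: list[FamilyRecord] = []
    discarded = 0
    for rec in records:
        u = rng.random(3)
        mother = None if (rec.mother is None or u[0] < rates["mother"]) else rec.mother
        father = None if (rec.father is None or u[1] < rates["father"]) else rec.father
        child = None if (rec.child is None or u[2] < rates["child"]) else rec.child
        degraded = FamilyRecord(rec.family_id, rec.is_case, mother, father, child)
        if degraded.configuration is None:
            discarded += 1
        else:
            out.append(degraded)
    if discarded:
        logger.debug("discarded %d families with no usable configuration", discarded)
    return out, discarded


def records_to_counts(records: Sequence[FamilyRecord]
                      ) -> dict[tuple[bool, str], dict[tuple, int]]:
    """Re-bin (possibly degraded) records into per-configuration count tables."""
    out: dict[tuple[bool, str], dict[tuple, int]] = {}
    for rec in records:
        cfg = rec.configuration
        if cfg is None:
            continue
        child = tuple(sorted(rec.child))
        key: tuple
        if cfg == "mfc":
            key = (rec.mother, rec.father, child)
        elif cfg == "mc":
            key = (rec.mother, child)
        elif cfg == "fc":
            key = (rec.father, child)
        else:
            key = (child,)
        table = out.setdefault((rec.is_case, cfg), {})
        table[key] = table.get(key, 0) + 1
    return out


def _design_from_counts(counts: Mapping[tuple[bool, str], Mapping[tuple, int]]
                        ) -> DesignSpec:
    cases = {cfg: sum(t.values()) for (is_case, cfg), t in counts.items() if is_case}
    controls = {cfg: sum(t.values()) for (is_case, cfg), t in counts.items() if not is_case}
    return DesignSpec(cases, controls)


# ---------------------------------------------------------------------------
# Replicated fitting
# ---------------------------------------------------------------------------

def _fit_one(config: SimConfig, replicate: int,
             model: DesignModel | None) -> tuple[dict[str, float] | None, int]:
    """Simulate and fit one replicate.

    Returns (p-values per contrast or None on fit failure, number of
    families discarded by missingness).
    """
    if config.has_missingness:
        records = simulate_families(config, replicate)
        # dropout draws come from their own substream, independent of genotypes
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(replicate, 1)))
        records, discarded = apply_missingness(records, config.missing_rates, rng)
        counts = records_to_counts(records)
        design = _design_from_counts(counts)
        fit_model = build_design_model(config.locus, config.effect, design)
        fit = fit_mle(counts, config.effect, design, model=fit_model)
        layout_model = fit_model
    else:
        discarded = 0
        counts = simulate_counts(config, replicate)
        fit = fit_mle(counts, config.effect, config.design, model=model)
        layout_model = model
    if not fit.converged:
        return None, discarded
    contrasts = build_contrasts(layout_model.layout, config.effect, config.locus)
    return {name: wald(fit, c)[1] for name, c in contrasts.items()}, discarded


def run_replicates(config: SimConfig, n_jobs: int = 1) -> SimPowerResult:
    """Estimate power as the rejection fraction over simulated replicates.

    Replicates with non-converged fits are excluded and counted; a warning
    is emitted when they exceed 1% of the total.  Results are identical for
    any ``n_jobs`` because every replicate owns a seed substream.
    """
    model = None
    if not config.has_missingness:
        model = build_design_model(config.locus, config.effect, config.design)

    indices = range(config.n_replicates)
    if n_jobs > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one)(config, r, model) for r in indices)
    else:
        results = [_fit_one(config, r, model) for r in indices]

    ok = [p for p, _d in results if p is not None]
    n_discarded = sum(d for _p, d in results)
    n_fail = len(results) - len(ok)
    if n_fail > 0.01 * config.n_replicates:
        logger.warning("%d/%d replicates failed to converge and were excluded",
                       n_fail, config.n_replicates)
    if not ok:
        raise RuntimeError("every replicate failed to fit")
    names = list(ok[0])
    pvals = {n: np.array([r[n] for r in ok]) for n in names}
    R = len(ok)
    power = {n: float(np.mean(p < config.alpha)) for n, p in pvals.items()}
    se = {n: float(np.sqrt(power[n] * (1 - power[n]) / R)) for n in names}
    return SimPowerResult(power=power, se=se, pvalues=pvals,
                          n_replicates=config.n_replicates, n_used=R,
                          n_fit_failures=n_fail, n_families_discarded=n_discarded,
                          alpha=config.alpha, seed=config.seed)


# ---------------------------------------------------------------------------
# PLINK export
# ---------------------------------------------------------------------------

def write_plink(records: Sequence[FamilyRecord], prefix: str | Path,
                locus: LocusSpec, snp_id: str = "snp1", chromosome: int = 1,
                position: int = 1) -> tuple[Path, Path]:
    """Write whitespace-delimited text .ped/.map pedigree files.

    Each genotyped family member gets one .ped line: FID, IID, father IID,
    mother IID, sex (1=male, 2=female, 0=unknown), phenotype (2=case,
    1=control for the child; 0=unknown for parents), then two allele
    columns ("0 0" for a missing genotype).  Parent pointers are "0" when
    the parent is not in the file.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    def geno_cols(geno: tuple[int, int] | None) -> str:
        if geno is None:
            return "0 0"
        return f"{locus.alleles[geno[0]]} {locus.alleles[geno[1]]}"

    try:
        with open(ped_path, "w") as ped:
            for rec in records:
                fid = rec.family_id
                mother_iid = f"{fid}_M" if rec.mother is not None else "0"
                father_iid = f"{fid}_F" if rec.father is not None else "0"
                if rec.mother is not None:
                    ped.write(f"{fid} {mother_iid} 0 0 2 0 {geno_cols(rec.mother)}\n")
                if rec.father is not None:
                    ped.write(f"{fid} {father_iid} 0 0 1 0 {geno_cols(rec.father)}\n")
                if rec.child is not None:
                    pheno = 2 if rec.is_case else 1
                    ped.write(f"{fid} {fid}_C {father_iid} {mother_iid} 0 {pheno} "
                              f"{geno_cols(rec.child)}\n")
        with open(map_path, "w") as mp:
            mp.write(f"{chromosome} {snp_id} 0 {position}\n")
    except OSError as exc:
        raise OSError(f"failed writing PLINK files at {prefix}: {exc}") from exc
    return ped_path, map_path
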