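"""Family genotype enumeration and penetrance models for case-parent designs.

This module enumerates every genotype configuration of a nuclear family
(mother, father, child) at a single autosomal locus, assigns population
probabilities under Hardy-Weinberg equilibrium, random mating and Mendelian
transmission, and converts them into disease-conditional probabilities using
multiplicative relative-risk penetrance models for child, parent-of-origin
(PoO) and maternal effects.

The child's genotype is kept *origin-resolved*: it is an ordered pair
(maternally inherited allele, paternally inherited allele).  Parental origin
is what distinguishes a PoO effect from an ordinary child effect, but it is
not directly observable — when both parents and the child are heterozygous
the origin of the child's alleles is ambiguous.  :func:`marginalize` erases
origin (and absent family members) to produce the categories an observer can
actually distinguish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LocusSpec",
    "EffectSpec",
    "DesignSpec",
    "Cell",
    "CellTable",
    "CategoryTable",
    "CONFIGURATIONS",
    "enumerate_cells",
    "penetrance_weight",
    "case_probs",
    "control_probs",
    "marginalize",
    "observable_map",
]

#: Supported family configurations: m = mother, f = father, c = child.
CONFIGURATIONS = ("mfc", "mc", "fc", "c")

_PROB_TOL = 1e-12


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """A single autosomal locus with known population allele frequencies.

    Parameters
    ----------
    alleles
        Ordered allele labels, e.g. ``("1", "2")``.
    freqs
        Population frequency of each allele; strictly positive, sums to 1.
    reference_index
        Index of the reference allele.  Defaults to the most frequent
        allele (ties broken by lowest index), matching the convention that
        relative risks are expressed against the common allele.
    """

    alleles: tuple[str, ...]
    freqs: tuple[float, ...]
    reference_index: int = -1

    def __post_init__(self) -> None:
        alleles = tuple(str(a) for a in self.alleles)
        freqs = tuple(float(f) for f in self.freqs)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "freqs", freqs)
        if len(alleles) < 2:
            raise ValueError("a locus needs at least 2 alleles")
        if len(alleles) != len(freqs):
            raise ValueError("alleles and freqs must have equal length")
        if len(set(alleles)) != len(alleles):
            raise ValueError("allele labels must be unique")
        if any(not (0.0 < f < 1.0) for f in freqs):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if abs(sum(freqs) - 1.0) > _PROB_TOL:
            raise ValueError(f"allele frequencies sum to {sum(freqs)!r}, not 1")
        ref = self.reference_index
        if ref == -1:
            # most frequent allele, lowest index on ties
            ref = max(range(len(freqs)), key=lambda i: (freqs[i], -i))
            object.__setattr__(self, "reference_index", ref)
        if not 0 <= ref < len(alleles):
            raise ValueError(f"reference_index {ref} out of range")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def nonref_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(len(self.alleles)) if i != self.reference_index)


#: Effect models.  ``child`` and ``poo`` are mutually exclusive branches;
#: ``+maternal`` adds maternal-genotype relative risks to either.
EFFECT_MODELS = ("child", "poo", "child+maternal", "poo+maternal")


def _check_rr(name: str, rr: tuple[float, ...] | None, k: int, ref: int) -> tuple[float, ...] | None:
    if rr is None:
        return None
    rr = tuple(float(x) for x in rr)
    if len(rr) != k:
        raise ValueError(f"{name} must have one entry per allele ({k}), got {len(rr)}")
    if any(x <= 0 for x in rr):
        raise ValueError(f"{name} entries must be strictly positive")
    if abs(rr[ref] - 1.0) > 1e-12:
        raise ValueError(f"{name}[{ref}] is the reference allele and must equal 1")
    return rr


@dataclass(frozen=True)
class EffectSpec:
    """Relative-risk effect sizes for one of the four penetrance models.

    The penetrance (probability of disease given the family's genotypes) is
    a baseline ``B`` times a product of per-allele relative risks:

    * child model: ``B * RR_j * RR_l * RRdd_{jl}`` for a child carrying
      alleles ``j`` and ``l`` (``RRdd`` only when ``j == l``);
    * PoO model: ``B * RRcm_j * RRcf_l * RRdd_{jl}`` where ``j`` is the
      maternally and ``l`` the paternally inherited allele;
    * the ``+maternal`` variants multiply in ``RRmat_i * RRmat_j *
      RRmatdd_{ij}`` over the mother's own genotype ``(i, j)``.

    ``baseline`` never enters any computation here: conditioning on an
    affected child normalizes it away (rare-disease assumption).  Double-dose
    deviations (``rr_dd_*``) are accepted by the simulation path only; the
    asymptotic machinery assumes a multiplicative dose-response.
    """

    model: str
    rr_child: tuple[float, ...] | None = None
    rr_poo_m: tuple[float, ...] | None = None
    rr_poo_f: tuple[float, ...] | None = None
    rr_maternal: tuple[float, ...] | None = None
    rr_dd_child: tuple[float, ...] | None = None
    rr_dd_maternal: tuple[float, ...] | None = None
    baseline: float = 1.0
    n_alleles: int = 2
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.model not in EFFECT_MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {EFFECT_MODELS}")
        k, ref = self.n_alleles, self.reference_index
        has_child = self.model.startswith("child")
        has_poo = self.model.startswith("poo")
        has_mat = self.model.endswith("maternal")
        if has_child and self.rr_child is None:
            raise ValueError(f"model {self.model!r} requires rr_child")
        if has_poo and (self.rr_poo_m is None or self.rr_poo_f is None):
            raise ValueError(f"model {self.model!r} requires rr_poo_m and rr_poo_f")
        if has_mat and self.rr_maternal is None:
            raise ValueError(f"model {self.model!r} requires rr_maternal")
        if not has_child and self.rr_child is not None:
            raise ValueError(f"rr_child given but model is {self.model!r}")
        if not has_poo and (self.rr_poo_m is not None or self.rr_poo_f is not None):
            raise ValueError(f"rr_poo_m/rr_poo_f given but model is {self.model!r}")
        if not has_mat and self.rr_maternal is not None:
            raise ValueError(f"rr_maternal given but model is {self.model!r}")
        for name in ("rr_child", "rr_poo_m", "rr_poo_f", "rr_maternal",
                     "rr_dd_child", "rr_dd_maternal"):
            object.__setattr__(self, name, _check_rr(name, getattr(self, name), k, ref))
        if self.baseline <= 0:
            raise ValueError("baseline risk must be strictly positive")

    @property
    def has_maternal(self) -> bool:
        return self.model.endswith("maternal")

    @property
    def is_poo(self) -> bool:
        return self.model.startswith("poo")

    @property
    def has_double_dose(self) -> bool:
        """True when any double-dose deviation differs from 1."""
        for rr in (self.rr_dd_child, self.rr_dd_maternal):
            if rr is not None and any(abs(x - 1.0) > 1e-12 for x in rr):
                return True
        return False

    def null(self) -> "EffectSpec":
        """The same model shape with every relative risk set to 1."""
        ones = tuple(1.0 for _ in range(self.n_alleles))
        return EffectSpec(
            model=self.model,
            rr_child=ones if self.rr_child is not None else None,
            rr_poo_m=ones if self.rr_poo_m is not None else None,
            rr_poo_f=ones if self.rr_poo_f is not None else None,
            rr_maternal=ones if self.rr_maternal is not None else None,
            n_alleles=self.n_alleles,
            reference_index=self.reference_index,
        )


@dataclass(frozen=True)
class DesignSpec:
    """Counts of case and control families by configuration.

    ``case_families`` and ``control_families`` map configuration labels
    (``mfc``, ``mc``, ``fc``, ``c``) to family counts.  Hybrid designs such
    as ``mfc-mfc`` (case triads plus unrelated control triads) or ``mc-mc``
    are expressed by populating both maps.  Control-family genotypes follow
    the population distribution (rare-disease assumption).
    """

    case_families: Mapping[str, int]
    control_families: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cases = dict(self.case_families)
        controls = dict(self.control_families)
        for which, fam in (("case", cases), ("control", controls)):
            for label, n in fam.items():
                if label not in CONFIGURATIONS:
                    raise ValueError(
                        f"unknown {which} configuration {label!r}; "
                        f"supported: {', '.join(CONFIGURATIONS)}")
                if not (isinstance(n, (int, np.integer)) and n >= 0):
                    raise ValueError(f"{which} count for {label!r} must be a non-negative integer")
        if sum(cases.values()) < 1:
            raise ValueError("at least one case family is required")
        object.__setattr__(self, "case_families", cases)
        object.__setattr__(self, "control_families", controls)

    def strata(self) -> list[tuple[bool, str, int]]:
        """(is_case, configuration, count) for every non-empty stratum."""
        out = [(True, cfg, n) for cfg, n in self.case_families.items() if n > 0]
        out += [(False, cfg, n) for cfg, n in self.control_families.items() if n > 0]
        return out

    def scaled(self, factor: float) -> "DesignSpec":
        """Design with all family counts multiplied by an integer factor."""
        return DesignSpec(
            {c: int(round(n * factor)) for c, n in self.case_families.items()},
            {c: int(round(n * factor)) for c, n in self.control_families.items()},
        )

    @property
    def n_case(self) -> int:
        return sum(self.case_families.values())

    @property
    def n_control(self) -> int:
        return sum(self.control_families.values())

    def label(self) -> str:
        case = ",".join(f"{c}={n}" for c, n in self.case_families.items())
        ctrl = ",".join(f"{c}={n}" for c, n in self.control_families.items())
        return case + (f" / controls {ctrl}" if ctrl else "")


# ---------------------------------------------------------------------------
# Cells and tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """One origin-resolved family genotype configuration.

    Parental genotypes are unordered allele-index pairs ``(i, j)`` with
    ``i <= j``; the child genotype is the ordered pair
    ``(maternal-origin allele, paternal-origin allele)``.
    """

    mother: tuple[int, int]
    father: tuple[int, int]
    child: tuple[int, int]

    @property
    def child_unordered(self) -> tuple[int, int]:
        return tuple(sorted(self.child))  # type: ignore[return-value]

    def swapped_origin(self) -> "Cell":
        return Cell(self.mother, self.father, (self.child[1], self.child[0]))


@dataclass
class CellTable:
    """Origin-resolved cells with population and conditional probabilities."""

    locus: LocusSpec
    cells: list[Cell]
    pop_prob: np.ndarray
    cond_prob: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class CategoryTable:
    """Observable categories after erasing origin and absent members."""

    configuration: str
    categories: list[tuple]
    probs: np.ndarray


def _genotypes(k: int) -> list[tuple[int, int]]:
    return list(combinations_with_replacement(range(k), 2))


def _hwe_prob(geno: tuple[int, int], freqs: Sequence[float]) -> float:
    p = freqs[geno[0]] * freqs[geno[1]]
    return 2.0 * p if geno[0] != geno[1] else p


def enumerate_cells(locus: LocusSpec) -> CellTable:
    """Enumerate all origin-resolved family cells with population probabilities.

    Parents are drawn independently under HWE (random mating); each parent
    transmits one of its alleles with probability 1/2 (probability 1 from a
    homozygote).  For a diallelic locus this yields 16 cells; the
    double-heterozygote family with a heterozygous child appears twice,
    once per parental origin of the variant allele.
    """
    freqs = locus.freqs
    cells: list[Cell] = []
    probs: list[float] = []
    for mother in _genotypes(locus.n_alleles):
        p_m = _hwe_prob(mother, freqs)
        for father in _genotypes(locus.n_alleles):
            p_f = _hwe_prob(father, freqs)
            for am in dict.fromkeys(mother):  # preserves order, unique
                t_m = 1.0 if mother[0] == mother[1] else 0.5
                for af in dict.fromkeys(father):
                    t_f = 1.0 if father[0] == father[1] else 0.5
                    cells.append(Cell(mother, father, (am, af)))
                    probs.append(p_m * p_f * t_m * t_f)
    return CellTable(locus=locus, cells=cells, pop_prob=np.asarray(probs))


def penetrance_weight(cell: Cell, effect: EffectSpec) -> float:
    """Penetrance of a cell up to the baseline constant B.

    Multiplies the per-allele relative risks for the child's two alleles
    (origin-specific under a PoO model), the double-dose deviation when the
    child is homozygous, and — when the model includes maternal effects —
    the per-allele maternal relative risks of the mother's genotype.
    """
    am, af = cell.child
    w = 1.0
    if effect.is_poo:
        w *= effect.rr_poo_m[am] * effect.rr_poo_f[af]  # type: ignore[index]
    else:
        w *= effect.rr_child[am] * effect.rr_child[af]  # type: ignore[index]
    if am == af and effect.rr_dd_child is not None:
        w *= effect.rr_dd_child[am]
    if effect.has_maternal:
        mi, mj = cell.mother
        w *= effect.rr_maternal[mi] * effect.rr_maternal[mj]  # type: ignore[index]
        if mi == mj and effect.rr_dd_maternal is not None:
            w *= effect.rr_dd_maternal[mi]
    return w


def case_probs(cells: CellTable, effect: EffectSpec) -> CellTable:
    """Disease-conditional cell probabilities for case families.

    ``cond_prob_i ∝ pop_prob_i * penetrance_i``; the baseline risk cancels
    in the normalization.
    """
    w = np.array([penetrance_weight(c, effect) for c in cells.cells])
    num = cells.pop_prob * w
    return CellTable(cells.locus, cells.cells, cells.pop_prob, num / num.sum())


def control_probs(cells: CellTable) -> CellTable:
    """Conditional probabilities for control families.

    Under the rare-disease assumption the genotype distribution of
    unaffected families is the population distribution itself.
    """
    return CellTable(cells.locus, cells.cells, cells.pop_prob, cells.pop_prob.copy())


def _category_key(cell: Cell, configuration: str) -> tuple:
    child = cell.child_unordered
    if configuration == "mfc":
        return (cell.mother, cell.father, child)
    if configuration == "mc":
        return (cell.mother, child)
    if configuration == "fc":
        return (cell.father, child)
    if configuration == "c":
        return (child,)
    raise ValueError(f"unknown configuration {configuration!r}")


def observable_map(cells: CellTable, configuration: str) -> tuple[list[tuple], np.ndarray]:
    """Categories and 0/1 aggregation matrix M such that p_obs = M @ p_cell.

    Each origin-resolved cell maps to exactly one observable category:
    parental origin is erased and the genotypes of absent members are
    marginalized out.
    """
    keys = sorted({_category_key(c, configuration) for c in cells.cells})
    index = {k: i for i, k in enumerate(keys)}
    M = np.zeros((len(keys), len(cells.cells)))
    for j, cell in enumerate(cells.cells):
        M[index[_category_key(cell, configuration)], j] = 1.0
    return keys, M


def marginalize(cells: CellTable, configuration: str) -> CategoryTable:
    """Collapse conditional cell probabilities to observable categories."""
    if cells.cond_prob is None:
        raise ValueError("cond_prob not computed; call case_probs/control_probs first")
    keys, M = observable_map(cells, configuration)
    return CategoryTable(configuration, keys, M @ cells.cond_prob)


def format_genotype(geno: tuple[int, int], locus: LocusSpec) -> str:
    return locus.alleles[geno[0]] + "/" + locus.alleles[geno[1]]


def format_category(key: tuple, configuration: str, locus: LocusSpec) -> str:
    members = {"mfc": "mfc", "mc": "mc", "fc": "fc", "c": "c"}[configuration]
    parts = [f"{m}:{format_genotype(g, locus)}" for m, g in zip(members, key)]
    return " ".join(parts)
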