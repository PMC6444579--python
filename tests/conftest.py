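import numpy as np
import pytest

from triadpower import DesignSpec, EffectSpec, LocusSpec


@pytest.fixture
def locus():
    """Diallelic SNP with MAF 0.2; allele 1 is the reference."""
    return LocusSpec(("1", "2"), (0.8, 0.2))


@pytest.fixture
def triads500():
    return DesignSpec({"mfc": 500})


def make_effect(model, **rr):
    """EffectSpec for a diallelic locus with reference allele 0."""
    return EffectSpec(model=model, n_alleles=2, reference_index=0, **rr)


@pytest.fixture
def child_effect():
    return make_effect("child", rr_child=(1, 1.4))


@pytest.fixture
def poo_effect():
    return make_effect("poo", rr_poo_m=(1, 2), rr_poo_f=(1, 1.5))


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_tables(freqs, rr_child=None, rr_poo=None, rr_maternal=None,
                       rr_dd_child=None, rr_dd_maternal=None):
    """Exhaustive enumeration of family genotypes, written independently.

    Parents are *ordered* allele pairs (probability q_i * q_j each), each
    parent transmits slot 0 or slot 1 with probability 1/2, and the
    penetrance is looked up in an explicit table.  Returns a dict mapping
    (sorted mother, sorted father, (maternal allele, paternal allele)) to
    (population probability, case-conditional probability).
    """
    from itertools import product

    k = len(freqs)
    pop = {}
    weight = {}
    for mom in product(range(k), repeat=2):
        for dad in product(range(k), repeat=2):
            for slot_m in (0, 1):
                for slot_f in (0, 1):
                    am, af = mom[slot_m], dad[slot_f]
                    key = (tuple(sorted(mom)), tuple(sorted(dad)), (am, af))
                    p = freqs[mom[0]] * freqs[mom[1]] * freqs[dad[0]] * freqs[dad[1]]
                    p *= 0.25
                    w = 1.0
                    if rr_poo is not None:
                        rrm, rrf = rr_poo
                        w *= rrm[am] * rrf[af]
                    elif rr_child is not None:
                        w *= rr_child[am] * rr_child[af]
                    if am == af and rr_dd_child is not None:
                        w *= rr_dd_child[am]
                    if rr_maternal is not None:
                        w *= rr_maternal[mom[0]] * rr_maternal[mom[1]]
                        if mom[0] == mom[1] and rr_dd_maternal is not None:
                            w *= rr_dd_maternal[mom[0]]
                    pop[key] = pop.get(key, 0.0) + p
                    weight[key] = w
    total = sum(pop[c] * weight[c] for c in pop)
    cond = {c: pop[c] * weight[c] / total for c in pop}
    return pop, cond
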