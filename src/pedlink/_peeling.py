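"""Two-locus pedigree likelihood by genotype peeling.

The joint state of one individual is an ordered pair of two-locus
haplotypes.  A haplotype combines a marker allele (codes 1/2, index 0/1)
with a disease allele (wild type / disease), giving 4 haplotypes and 16
ordered single-person states.  The pedigree likelihood is the sum over all
members' joint states of

    prod founders  P(haplotype pair)            (linkage equilibrium, HWE)
    prod meioses   P(gamete | parent; theta)    (recombination fraction)
    prod members   P(marker call | state) * P(phenotype | disease genotype)

computed by variable elimination (peeling) over individuals.  Loopless
pedigrees give tree-structured factor graphs, so elimination cliques stay at
nuclear-family size.  Likelihoods are accumulated with per-step rescaling to
avoid underflow; the log scale is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .disease_model import DiseaseModel
from .pedio import MISSING, Pedigree, Phenotype

N_HAP = 4  # (marker allele 0/1) x (disease allele 0/1)
N_STATE = 16  # ordered haplotype pairs


class UnsupportedStructureError(ValueError):
    """Raised for pedigrees the peeler does not handle (loops)."""


def _hap(marker_allele: int, disease_allele: int) -> int:
    return 2 * marker_allele + disease_allele


def _state(pat_hap: int, mat_hap: int) -> int:
    return N_HAP * pat_hap + mat_hap


_MARKER_OF_HAP = np.arange(N_HAP) // 2
_DISEASE_OF_HAP = np.arange(N_HAP) % 2
STATE_PAT = np.arange(N_STATE) // N_HAP
STATE_MAT = np.arange(N_STATE) % N_HAP
STATE_MARKER_PAIR = np.stack(
    [_MARKER_OF_HAP[STATE_PAT], _MARKER_OF_HAP[STATE_MAT]], axis=1
)
STATE_COPIES = _DISEASE_OF_HAP[STATE_PAT] + _DISEASE_OF_HAP[STATE_MAT]


def founder_prior(marker_freq: float, q: float) -> np.ndarray:
    pm = np.array([marker_freq, 1.0 - marker_freq])
    pd = np.array([1.0 - q, q])
    hap = np.repeat(pm, 2) * np.tile(pd, 2)
    return np.outer(hap, hap).ravel()


def gamete_table(theta: float) -> np.ndarray:
    """T[g, s] = P(parent in state s transmits haplotype g)."""
    t = np.zeros((N_HAP, N_STATE))
    for s in range(N_STATE):
        pat, mat = STATE_PAT[s], STATE_MAT[s]
        pm, pd = _MARKER_OF_HAP[pat], _DISEASE_OF_HAP[pat]
        mm, md = _MARKER_OF_HAP[mat], _DISEASE_OF_HAP[mat]
        t[_hap(pm, pd), s] += (1 - theta) / 2  # parental
        t[_hap(mm, md), s] += (1 - theta) / 2
        t[_hap(pm, md), s] += theta / 2  # recombinant
        t[_hap(mm, pd), s] += theta / 2
    return t


def transmission_tensor(theta: float) -> np.ndarray:
    """P[c, f, m] = P(child state c | father state f, mother state m)."""
    g = gamete_table(theta)
    out = np.zeros((N_STATE, N_STATE, N_STATE))
    for c in range(N_STATE):
        out[c] = np.outer(g[STATE_PAT[c]], g[STATE_MAT[c]])
    return out


def evidence_vector(
    genotype: tuple[int, int], phenotype: Phenotype, model: DiseaseModel
) -> np.ndarray:
    """Per-person factor: marker-call consistency times penetrance."""
    ev = np.ones(N_STATE)
    a, b = genotype
    if a != MISSING:
        want = (min(a, b) - 1, max(a, b) - 1)
        got = np.sort(STATE_MARKER_PAIR, axis=1)
        ev *= (got[:, 0] == want[0]) & (got[:, 1] == want[1])
    if phenotype is not Phenotype.UNKNOWN:
        pen = np.asarray(model.penetrances)[STATE_COPIES]
        ev *= pen if phenotype is Phenotype.AFFECTED else 1.0 - pen
    return ev


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # one length-16 axis per variable


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    vars_out = a.vars + tuple(v for v in b.vars if v not in a.vars)
    ta = a.table.reshape(a.table.shape + (1,) * (len(vars_out) - len(a.vars)))
    # reorder b's axes to their order of appearance in vars_out, then pad
    # singleton axes for the variables b does not carry
    dest = [vars_out.index(v) for v in b.vars]
    order = sorted(range(len(dest)), key=lambda i: dest[i])
    tb = np.transpose(b.table, axes=order)
    shape = [N_STATE if v in b.vars else 1 for v in vars_out]
    tb = tb.reshape(shape)
    return _Factor(vars_out, ta * tb)


def _sum_out(f: _Factor, var: str) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(tuple(v for v in f.vars if v != var), f.table.sum(axis=ax))


def pedigree_log10_likelihood(
    pedigree: Pedigree,
    genotypes: dict[str, tuple[int, int]],
    model: DiseaseModel,
    theta: float,
    marker_freq: float,
) -> float:
    """log10 joint likelihood of one marker plus phenotypes at recombination
    fraction ``theta``.

    ``genotypes`` maps individual id -> unordered allele pair (1/2, 0 missing);
    untyped individuals may be absent from the mapping.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    if pedigree.has_loops():
        raise UnsupportedStructureError(
            f"family {pedigree.family_id}: pedigree loops are not supported "
            "by the peeler"
        )
    prior = founder_prior(marker_freq, model.q)
    trans = transmission_tensor(theta)
    factors: list[_Factor] = []
    for ind in pedigree.members:
        iid = ind.individual_id
        ev = evidence_vector(
            genotypes.get(iid, (MISSING, MISSING)), ind.phenotype, model
        )
        if ind.is_founder:
            factors.append(_Factor((iid,), prior * ev))
        else:
            factors.append(
                _Factor((iid, ind.father_id, ind.mother_id), trans * ev[:, None, None])
            )

    log_scale = 0.0
    remaining = {m.individual_id for m in pedigree.members}
    while remaining:
        # eliminate the variable whose combined factor has fewest variables
        best_var, best_cost = None, None
        for var in remaining:
            touched = {v for f in factors if var in f.vars for v in f.vars}
            cost = len(touched)
            if best_cost is None or cost < best_cost or (
                cost == best_cost and var < best_var
            ):
                best_var, best_cost = var, cost
        involved = [f for f in factors if best_var in f.vars]
        factors = [f for f in factors if best_var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        new = _sum_out(prod, best_var)
        peak = float(new.table.max())
        if peak <= 0.0:
            return -math.inf
        new.table /= peak
        log_scale += math.log10(peak)
        factors.append(new)
        remaining.discard(best_var)

    total = 1.0
    for f in factors:
        total *= float(f.table)  # all scalars now
    if total <= 0.0:
        return -math.inf
    return math.log10(total) + log_scale
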