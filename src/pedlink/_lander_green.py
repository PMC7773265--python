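"""Inheritance-vector machinery for multipoint linkage.

The multipoint HMM state is the inheritance vector v in {0,1}^b with one
bit per meiosis (paternal and maternal meiosis of every nonfounder); bit 0
means the grandpaternal chromosome was transmitted.  Between adjacent map
positions each bit flips independently with the Haldane recombination
probability for the gap.

Founder-phase reduction
-----------------------
Relabelling the two chromosomes of any founder maps the state space onto
itself (it flips all meiosis bits transmitted by that founder) and leaves
priors, emissions and phenotype likelihoods unchanged, because both founder
slots carry identical population priors.  The engine therefore freezes one
meiosis bit per transmitting founder and works on the reduced hypercube.
The transition kernel folds exactly onto the quotient: for a founder with
meioses (m1 frozen, m2..mk free) it becomes

    B_{m2..mk} o [ (1-theta) I + theta X_{m2..mk} ]

where B is the usual per-bit butterfly and X flips all the founder's free
bits jointly.  Setting ``founder_reduction=False`` keeps the full space;
both paths give identical likelihood ratios.

Emissions sum over founder-allele assignments restricted to orderings
consistent with the founders' own observed genotypes, which keeps the
assignment axis small on densely typed pedigrees.
"""

from __future__ import annotations

import itertools

import numpy as np

from .disease_model import DiseaseModel
from .pedio import MISSING, GenotypeMatrix, Pedigree, Phenotype

__all__ = ["InheritanceEngine", "CapacityError", "InconsistentGenotypesError"]

_ASSIGN_CHUNK = 4096


class CapacityError(ValueError):
    """Pedigree exceeds the configured meiosis-bit cap."""


class InconsistentGenotypesError(ValueError):
    """Marker genotypes impossible on every inheritance vector."""


class InheritanceEngine:
    def __init__(
        self,
        pedigree: Pedigree,
        bit_cap: int = 20,
        founder_reduction: bool = True,
    ):
        self.pedigree = pedigree
        order = pedigree.topological_order()
        self.members = order
        self.idx = {m.individual_id: i for i, m in enumerate(order)}
        self.founder_ids = [m.individual_id for m in order if m.is_founder]
        self.founder_no = {iid: k for k, iid in enumerate(self.founder_ids)}
        self.n_founders = len(self.founder_ids)

        # canonical meiosis order: nonfounders in topological order,
        # paternal bit before maternal bit
        self.meioses: list[tuple[str, int, str]] = []  # (child, side, parent)
        for m in order:
            if m.is_founder:
                continue
            self.meioses.append((m.individual_id, 0, m.father_id))
            self.meioses.append((m.individual_id, 1, m.mother_id))
        self.b_total = len(self.meioses)
        if self.b_total > bit_cap:
            raise CapacityError(
                f"family {pedigree.family_id}: {self.b_total} meiosis bits "
                f"exceed the cap of {bit_cap}; split the pedigree or raise "
                "the cap"
            )

        # founder groups and frozen bits
        self.fixed = np.zeros(self.b_total, dtype=bool)
        groups: dict[str, list[int]] = {}
        for bit, (_, _, parent) in enumerate(self.meioses):
            if pedigree[parent].is_founder:
                groups.setdefault(parent, []).append(bit)
        if founder_reduction:
            for bits in groups.values():
                self.fixed[bits[0]] = True
        self.founder_groups = groups
        self.founder_reduction = founder_reduction

        free_bits = [b for b in range(self.b_total) if not self.fixed[b]]
        self.free_pos = {b: p for p, b in enumerate(free_bits)}
        self.n_free = len(free_bits)
        self.n_states = 1 << self.n_free
        states = np.arange(self.n_states)

        def bit_values(bit: int) -> np.ndarray:
            if self.fixed[bit]:
                return np.zeros(self.n_states, dtype=np.int64)
            return (states >> self.free_pos[bit]) & 1

        # founder-allele slots: founder k owns slots 2k (phase 0) and 2k+1
        self.n_slots = 2 * self.n_founders
        slotP: dict[str, np.ndarray] = {}
        slotM: dict[str, np.ndarray] = {}
        bit_of = {
            (child, side): b for b, (child, side, _) in enumerate(self.meioses)
        }
        for m in order:
            iid = m.individual_id
            if m.is_founder:
                k = self.founder_no[iid]
                slotP[iid] = np.full(self.n_states, 2 * k, dtype=np.int16)
                slotM[iid] = np.full(self.n_states, 2 * k + 1, dtype=np.int16)
            else:
                bp = bit_values(bit_of[(iid, 0)])
                bm = bit_values(bit_of[(iid, 1)])
                slotP[iid] = np.where(
                    bp == 0, slotP[m.father_id], slotM[m.father_id]
                ).astype(np.int16)
                slotM[iid] = np.where(
                    bm == 0, slotP[m.mother_id], slotM[m.mother_id]
                ).astype(np.int16)
        self.slotP, self.slotM = slotP, slotM

        # axes for transition butterflies: free bit b lives on axis
        # n_free - 1 - free_pos[b] of the reshaped (2,)*n_free array
        self._axis = {
            b: self.n_free - 1 - p for b, p in self.free_pos.items()
        }
        self._single_bits = [
            b
            for b, (_, _, parent) in enumerate(self.meioses)
            if not pedigree[parent].is_founder
        ]

    # -- emissions ----------------------------------------------------------

    def _founder_assignments(self, genotypes: dict[str, tuple[int, int]], freq: float):
        """Allele value per founder slot for every consistent phase ordering.

        Returns (slot_alleles (n_assign, n_slots) uint8, weights (n_assign,)).
        """
        p = {1: freq, 2: 1.0 - freq}
        options: list[list[tuple[int, int, float]]] = []
        for iid in self.founder_ids:
            g = genotypes.get(iid, (MISSING, MISSING))
            a, b = g
            if a == MISSING:
                options.append(
                    [
                        (x, y, p[x] * p[y])
                        for x in (1, 2)
                        for y in (1, 2)
                    ]
                )
            elif a == b:
                options.append([(a, a, p[a] * p[a])])
            else:
                lo, hi = min(a, b), max(a, b)
                w = p[lo] * p[hi]
                options.append([(lo, hi, w), (hi, lo, w)])
        combos = list(itertools.product(*options))
        slot_alleles = np.empty((len(combos), self.n_slots), dtype=np.uint8)
        weights = np.empty(len(combos))
        for i, combo in enumerate(combos):
            w = 1.0
            for k, (x, y, wk) in enumerate(combo):
                slot_alleles[i, 2 * k] = x
                slot_alleles[i, 2 * k + 1] = y
                w *= wk
            weights[i] = w
        return slot_alleles, weights

    def marker_emission(
        self, genotypes: dict[str, tuple[int, int]], freq: float, marker_name: str = "?"
    ) -> np.ndarray:
        """P(observed genotypes at one marker | v), for every state v."""
        slot_alleles, weights = self._founder_assignments(genotypes, freq)
        out = np.zeros(self.n_states)
        typed_nonfounders = [
            m
            for m in self.members
            if not m.is_founder
            and genotypes.get(m.individual_id, (MISSING, MISSING))[0] != MISSING
        ]
        for lo in range(0, len(weights), _ASSIGN_CHUNK):
            hi = min(lo + _ASSIGN_CHUNK, len(weights))
            sa = slot_alleles[lo:hi]
            mask = np.ones((hi - lo, self.n_states), dtype=bool)
            for m in typed_nonfounders:
                iid = m.individual_id
                g1, g2 = sorted(genotypes[iid])
                aP = sa[:, self.slotP[iid]]
                aM = sa[:, self.slotM[iid]]
                mask &= ((aP == g1) & (aM == g2)) | ((aP == g2) & (aM == g1))
            out += weights[lo:hi] @ mask
        if not out.any():
            raise InconsistentGenotypesError(
                f"family {self.pedigree.family_id}, marker {marker_name}: "
                "genotypes are inconsistent with Mendelian transmission; run "
                "mendelian_check first"
            )
        return out

    def emissions_from_matrix(self, genotypes: GenotypeMatrix) -> list[np.ndarray]:
        fid = self.pedigree.family_id
        rows = genotypes.family_rows(fid)
        out = []
        for j, marker in enumerate(genotypes.markers):
            gmap = {
                iid: (int(genotypes.calls[r, j, 0]), int(genotypes.calls[r, j, 1]))
                for iid, r in rows.items()
            }
            out.append(self.marker_emission(gmap, marker.freq, marker.name))
        return out

    # -- phenotype likelihood ----------------------------------------------

    def phenotype_likelihood(self, model: DiseaseModel) -> np.ndarray:
        """R(v) = P(phenotypes | v), summing founder disease-allele
        assignments under Hardy-Weinberg and applying the penetrances."""
        phenotyped = [
            m for m in self.members if m.phenotype is not Phenotype.UNKNOWN
        ]
        if not phenotyped:
            return np.ones(self.n_states)
        q = model.q
        pen_aff = np.asarray(model.penetrances)
        pen_un = 1.0 - pen_aff
        n_assign = 1 << self.n_slots
        patterns = np.arange(n_assign, dtype=np.int64)
        R = np.zeros(self.n_states)
        for lo in range(0, n_assign, _ASSIGN_CHUNK):
            chunk = patterns[lo : lo + _ASSIGN_CHUNK]
            d = ((chunk[:, None] >> np.arange(self.n_slots)) & 1).astype(np.uint8)
            n_dis = d.sum(axis=1)
            w = (q ** n_dis) * ((1.0 - q) ** (self.n_slots - n_dis))
            acc = np.repeat(w[:, None], self.n_states, axis=1)
            for m in phenotyped:
                iid = m.individual_id
                copies = d[:, self.slotP[iid]] + d[:, self.slotM[iid]]
                tbl = pen_aff if m.phenotype is Phenotype.AFFECTED else pen_un
                acc *= tbl[copies]
            R += acc.sum(axis=0)
        return R

    # -- transitions --------------------------------------------------------

    def transition(self, x: np.ndarray, theta: float) -> np.ndarray:
        """Propagate a state distribution across a gap with recombination
        fraction ``theta`` per meiosis."""
        if theta == 0.0 or self.n_free == 0:
            return x.copy()
        X = x.reshape((2,) * self.n_free)

        def butterfly(arr, axis):
            return (1.0 - theta) * arr + theta * np.flip(arr, axis=axis)

        for bit in self._single_bits:
            X = butterfly(X, self._axis[bit])
        for founder, bits in self.founder_groups.items():
            if self.founder_reduction:
                free = [b for b in bits if not self.fixed[b]]
                if free:
                    axes = tuple(self._axis[b] for b in free)
                    X = (1.0 - theta) * X + theta * np.flip(X, axis=axes)
                    for b in free:
                        X = butterfly(X, self._axis[b])
                # single-meiosis founder: kernel is the identity
            else:
                for b in bits:
                    X = butterfly(X, self._axis[b])
        return X.reshape(-1)
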