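"""Pedigree haplotype phasing and IBD segregating-interval detection.

Phasing is deterministic and rule-based, in three passes per chromosome:

1. homozygotes self-phase, and a child's (paternal, maternal) allele order
   is forced wherever only one assignment is Mendelian-consistent with the
   parents' genotypes;
2. grandparental-origin bits are forced where a heterozygous parent is
   phased; founder phase itself is fixed greedily along the chromosome by
   minimum recombination over the founder's transmissions, and remaining
   child ambiguities are broken by preferring no bit flip since the last
   informative marker;
3. uninformative stretches inherit the previous informative bit and are
   flagged ``INFERRED``; anything genuinely undecidable stays ``UNRESOLVED``
   rather than being guessed silently.

The segregating interval is the maximal marker run over which every
affected, genotyped member carries a haplotype traceable to one founder
chromosome.  Unaffected carriers are permitted (incomplete penetrance).
Where an origin chain is broken the sharing test falls back to identity by
state against the founder haplotype's allele and the marker is flagged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .pedio import (
    MISSING,
    GenotypeMatrix,
    Pedigree,
    Phenotype,
)

__all__ = [
    "Resolution",
    "HaplotypeAssignment",
    "SegregatingInterval",
    "phase_pedigree",
    "segregating_interval",
    "per_family_penetrance",
    "InsufficientDataError",
    "PhasingError",
]


class InsufficientDataError(ValueError):
    """Fewer than two affected members with genotype data."""


class PhasingError(ValueError):
    """Mendelian inconsistency hit during phasing."""


class Resolution(enum.IntEnum):
    UNRESOLVED = 0
    FORCED = 1
    INFERRED = 2


@dataclass
class HaplotypeAssignment:
    """Phased view of one family's genotypes on one chromosome.

    ``ordered[i, j]`` is the (paternal, maternal) allele pair of member i at
    marker j (0 = unresolved); ``origin[i, j, s]`` is the grandparental
    origin bit of side s (0 = transmitting parent's paternal chromosome,
    -1 = unresolved) with its ``quality``.  Founder rows carry their own
    arbitrary-but-fixed phase convention in ``ordered``.
    """

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    marker_order: list[int]  # columns of `genotypes`, sorted by cM
    ordered: np.ndarray  # (n_members, n_markers, 2) uint8
    origin: np.ndarray  # (n_members, n_markers, 2) int8
    quality: np.ndarray  # (n_members, n_markers, 2) uint8 (Resolution)

    def member_index(self, iid: str) -> int:
        return self._midx[iid]

    def __post_init__(self):
        self._midx = {
            m.individual_id: i for i, m in enumerate(self.pedigree.members)
        }

    @property
    def markers(self):
        return [self.genotypes.markers[c] for c in self.marker_order]

    def collapse(self) -> np.ndarray:
        """Unordered genotypes implied by the assignment; where a position
        is unresolved the input call is passed through unchanged."""
        fid = self.pedigree.family_id
        out = np.zeros_like(self.ordered)
        for i, m in enumerate(self.pedigree.members):
            row = self.genotypes.row(fid, m.individual_id)
            for jj, col in enumerate(self.marker_order):
                o = self.ordered[i, jj]
                if o[0] != 0:
                    out[i, jj] = sorted(o)
                else:
                    out[i, jj] = sorted(self.genotypes.calls[row, col])
        return out


def _single_chromosome(genotypes: GenotypeMatrix) -> list[int]:
    chroms = {m.chromosome for m in genotypes.markers}
    if len(chroms) != 1:
        raise ValueError(
            "phasing operates on one chromosome at a time; subset the "
            f"matrix first (got {sorted(chroms)})"
        )
    order = sorted(
        range(len(genotypes.markers)),
        key=lambda j: (genotypes.markers[j].cm, genotypes.markers[j].bp),
    )
    return order


def phase_pedigree(
    pedigree: Pedigree, genotypes: GenotypeMatrix
) -> HaplotypeAssignment:
    fid = pedigree.family_id
    order = _single_chromosome(genotypes)
    members = pedigree.members
    n, m = len(members), len(order)
    midx = {ind.individual_id: i for i, ind in enumerate(members)}

    geno = np.zeros((n, m, 2), dtype=np.uint8)
    for i, ind in enumerate(members):
        if genotypes.has_sample(fid, ind.individual_id):
            row = genotypes.row(fid, ind.individual_id)
            geno[i] = genotypes.calls[row][order]

    ordered = np.zeros((n, m, 2), dtype=np.uint8)
    origin = np.full((n, m, 2), -1, dtype=np.int8)
    quality = np.zeros((n, m, 2), dtype=np.uint8)

    topo = [midx[ind.individual_id] for ind in pedigree.topological_order()]
    nonfounders = [i for i in topo if not members[i].is_founder]
    founders = [i for i in topo if members[i].is_founder]
    father_of = {
        i: midx[members[i].father_id] for i in nonfounders
    }
    mother_of = {
        i: midx[members[i].mother_id] for i in nonfounders
    }
    children_of: dict[int, list[tuple[int, int]]] = {}
    for c in nonfounders:
        children_of.setdefault(father_of[c], []).append((c, 0))
        children_of.setdefault(mother_of[c], []).append((c, 1))

    prev_bit = np.full((n, 2), -1, dtype=np.int8)  # last assigned origin bit
    founder_phase: dict[int, tuple[int, int]] = {}

    def candidates(c: int, j: int) -> list[tuple[int, int]]:
        a, b = int(geno[c, j, 0]), int(geno[c, j, 1])
        fa = set(int(x) for x in geno[father_of[c], j] if x != MISSING) or {1, 2}
        mo = set(int(x) for x in geno[mother_of[c], j] if x != MISSING) or {1, 2}
        cands = []
        for x, y in {(a, b), (b, a)}:
            if x in fa and y in mo:
                cands.append((x, y))
        return sorted(cands)

    def set_bit(c: int, side: int, j: int, bit: int, qual: Resolution):
        origin[c, j, side] = bit
        quality[c, j, side] = qual
        prev_bit[c, side] = bit

    def bit_from_parent(c: int, side: int, j: int, transmitted: int):
        """Assign the origin bit when the phased parent is heterozygous.

        A nonfounder parent's (paternal, maternal) order is anchored by its
        own parents, so the bit is FORCED; a founder's phase is itself a
        greedy minimum-recombinant choice, so bits through it are INFERRED.
        """
        p = father_of[c] if side == 0 else mother_of[c]
        po = ordered[p, j]
        if po[0] == 0 or po[0] == po[1]:
            return
        qual = Resolution.INFERRED if members[p].is_founder else Resolution.FORCED
        if transmitted == po[0]:
            set_bit(c, side, j, 0, qual)
        elif transmitted == po[1]:
            set_bit(c, side, j, 1, qual)

    for j in range(m):
        transmitted = np.zeros((n, 2), dtype=np.uint8)  # per child, per side

        # pass 1: self-phasing and forced child orderings
        for i in range(n):
            a, b = int(geno[i, j, 0]), int(geno[i, j, 1])
            if a != MISSING and a == b:
                ordered[i, j] = (a, a)
        for c in nonfounders:
            if geno[c, j, 0] == MISSING:
                continue
            cands = candidates(c, j)
            if not cands:
                iid = members[c].individual_id
                raise PhasingError(
                    f"family {fid}: Mendelian violation at marker "
                    f"{genotypes.markers[order[j]].name} for {iid}; run "
                    "mendelian_check / set_violations_missing first"
                )
            if len(cands) == 1:
                ordered[c, j] = cands[0]
                transmitted[c] = cands[0]

        # pass 2a: founder phase by minimum recombination over transmissions;
        # cost ties keep the ordering used at the previous heterozygous
        # marker (chromosome-level continuity of the phase convention)
        for f in founders:
            a, b = int(geno[f, j, 0]), int(geno[f, j, 1])
            if a == MISSING or a == b:
                continue
            kids = [
                (c, side)
                for c, side in children_of.get(f, [])
                if transmitted[c, side] != 0
            ]
            lo, hi = min(a, b), max(a, b)
            prev = founder_phase.get(f, (lo, hi))
            choices = [prev, (prev[1], prev[0])]
            best = None
            for choice in choices:
                cost = 0
                for c, side in kids:
                    bit = 0 if transmitted[c, side] == choice[0] else 1
                    if prev_bit[c, side] != -1 and bit != prev_bit[c, side]:
                        cost += 1
                if best is None or cost < best[0]:
                    best = (cost, choice)
            ordered[f, j] = best[1]
            founder_phase[f] = best[1]

        # pass 2b: forced bits from phased heterozygous parents
        for c in nonfounders:
            if transmitted[c, 0] == 0:
                continue
            bit_from_parent(c, 0, j, int(transmitted[c, 0]))
            bit_from_parent(c, 1, j, int(transmitted[c, 1]))

        # pass 2c: break remaining child ambiguity by minimum recombination
        for c in nonfounders:
            if geno[c, j, 0] == MISSING or ordered[c, j, 0] != 0:
                continue
            cands = candidates(c, j)
            if len(cands) != 2:
                continue
            scored = []
            for cand in cands:
                cost = bits = 0
                implied = []
                for side, t in enumerate(cand):
                    p = father_of[c] if side == 0 else mother_of[c]
                    po = ordered[p, j]
                    if po[0] != 0 and po[0] != po[1]:
                        bit = 0 if t == po[0] else 1
                        implied.append((side, bit))
                        if prev_bit[c, side] != -1:
                            bits += 1
                            if bit != prev_bit[c, side]:
                                cost += 1
                scored.append((cost, bits, cand, implied))
            scored.sort(key=lambda s: s[0])
            if len(scored) == 2 and scored[0][0] < scored[1][0] and scored[0][1]:
                _, _, cand, implied = scored[0]
                ordered[c, j] = cand
                for side, bit in implied:
                    set_bit(c, side, j, bit, Resolution.INFERRED)

    # pass 3: greedy fill of uninformative stretches
    last = np.full((n, 2), -1, dtype=np.int8)
    for j in range(m):
        for c in nonfounders:
            for side in (0, 1):
                if origin[c, j, side] != -1:
                    last[c, side] = origin[c, j, side]
                elif last[c, side] != -1:
                    origin[c, j, side] = last[c, side]
                    quality[c, j, side] = Resolution.INFERRED

    return HaplotypeAssignment(
        pedigree=pedigree,
        genotypes=genotypes,
        marker_order=order,
        ordered=ordered,
        origin=origin,
        quality=quality,
    )


@dataclass
class SegregatingInterval:
    """A haplotype block shared by all affected, genotyped members."""

    chromosome: str
    start_bp: int
    end_bp: int
    start_marker: str
    end_marker: str
    carriers: list[str]
    founder_slot: tuple[str, int]  # (founder id, phase) the block traces to
    marker_indices: tuple[int, int]  # run bounds in the sorted marker order
    ibs_only_markers: list[str]  # markers where sharing rests on IBS fallback

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("interval start must not exceed end")


def _founder_labels(hap: HaplotypeAssignment) -> tuple[np.ndarray, np.ndarray]:
    """Founder-slot label per (member, marker, chromosome copy) and whether
    the full descent chain is FORCED (Mendelian-anchored at every step).

    slot = 2 * founder_index + phase; -1 where the chain is broken.
    """
    ped = hap.pedigree
    members = ped.members
    midx = {m.individual_id: i for i, m in enumerate(members)}
    founders = [m.individual_id for m in ped.topological_order() if m.is_founder]
    fno = {iid: k for k, iid in enumerate(founders)}
    n, mm = hap.origin.shape[:2]
    labels = np.full((n, mm, 2), -1, dtype=np.int16)
    forced = np.zeros((n, mm, 2), dtype=bool)
    for ind in ped.topological_order():
        i = midx[ind.individual_id]
        if ind.is_founder:
            k = fno[ind.individual_id]
            labels[i, :, 0] = 2 * k
            labels[i, :, 1] = 2 * k + 1
            forced[i] = True
        else:
            fa, mo = midx[ind.father_id], midx[ind.mother_id]
            for side, p in ((0, fa), (1, mo)):
                bits = hap.origin[i, :, side]
                ok = bits != -1
                sel = np.clip(bits, 0, 1)
                rows = labels[p, np.arange(mm), sel]
                labels[i, :, side] = np.where(ok, rows, -1)
                forced[i, :, side] = (
                    ok
                    & (hap.quality[i, :, side] == Resolution.FORCED)
                    & forced[p, np.arange(mm), sel]
                )
    return labels, forced


def _slot_allele(hap: HaplotypeAssignment, founders: list[str], slot: int) -> np.ndarray:
    """Allele carried by a founder chromosome per marker (0 = unknown)."""
    fid_name = founders[slot // 2]
    i = hap.member_index(fid_name)
    return hap.ordered[i, :, slot % 2]


def segregating_interval(
    pedigree: Pedigree,
    haplotypes: HaplotypeAssignment,
    region_hint: tuple[int, int] | None = None,
) -> SegregatingInterval | None:
    """Maximal run of markers at which every affected, genotyped member
    carries one founder chromosome; ``None`` if no run of >= 2 markers.

    ``region_hint`` is a closed bp interval used to pick among candidate
    runs; without it the longest run wins.
    """
    ped = pedigree
    hap = haplotypes
    fid = ped.family_id
    members = ped.members
    markers = hap.markers
    founders = [m.individual_id for m in ped.topological_order() if m.is_founder]
    geno_ok = {
        m.individual_id
        for m in members
        if hap.genotypes.has_sample(fid, m.individual_id)
        and (hap.genotypes.calls[hap.genotypes.row(fid, m.individual_id)] != MISSING).any()
    }
    affected = [
        m.individual_id
        for m in members
        if m.phenotype is Phenotype.AFFECTED and m.individual_id in geno_ok
    ]
    if len(affected) < 2:
        raise InsufficientDataError(
            f"family {fid}: need >= 2 affected members with genotype data"
        )

    labels, chain_forced = _founder_labels(hap)
    mm = labels.shape[1]
    aff_idx = [hap.member_index(a) for a in affected]

    # genotype matrix aligned to the sorted marker order
    geno = np.zeros((len(members), mm, 2), dtype=np.uint8)
    for i, ind in enumerate(members):
        if ind.individual_id in geno_ok:
            row = hap.genotypes.row(fid, ind.individual_id)
            geno[i] = hap.genotypes.calls[row][hap.marker_order]

    candidate_slots = sorted(
        {int(s) for i in aff_idx for s in labels[i].ravel() if s >= 0}
    )

    def compat(i: int, j: int, slot: int, slot_all: np.ndarray):
        """(compatible, via_ibs) for member i at marker j.

        Strict refutation requires both descent chains to be Mendelian-
        anchored; where a chain rests on a greedy phase choice or is broken
        the test falls back to identity by state against the founder
        haplotype's allele.
        """
        lab = labels[i, j]
        if slot in lab:
            return True, False
        if chain_forced[i, j, 0] and chain_forced[i, j, 1]:
            return False, False
        a = int(slot_all[j])
        g = geno[i, j]
        if g[0] == MISSING or a == 0 or a in g:
            return True, True
        return False, False

    best = None  # (run length, -start, slot, start, end, ibs markers)
    for slot in candidate_slots:
        slot_all = _slot_allele(hap, founders, slot)
        ok = np.zeros(mm, dtype=bool)
        via_ibs = np.zeros(mm, dtype=bool)
        for j in range(mm):
            good = True
            ibs = False
            for i in aff_idx:
                c, v = compat(i, j, slot, slot_all)
                if not c:
                    good = False
                    break
                ibs = ibs or v
            ok[j] = good
            via_ibs[j] = good and ibs
        # maximal runs of >= 2 markers
        j = 0
        while j < mm:
            if not ok[j]:
                j += 1
                continue
            k = j
            while k + 1 < mm and ok[k + 1]:
                k += 1
            if k - j + 1 >= 2:
                run_bp = (markers[j].bp, markers[k].bp)
                in_hint = (
                    region_hint is None
                    or (run_bp[0] <= region_hint[1] and run_bp[1] >= region_hint[0])
                )
                if in_hint:
                    cand = (k - j + 1, -j, slot, j, k, via_ibs[j : k + 1].copy())
                    if best is None or cand[:2] > best[:2]:
                        best = cand
            j = k + 1
    if best is None:
        return None
    _, _, slot, j, k, ibs_run = best
    slot_all = _slot_allele(hap, founders, slot)
    carriers = []
    for i, ind in enumerate(members):
        if ind.individual_id not in geno_ok:
            continue
        if all(compat(i, jj, slot, slot_all)[0] for jj in range(j, k + 1)):
            carriers.append(ind.individual_id)
    return SegregatingInterval(
        chromosome=markers[0].chromosome,
        start_bp=markers[j].bp,
        end_bp=markers[k].bp,
        start_marker=markers[j].name,
        end_marker=markers[k].name,
        carriers=carriers,
        founder_slot=(founders[slot // 2], slot % 2),
        marker_indices=(j, k),
        ibs_only_markers=[
            markers[jj].name for jj in range(j, k + 1) if ibs_run[jj - j]
        ],
    )


def per_family_penetrance(pedigree: Pedigree, interval: SegregatingInterval) -> float:
    """Affected carriers / phenotype-known carriers of the shared block."""
    known = [
        iid
        for iid in interval.carriers
        if pedigree[iid].phenotype is not Phenotype.UNKNOWN
    ]
    if not known:
        raise ValueError("interval has no carriers with known phenotype")
    affected = sum(
        1 for iid in known if pedigree[iid].phenotype is Phenotype.AFFECTED
    )
    return affected / len(known)
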