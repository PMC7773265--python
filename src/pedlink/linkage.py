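"""Parametric LOD computation.

Two-point LOD scores by Elston-Stewart peeling, multipoint LOD curves by a
Lander-Green inheritance-vector HMM, marker thinning into bounded analysis
sets, and additive combination of per-family curves.

The map function is Haldane's: theta = (1 - exp(-2 d / 100)) / 2 for a gap
of d centimorgan, consistent with the HMM's independent-bit transitions (no
crossover interference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._lander_green import InheritanceEngine
from ._peeling import pedigree_log10_likelihood
from .disease_model import DiseaseModel
from .pedio import GenotypeMatrix, Marker, Pedigree, sort_markers

__all__ = [
    "LodCurve",
    "haldane_theta",
    "haldane_cm",
    "twopoint_lod",
    "multipoint_lod",
    "additive_lod",
    "thin_markers",
    "AlignmentError",
]

_POS_DECIMALS = 6  # grid positions are compared after rounding to 1e-6 cM


class AlignmentError(ValueError):
    """Curves to be combined do not share an identical grid."""


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction for a map distance in centimorgan."""
    return 0.5 * (1.0 - math.exp(-2.0 * abs(d_cm) / 100.0))


def haldane_cm(theta: float) -> float:
    """Inverse Haldane map function."""
    if not 0.0 <= theta < 0.5:
        raise ValueError("theta must lie in [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * theta)


@dataclass
class LodCurve:
    chromosome: str
    positions: np.ndarray  # cM, strictly increasing
    lod: np.ndarray
    family_id: str = "combined"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.lod = np.asarray(self.lod, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.lod.shape:
            raise ValueError("positions and lod must be matching 1-d arrays")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.lod)):
            raise ValueError("LOD values must be finite")

    @property
    def peak(self) -> float:
        return float(self.lod.max())

    @property
    def peak_position(self) -> float:
        return float(self.positions[int(np.argmax(self.lod))])


def twopoint_lod(
    pedigree: Pedigree,
    genotypes: dict[str, tuple[int, int]],
    model: DiseaseModel,
    theta: float,
    marker_freq: float = 0.5,
) -> float:
    """log10 L(theta) / L(1/2) for one marker jointly with the phenotypes.

    ``genotypes`` maps individual id to an unordered allele pair in codes
    {1, 2} (0 = missing); untyped members may be omitted.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    l_theta = pedigree_log10_likelihood(pedigree, genotypes, model, theta, marker_freq)
    l_half = pedigree_log10_likelihood(pedigree, genotypes, model, 0.5, marker_freq)
    return l_theta - l_half


def _posterior_curve(
    engine: InheritanceEngine,
    positions_cm: np.ndarray,
    emissions: list[np.ndarray],
    grid: np.ndarray,
) -> list[np.ndarray]:
    """Normalised P(v at x | all marker data) for every grid position."""
    n = len(positions_cm)
    uniform = np.full(engine.n_states, 1.0 / engine.n_states)

    fwd: list[np.ndarray] = []
    cur = uniform * emissions[0]
    fwd.append(cur / cur.sum())
    for i in range(1, n):
        theta = haldane_theta(positions_cm[i] - positions_cm[i - 1])
        cur = engine.transition(fwd[-1], theta) * emissions[i]
        fwd.append(cur / cur.sum())

    bwd: list[np.ndarray] = [None] * n
    cur = np.ones(engine.n_states)
    bwd[n - 1] = cur
    for i in range(n - 2, -1, -1):
        theta = haldane_theta(positions_cm[i + 1] - positions_cm[i])
        cur = engine.transition(emissions[i + 1] * bwd[i + 1], theta)
        cur = cur / cur.max()
        bwd[i] = cur

    out = []
    for x in grid:
        j = int(np.searchsorted(positions_cm, x))
        exact = None
        for cand in (j - 1, j):
            if 0 <= cand < n and abs(positions_cm[cand] - x) < 10 ** (-_POS_DECIMALS):
                exact = cand
        if exact is not None:
            post = fwd[exact] * bwd[exact]
        elif j == 0:
            theta = haldane_theta(positions_cm[0] - x)
            post = engine.transition(emissions[0] * bwd[0], theta)
        elif j == n:
            theta = haldane_theta(x - positions_cm[n - 1])
            post = engine.transition(fwd[n - 1], theta)
        else:
            tl = haldane_theta(x - positions_cm[j - 1])
            tr = haldane_theta(positions_cm[j] - x)
            post = engine.transition(fwd[j - 1], tl) * engine.transition(
                emissions[j] * bwd[j], tr
            )
        out.append(post / post.sum())
    return out


def multipoint_lod(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    model: DiseaseModel,
    grid: np.ndarray,
    bit_cap: int = 20,
    founder_reduction: bool = True,
) -> LodCurve:
    """Multipoint parametric LOD curve for one family on one chromosome.

    At each grid position x the inheritance-vector posterior given all
    markers is combined with the phenotype likelihood R(v):

        LOD(x) = log10 [ sum_v P(v | markers) R(v) / mean_v R(v) ]

    where the denominator is the prior (linkage-free) expectation of R.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty position grid")
    chroms = {m.chromosome for m in genotypes.markers}
    if len(chroms) != 1:
        raise ValueError(f"markers span several chromosomes: {sorted(chroms)}")
    markers = sort_markers(genotypes.markers)
    genotypes = genotypes.subset_markers([m.name for m in markers])

    engine = InheritanceEngine(pedigree, bit_cap=bit_cap, founder_reduction=founder_reduction)
    R = engine.phenotype_likelihood(model)
    mean_R = float(R.mean())
    if mean_R <= 0.0:
        raise ValueError(
            f"family {pedigree.family_id}: phenotypes impossible under the model"
        )
    emissions = engine.emissions_from_matrix(genotypes)
    positions = np.array([m.cm for m in markers])
    posts = _posterior_curve(engine, positions, emissions, grid)
    lod = np.array([math.log10(float(p @ R) / mean_R) for p in posts])
    return LodCurve(
        chromosome=markers[0].chromosome,
        positions=grid,
        lod=lod,
        family_id=pedigree.family_id,
    )


def additive_lod(curves: list[LodCurve]) -> LodCurve:
    """Pointwise sum of per-family curves sharing one grid exactly."""
    if not curves:
        raise ValueError("no curves to combine")
    first = curves[0]
    for c in curves[1:]:
        if c.chromosome != first.chromosome or not np.array_equal(
            np.round(c.positions, _POS_DECIMALS),
            np.round(first.positions, _POS_DECIMALS),
        ):
            raise AlignmentError(
                "curves must share chromosome and positions exactly; "
                "no silent interpolation is performed"
            )
    total = np.sum([c.lod for c in curves], axis=0)
    return LodCurve(first.chromosome, first.positions.copy(), total, "combined")


def thin_markers(
    markers: list[Marker], spacing_cm: float, set_size: int
) -> tuple[list[Marker], list[list[Marker]]]:
    """One marker per spacing bin, chunked into overlapping analysis sets.

    Greedy left-to-right: bins of width ``spacing_cm`` anchored at the first
    marker; within a bin the marker with the largest minor-allele frequency
    wins (most informative), ties broken by lowest bp.  Selected markers are
    chunked into consecutive sets of ``set_size``, adjacent sets sharing one
    marker so the per-set HMM runs can be stitched.
    """
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    if set_size < 2:
        raise ValueError("set_size must be at least 2")
    if not markers:
        raise ValueError("empty marker map")
    chroms = {m.chromosome for m in markers}
    if len(chroms) != 1:
        raise ValueError("thin_markers operates on a single chromosome")
    markers = sort_markers(markers)
    origin = markers[0].cm
    selected: list[Marker] = []
    by_bin: dict[int, Marker] = {}
    for m in markers:
        b = int((m.cm - origin) / spacing_cm + 1e-9)
        cur = by_bin.get(b)
        if cur is None or (m.maf, -m.bp) > (cur.maf, -cur.bp):
            by_bin[b] = m
    selected = [by_bin[b] for b in sorted(by_bin)]

    sets: list[list[Marker]] = []
    if len(selected) <= set_size:
        sets.append(list(selected))
    else:
        start = 0
        while True:
            chunk = selected[start : start + set_size]
            sets.append(chunk)
            if start + set_size >= len(selected):
                break
            start += set_size - 1  # overlap of one marker
    return selected, sets
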