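"""Locus discovery under heterogeneity.

The workflow mirrors a family-clustered scan: an all-family genome scan
(additive LOD over families), per-family extraction of every positive-LOD
run as a candidate locus, cross-family interval intersection, a combined
additive LOD on the identical thinned marker set inside the overlap, and a
tabular report.

Interval conventions: physical coordinates are 1-based closed bp; genetic
coordinates are centimorgan reals.  Overlaps are computed independently on
the two scales as (max of starts, min of ends); no interpolation between
scales is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .disease_model import DiseaseModel
from .linkage import LodCurve, additive_lod, multipoint_lod, thin_markers
from .pedio import GenotypeMatrix, Marker, Pedigree, sort_markers

__all__ = [
    "ScanConfig",
    "CandidateLocus",
    "OverlapResult",
    "ScanResult",
    "genome_scan",
    "extract_family_loci",
    "intersect_loci",
    "combined_lod_at_overlap",
    "locus_report",
    "CoverageError",
]

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NONE = "none"


class CoverageError(ValueError):
    """No shared typed markers inside the requested overlap."""


@dataclass
class ScanConfig:
    """Analysis-stage parameters.

    ``spacing_cm`` thins the map for the genome scan (default one marker
    every 0.2 cM); ``rerun_spacing_cm`` is used for the combined rerun at a
    candidate overlap; ``set_size`` bounds each HMM run; the grid adds
    equally spaced evaluation points between the selected markers.
    """

    spacing_cm: float = 0.2
    rerun_spacing_cm: float = 0.3
    set_size: int = 50
    grid_spacing_cm: float | None = None
    bit_cap: int = 20
    significant_lod: float = 3.0
    suggestive_lod: float = 2.0

    @property
    def grid_step(self) -> float:
        return self.grid_spacing_cm if self.grid_spacing_cm is not None else self.spacing_cm


@dataclass
class CandidateLocus:
    chromosome: str
    family_id: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    boundary_snps: tuple[str, str] = ("", "")
    peak_lod: float = float("nan")

    def __post_init__(self):
        if self.start_bp > self.end_bp or self.start_cm > self.end_cm:
            raise ValueError("locus start must not exceed end")


@dataclass
class OverlapResult:
    loci: list[CandidateLocus]
    overlap_bp: tuple[int, int] | None
    overlap_cm: tuple[float, float] | None
    combined_lod: float | None = None
    classification: str = NONE

    @property
    def chromosome(self) -> str:
        return self.loci[0].chromosome

    @property
    def families(self) -> list[str]:
        return [l.family_id for l in self.loci]

    @property
    def span_cm(self) -> float | None:
        if self.overlap_cm is None:
            return None
        return round(self.overlap_cm[1] - self.overlap_cm[0], 2)

    def classify(self, significant: float = 3.0, suggestive: float = 2.0) -> str:
        if self.overlap_bp is None or self.combined_lod is None:
            self.classification = NONE
        elif self.combined_lod >= significant:
            self.classification = SIGNIFICANT
        elif self.combined_lod >= suggestive:
            self.classification = SUGGESTIVE
        else:
            self.classification = NONE
        return self.classification


@dataclass
class ScanResult:
    per_family: dict[str, dict[str, LodCurve]]  # family -> chromosome -> curve
    combined: dict[str, LodCurve]  # chromosome -> curve
    any_significant: bool


def _scan_grid(selected: list[Marker], step: float) -> np.ndarray:
    lo, hi = selected[0].cm, selected[-1].cm
    pts = np.arange(lo, hi + 1e-12, step)
    grid = np.union1d(np.round(pts, 6), np.round([m.cm for m in selected], 6))
    return grid


def _scan_chromosome(
    family: Pedigree,
    genotypes: GenotypeMatrix,
    sets: list[list[Marker]],
    grid: np.ndarray,
    model: DiseaseModel,
    config: ScanConfig,
) -> LodCurve:
    """Run the multipoint HMM per bounded marker set and stitch the curve."""
    boundaries = np.array([s[-1].cm for s in sets])
    which = np.searchsorted(boundaries, grid, side="left")
    which = np.clip(which, 0, len(sets) - 1)
    pieces = []
    for i, marker_set in enumerate(sets):
        chunk = grid[which == i]
        if chunk.size == 0:
            continue
        sub = genotypes.subset_markers([m.name for m in marker_set])
        pieces.append(
            multipoint_lod(family, sub, model, chunk, bit_cap=config.bit_cap)
        )
    return LodCurve(
        chromosome=pieces[0].chromosome,
        positions=np.concatenate([p.positions for p in pieces]),
        lod=np.concatenate([p.lod for p in pieces]),
        family_id=family.family_id,
    )


def genome_scan(
    families: list[Pedigree],
    genotypes: GenotypeMatrix,
    model: DiseaseModel,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Per-family and combined multipoint curves over every chromosome with
    markers; flags whether the combined curve reaches the significance
    threshold anywhere."""
    if not families:
        raise ValueError("at least one family is required")
    config = config or ScanConfig()
    by_chrom: dict[str, list[Marker]] = {}
    for mk in sort_markers(genotypes.markers):
        by_chrom.setdefault(mk.chromosome, []).append(mk)

    per_family: dict[str, dict[str, LodCurve]] = {f.family_id: {} for f in families}
    combined: dict[str, LodCurve] = {}
    for chrom, markers in by_chrom.items():
        selected, sets = thin_markers(markers, config.spacing_cm, config.set_size)
        grid = _scan_grid(selected, config.grid_step)
        curves = []
        for fam in families:
            curve = _scan_chromosome(fam, genotypes, sets, grid, model, config)
            per_family[fam.family_id][chrom] = curve
            curves.append(curve)
        combined[chrom] = additive_lod(curves)
    any_sig = any(
        c.peak >= config.significant_lod for c in combined.values()
    )
    return ScanResult(per_family=per_family, combined=combined, any_significant=any_sig)


def extract_family_loci(curve: LodCurve, markers: list[Marker]) -> list[CandidateLocus]:
    """Maximal runs of consecutive grid positions with LOD > 0.

    Physical bounds are the outermost markers inside the run; a run
    containing no marker cannot be demarcated and is dropped.
    """
    if curve.positions.size == 0:
        raise ValueError("empty curve")
    markers = [m for m in sort_markers(markers) if m.chromosome == curve.chromosome]
    mpos = np.array([m.cm for m in markers])
    pos, lod = curve.positions, curve.lod
    loci: list[CandidateLocus] = []
    j = 0
    n = len(pos)
    while j < n:
        if lod[j] <= 0:
            j += 1
            continue
        k = j
        while k + 1 < n and lod[k + 1] > 0:
            k += 1
        lo_cm, hi_cm = pos[j], pos[k]
        inside = np.nonzero((mpos >= lo_cm - 1e-9) & (mpos <= hi_cm + 1e-9))[0]
        if inside.size:
            first, last = markers[inside[0]], markers[inside[-1]]
            loci.append(
                CandidateLocus(
                    chromosome=curve.chromosome,
                    family_id=curve.family_id,
                    start_bp=first.bp,
                    end_bp=last.bp,
                    start_cm=float(lo_cm),
                    end_cm=float(hi_cm),
                    boundary_snps=(first.name, last.name),
                    peak_lod=float(lod[j : k + 1].max()),
                )
            )
        j = k + 1
    return loci


def intersect_loci(loci: list[CandidateLocus]) -> OverlapResult:
    """Overlap of per-family loci: (max of starts, min of ends), computed
    independently in bp and in cM."""
    if len(loci) < 2:
        raise ValueError("need at least two loci to intersect")
    chroms = {l.chromosome for l in loci}
    if len(chroms) != 1:
        raise ValueError(f"loci lie on different chromosomes: {sorted(chroms)}")
    bp_lo = max(l.start_bp for l in loci)
    bp_hi = min(l.end_bp for l in loci)
    cm_lo = max(l.start_cm for l in loci)
    cm_hi = min(l.end_cm for l in loci)
    overlap_bp = (bp_lo, bp_hi) if bp_lo <= bp_hi else None
    overlap_cm = (cm_lo, cm_hi) if cm_lo <= cm_hi else None
    return OverlapResult(
        loci=list(loci),
        overlap_bp=overlap_bp,
        overlap_cm=overlap_cm,
        combined_lod=None,
        classification=NONE,
    )


def combined_lod_at_overlap(
    families: list[Pedigree],
    genotypes: GenotypeMatrix,
    overlap: OverlapResult,
    model: DiseaseModel,
    config: ScanConfig | None = None,
) -> OverlapResult:
    """Rerun multipoint on one shared thinned marker set for every
    contributing family, sum the curves, and take the maximum combined LOD
    inside the overlap (cM interval)."""
    config = config or ScanConfig()
    if overlap.overlap_cm is None:
        return overlap
    chrom = overlap.chromosome
    markers = [m for m in sort_markers(genotypes.markers) if m.chromosome == chrom]
    selected, sets = thin_markers(markers, config.rerun_spacing_cm, config.set_size)
    lo, hi = overlap.overlap_cm
    if not any(lo - 1e-9 <= m.cm <= hi + 1e-9 for m in selected):
        raise CoverageError(
            f"no shared typed marker inside the overlap [{lo}, {hi}] cM on "
            f"chromosome {chrom}"
        )
    grid = _scan_grid(selected, config.grid_step)
    fams = [f for f in families if f.family_id in set(overlap.families)]
    curves = [
        _scan_chromosome(f, genotypes, sets, grid, model, config) for f in fams
    ]
    comb = additive_lod(curves)
    mask = (comb.positions >= lo - 1e-9) & (comb.positions <= hi + 1e-9)
    out = replace(overlap)
    out.loci = list(overlap.loci)
    out.combined_lod = float(comb.lod[mask].max()) if mask.any() else float(
        comb.lod.max()
    )
    out.classify(config.significant_lod, config.suggestive_lod)
    return out


def locus_report(results: list[OverlapResult]) -> pd.DataFrame:
    """Table-style report: one row per contributing family locus and one
    overlap row per result, with the genetic span in cM rounded to two
    decimals."""
    rows = []
    for res in results:
        for loc in res.loci:
            rows.append(
                {
                    "chromosome": loc.chromosome,
                    "family": loc.family_id,
                    "kind": "family",
                    "start_bp": loc.start_bp,
                    "end_bp": loc.end_bp,
                    "start_cm": loc.start_cm,
                    "end_cm": loc.end_cm,
                    "start_snp": loc.boundary_snps[0],
                    "end_snp": loc.boundary_snps[1],
                    "peak_lod": loc.peak_lod,
                    "span_cm": None,
                    "classification": None,
                }
            )
        rows.append(
            {
                "chromosome": res.chromosome,
                "family": "+".join(res.families),
                "kind": "overlap",
                "start_bp": res.overlap_bp[0] if res.overlap_bp else None,
                "end_bp": res.overlap_bp[1] if res.overlap_bp else None,
                "start_cm": res.overlap_cm[0] if res.overlap_cm else None,
                "end_cm": res.overlap_cm[1] if res.overlap_cm else None,
                "start_snp": "",
                "end_snp": "",
                "peak_lod": res.combined_lod,
                "span_cm": res.span_cm,
                "classification": res.classification,
            }
        )
    return pd.DataFrame(rows)
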