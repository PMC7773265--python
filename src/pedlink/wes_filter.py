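"""Exome candidate-variant filter cascade.

Applies the rare-variant cascade used for dominant-family designs to
decomposed, annotated variants: frequency (MAF <= 5% in Europeans, missing
frequency retained), functional class (drop synonymous; drop intergenic /
intronic / ncRNA-intronic), deleteriousness (CADD >= 15 or missing),
conservation (GERP >= 3 or missing), consequence whitelist, affected-only
segregation over the sequenced cohort, restriction to candidate linkage
loci, and per-family segregation within each locus's supporting families.
Genotype-level QC first sets calls with read depth < 10 or genotype quality
< 20 to missing.

Comparator direction for the MAF/CADD/GERP thresholds is configurable
(inclusive by default); every stage reports its surviving count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "Call",
    "SampleGenotype",
    "AnnotatedVariant",
    "FamilySamples",
    "FilterConfig",
    "CascadeTrace",
    "genotype_qc",
    "filter_cascade",
    "table_trace",
    "read_vcf_with_sidecar",
    "read_loci_bed",
]

FUNC_CLASSES = {"exonic", "splicing", "intronic", "intergenic", "ncRNA_intronic", "other"}
EXONIC_FUNCS = {
    "synonymous_snv",
    "nonsynonymous_snv",
    "frameshift",
    "stopgain",
    "stoploss",
    "other",
    "none",
}
DAMAGING_CONSEQUENCES = {
    "nonsynonymous_snv",
    "frameshift",
    "stopgain",
    "stoploss",
    "splicing",
}
EXCLUDED_CLASSES = {"intergenic", "intronic", "ncRNA_intronic"}


class Call(enum.Enum):
    REF = "ref"
    HET = "het"
    HOM = "hom"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Call.HET, Call.HOM)


@dataclass(frozen=True)
class SampleGenotype:
    call: Call
    depth: int | None = None
    quality: int | None = None


@dataclass
class AnnotatedVariant:
    chromosome: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    func_class: str = "other"
    exonic_func: str = "none"
    maf_eur: float | None = None
    cadd_phred: float | None = None
    gerp: float | None = None
    genotypes: dict[str, SampleGenotype] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.maf_eur is not None and not 0.0 <= self.maf_eur <= 1.0:
            raise ValueError("maf_eur must lie in [0, 1]")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown func_class {self.func_class!r}")
        if self.exonic_func not in EXONIC_FUNCS:
            raise ValueError(f"unknown exonic_func {self.exonic_func!r}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def consequence(self) -> str:
        """Splicing counts at the class level, otherwise the exonic call."""
        if self.func_class == "splicing":
            return "splicing"
        return self.exonic_func

    def carrier(self, sample: str) -> bool:
        g = self.genotypes.get(sample)
        return g is not None and g.call.carries_alt


@dataclass(frozen=True)
class FamilySamples:
    """Sequenced members of one family, split by affection status."""

    family_id: str
    affected: tuple[str, ...]
    unaffected: tuple[str, ...]


@dataclass(frozen=True)
class LocusInterval:
    chromosome: str
    start_bp: int
    end_bp: int  # closed
    families: tuple[str, ...] = ()

    def contains(self, chromosome: str, pos: int) -> bool:
        return chromosome == self.chromosome and self.start_bp <= pos <= self.end_bp


@dataclass
class FilterConfig:
    maf_max: float = 0.05
    maf_inclusive: bool = True
    cadd_min: float = 15.0
    cadd_inclusive: bool = True
    gerp_min: float = 3.0
    gerp_inclusive: bool = True
    min_depth: int = 10
    min_gq: int = 20


@dataclass
class CascadeTrace:
    """Ordered (stage name, surviving count) pairs plus the survivor set."""

    stages: list[tuple[str, int]]
    survivors: list[AnnotatedVariant]

    def counts(self) -> dict[str, int]:
        return dict(self.stages)


def genotype_qc(
    variants: list[AnnotatedVariant], min_depth: int = 10, min_gq: int = 20
) -> list[AnnotatedVariant]:
    """Set per-sample genotypes failing depth/quality thresholds to missing.

    Thresholds are exclusive failures (depth < min_depth or quality <
    min_gq); a genotype without depth/quality information fails.  Variant
    records are retained.
    """
    out = []
    for v in variants:
        new_gt = {}
        for sample, g in v.genotypes.items():
            if g.call is Call.MISSING:
                new_gt[sample] = g
                continue
            ok = (
                g.depth is not None
                and g.quality is not None
                and g.depth >= min_depth
                and g.quality >= min_gq
            )
            new_gt[sample] = g if ok else replace(g, call=Call.MISSING)
        out.append(replace(v, genotypes=new_gt))
    return out


def _pass_maf(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.maf_eur is None:
        return True
    return v.maf_eur <= cfg.maf_max if cfg.maf_inclusive else v.maf_eur < cfg.maf_max


def _pass_cadd(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.cadd_phred is None:
        return True
    return v.cadd_phred >= cfg.cadd_min if cfg.cadd_inclusive else v.cadd_phred > cfg.cadd_min


def _pass_gerp(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.gerp is None:
        return True
    return v.gerp >= cfg.gerp_min if cfg.gerp_inclusive else v.gerp > cfg.gerp_min


def _segregates(v: AnnotatedVariant, families: list[FamilySamples]) -> bool:
    """Carried by every sequenced affected and no sequenced unaffected."""
    affected = [s for f in families for s in f.affected]
    unaffected = [s for f in families for s in f.unaffected]
    if not affected:
        return False
    return all(v.carrier(s) for s in affected) and not any(
        v.carrier(s) for s in unaffected
    )


def filter_cascade(
    variants: list[AnnotatedVariant],
    loci: list[LocusInterval],
    families: list[FamilySamples],
    config: FilterConfig | None = None,
) -> CascadeTrace:
    """The nine-stage cascade, applied sequentially with per-stage counts.

    Stage order: MAF, synonymous exclusion, location-class exclusion, CADD,
    GERP, consequence whitelist, cohort-wide affected-only segregation,
    candidate-locus restriction, per-family segregation restricted to each
    locus's supporting families.
    """
    cfg = config or FilterConfig()
    by_fid = {f.family_id: f for f in families}

    def in_any_locus(v: AnnotatedVariant) -> bool:
        return any(l.contains(v.chromosome, v.pos) for l in loci)

    def per_family_seg(v: AnnotatedVariant) -> bool:
        for l in loci:
            if not l.contains(v.chromosome, v.pos):
                continue
            fams = [by_fid[f] for f in l.families if f in by_fid] or families
            if _segregates(v, fams):
                return True
        return False

    stages: list[tuple[str, "object"]] = [
        ("total", lambda v: True),
        ("maf_le_5pct_or_missing", lambda v: _pass_maf(v, cfg)),
        ("without_synonymous_snv", lambda v: v.exonic_func != "synonymous_snv"),
        (
            "without_intergenic_intronic_ncRNA_intronic",
            lambda v: v.func_class not in EXCLUDED_CLASSES,
        ),
        ("cadd_ge_15_or_missing", lambda v: _pass_cadd(v, cfg)),
        ("gerp_ge_3_or_missing", lambda v: _pass_gerp(v, cfg)),
        (
            "damaging_consequence",
            lambda v: v.consequence in DAMAGING_CONSEQUENCES,
        ),
        ("affected_only_cohort", lambda v: _segregates(v, families)),
        ("within_candidate_loci", in_any_locus),
        ("family_segregation_in_loci", per_family_seg),
    ]

    current = list(variants)
    trace: list[tuple[str, int]] = []
    for name, pred in stages:
        current = [v for v in current if pred(v)]
        trace.append((name, len(current)))
    return CascadeTrace(stages=trace, survivors=current)


def table_trace(
    variants: list[AnnotatedVariant],
    loci: list[LocusInterval],
    families: list[FamilySamples],
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Branched report: annotation stages first, then the cohort-wide
    segregation row, then per-locus rows (restriction and family
    segregation) each restarting from the annotation-stage survivors."""
    cfg = config or FilterConfig()
    main = filter_cascade(variants, [], [], cfg)
    annotated = [
        v
        for v in variants
        if _pass_maf(v, cfg)
        and v.exonic_func != "synonymous_snv"
        and v.func_class not in EXCLUDED_CLASSES
        and _pass_cadd(v, cfg)
        and _pass_gerp(v, cfg)
        and v.consequence in DAMAGING_CONSEQUENCES
    ]
    rows = [
        {"stage": name, "count": count}
        for name, count in main.stages[:7]
    ]
    rows.append(
        {
            "stage": "affected_only_cohort",
            "count": sum(1 for v in annotated if _segregates(v, families)),
        }
    )
    by_fid = {f.family_id: f for f in families}
    for l in loci:
        tag = f"{l.chromosome}:{l.start_bp}-{l.end_bp}"
        in_locus = [v for v in annotated if l.contains(v.chromosome, v.pos)]
        rows.append({"stage": f"locus_{tag}", "count": len(in_locus)})
        fams = [by_fid[f] for f in l.families if f in by_fid] or families
        seg = [v for v in in_locus if _segregates(v, fams)]
        rows.append({"stage": f"locus_{tag}_family_segregation", "count": len(seg)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def _num(x: str) -> float | None:
    x = x.strip()
    return None if x in ("", ".", "NA", "nan") else float(x)


def read_vcf_with_sidecar(
    vcf_path: str | Path, anno_path: str | Path
) -> list[AnnotatedVariant]:
    """Decomposed VCF (v4.2) plus a tab-separated annotation table keyed by
    chrom:pos:ref:alt with columns gene, func_class, exonic_func, maf_eur,
    cadd_phred, gerp (empty field = missing).  FORMAT fields DP and GQ are
    read when present."""
    from cyvcf2 import VCF

    anno = pd.read_csv(anno_path, sep="\t", dtype=str).fillna("")
    key_cols = ["chrom", "pos", "ref", "alt"]
    anno_map = {
        ":".join(str(row[c]) for c in key_cols): row for _, row in anno.iterrows()
    }
    out: list[AnnotatedVariant] = []
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{rec.CHROM}:{rec.POS}: multiallelic record; decompose first"
            )
        key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        row = anno_map.get(key)
        genotypes: dict[str, SampleGenotype] = {}
        depths = rec.format("DP")
        quals = rec.format("GQ")
        for i, sample in enumerate(samples):
            gt = rec.gt_types[i]  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            call = {0: Call.REF, 1: Call.HET, 3: Call.HOM, 2: Call.MISSING}[int(gt)]
            dp = int(depths[i][0]) if depths is not None and depths[i][0] >= 0 else None
            gq = int(quals[i][0]) if quals is not None and quals[i][0] >= 0 else None
            genotypes[sample] = SampleGenotype(call=call, depth=dp, quality=gq)
        out.append(
            AnnotatedVariant(
                chromosome=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                gene=(row["gene"] or None) if row is not None else None,
                func_class=(row["func_class"] or "other") if row is not None else "other",
                exonic_func=(row["exonic_func"] or "none") if row is not None else "none",
                maf_eur=_num(row["maf_eur"]) if row is not None else None,
                cadd_phred=_num(row["cadd_phred"]) if row is not None else None,
                gerp=_num(row["gerp"]) if row is not None else None,
                genotypes=genotypes,
            )
        )
    return out


def read_loci_bed(path: str | Path, families_by_locus=None) -> list[LocusInterval]:
    """Half-open BED converted to 1-based closed intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            fams: tuple[str, ...] = ()
            if families_by_locus:
                fams = tuple(families_by_locus.get((chrom, start + 1, end), ()))
            elif len(parts) > 3:
                fams = tuple(parts[3].split(","))
            out.append(
                LocusInterval(
                    chromosome=chrom, start_bp=start + 1, end_bp=end, families=fams
                )
            )
    return out
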