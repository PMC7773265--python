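"""End-to-end pipeline orchestration.

``run_pipeline`` executes simulate -> Mendelian QC -> genome scan ->
per-family locus discovery -> overlap intersection -> combined additive LOD
-> haplotype segregating intervals and per-family penetrance -> variant
filter cascade, writing plain-text artifacts (TSV/JSON) plus a manifest.
Every stochastic stage derives its stream from the single configured seed,
so a rerun with the identical configuration writes identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import haplotyping, locus_discovery, simulate, wes_filter
from .disease_model import DiseaseModel, from_prevalence
from .linkage import LodCurve
from .locus_discovery import ScanConfig
from .pedio import Phenotype, write_ped_map

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Serialisable configuration for one pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int | None = None
    # disease model
    prevalence: float = 0.03
    penetrance: float = 0.8
    phenocopy: float = 0.0
    allele_freq: float | None = None  # overrides the prevalence-derived q
    # simulation
    n_families: int = 3
    preset: str = "threegen12"
    n_markers: int = 101
    marker_spacing_cm: float = 1.0
    maf: float = 0.5
    disease_position_cm: float = 50.0
    min_affected: int = 4
    # analysis stages
    scan_spacing_cm: float = 0.2
    rerun_spacing_cm: float = 0.3
    set_size: int = 50
    bit_cap: int = 20
    significant_lod: float = 3.0
    suggestive_lod: float = 2.0
    # variant cascade
    n_noise_variants: int = 9

    def model(self) -> DiseaseModel:
        base = from_prevalence(self.prevalence, self.penetrance)
        q = self.allele_freq if self.allele_freq is not None else base.q
        return DiseaseModel(q=q, f0=self.phenocopy, f1=self.penetrance, f2=self.penetrance)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            spacing_cm=self.scan_spacing_cm,
            rerun_spacing_cm=self.rerun_spacing_cm,
            set_size=self.set_size,
            bit_cap=self.bit_cap,
            significant_lod=self.significant_lod,
            suggestive_lod=self.suggestive_lod,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _curves_tsv(curves: list[LodCurve], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tcM\tfamily\tlod\n")
        for c in curves:
            for x, y in zip(c.positions, c.lod):
                fh.write(f"{c.chromosome}\t{x:.6f}\t{c.family_id}\t{y:.6f}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the artifact manifest (also written as
    ``manifest.json``)."""
    if config.seed is None:
        raise ValueError("config.seed is required before any work is done")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict.pop("out_dir")  # paths stay out of the manifest: artifact names
    # are relative so identical configs give byte-identical outputs
    manifest: dict = {"stages": [], "artifacts": {}, "config": cfg_dict}
    t0 = time.time()
    timings: dict[str, float] = {}

    def stage(name: str):
        # wall-clock timings go to the log, not the manifest, so reruns
        # with an identical config stay byte-identical
        manifest["stages"].append({"name": name})
        timings[name] = round(time.time() - t0, 3)

    model = config.model()

    # -- simulate ----------------------------------------------------------
    families, truths = [], {}
    geno = None
    for i in range(config.n_families):
        cfg = simulate.SimulationConfig(
            pedigree_template=config.preset,
            n_markers=config.n_markers,
            spacing_cm=config.marker_spacing_cm,
            maf=config.maf,
            disease_position_cm=config.disease_position_cm,
            model=model,
            ascertainment_min_affected=config.min_affected,
            seed=int(np.random.SeedSequence((config.seed, i)).generate_state(1)[0] % (2**31)),
            family_id=f"F{i + 1}",
        )
        ped, g, truth, _ = simulate.ascertain(cfg)
        families.append(ped)
        truths[ped.family_id] = truth
        if geno is None:
            geno = g
        else:
            geno = _merge_genotypes(geno, g)
    write_ped_map(families, geno, out / "cohort.ped", out / "cohort.map")
    manifest["artifacts"]["ped"] = "cohort.ped"
    manifest["artifacts"]["map"] = "cohort.map"
    stage("simulate")

    # -- Mendelian QC ------------------------------------------------------
    from .pedio import mendelian_check, set_violations_missing

    violations = [v for fam in families for v in mendelian_check(fam, geno)]
    if violations:
        geno = set_violations_missing(geno, violations, families)
    manifest["mendelian_violations"] = len(violations)
    stage("mendelian_check")

    # -- genome scan -------------------------------------------------------
    scan_cfg = config.scan_config()
    scan = locus_discovery.genome_scan(families, geno, model, scan_cfg)
    curves = [c for fam in scan.per_family.values() for c in fam.values()]
    curves += list(scan.combined.values())
    _curves_tsv(curves, out / "curves.tsv")
    manifest["artifacts"]["curves"] = "curves.tsv"
    manifest["combined_significant"] = bool(scan.any_significant)
    stage("scan")

    # -- locus discovery ---------------------------------------------------
    loci = []
    for fam_id, per_chrom in scan.per_family.items():
        for chrom, curve in per_chrom.items():
            loci.extend(locus_discovery.extract_family_loci(curve, geno.markers))
    results = []
    by_chrom: dict[str, list] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom, ll in by_chrom.items():
        if len(ll) < 2:
            continue
        ov = locus_discovery.intersect_loci(ll)
        if ov.overlap_bp is not None:
            ov = locus_discovery.combined_lod_at_overlap(
                families, geno, ov, model, scan_cfg
            )
        results.append(ov)
    report = locus_discovery.locus_report(results)
    report.to_csv(out / "loci.tsv", sep="\t", index=False)
    with open(out / "loci.json", "w") as fh:
        json.dump(json.loads(report.to_json(orient="records")), fh, indent=1)
    manifest["artifacts"]["loci"] = "loci.tsv"
    manifest["n_candidate_loci"] = len(loci)
    manifest["overlaps"] = [
        {
            "chromosome": r.chromosome,
            "families": r.families,
            "overlap_bp": r.overlap_bp,
            "combined_lod": r.combined_lod,
            "classification": r.classification,
        }
        for r in results
    ]
    stage("locus_discovery")

    # -- haplotypes --------------------------------------------------------
    intervals = {}
    for fam in families:
        hap = haplotyping.phase_pedigree(fam, geno)
        hint = None
        sig = [r for r in results if r.overlap_bp]
        if sig:
            hint = sig[0].overlap_bp
        iv = haplotyping.segregating_interval(fam, hap, region_hint=hint)
        if iv is not None:
            intervals[fam.family_id] = {
                "chromosome": iv.chromosome,
                "start_bp": iv.start_bp,
                "end_bp": iv.end_bp,
                "start_marker": iv.start_marker,
                "end_marker": iv.end_marker,
                "carriers": iv.carriers,
                "penetrance": haplotyping.per_family_penetrance(fam, iv),
            }
    with open(out / "haplotype_intervals.json", "w") as fh:
        json.dump(intervals, fh, indent=1)
    manifest["artifacts"]["haplotypes"] = "haplotype_intervals.json"
    stage("haplotypes")

    # -- variant cascade ---------------------------------------------------
    cascade_loci = [
        wes_filter.LocusInterval(
            chromosome=r.chromosome,
            start_bp=r.overlap_bp[0],
            end_bp=r.overlap_bp[1],
            families=tuple(r.families),
        )
        for r in results
        if r.overlap_bp
    ]
    fam_samples = [
        wes_filter.FamilySamples(
            family_id=fam.family_id,
            # sample ids are family-qualified: PED individual ids are only
            # unique within a family, sequencing sample ids must be global
            affected=tuple(
                f"{fam.family_id}.{m.individual_id}"
                for m in fam.members
                if m.phenotype is Phenotype.AFFECTED
            ),
            unaffected=tuple(
                f"{fam.family_id}.{m.individual_id}"
                for m in fam.members
                if m.phenotype is Phenotype.UNAFFECTED
            ),
        )
        for fam in families
    ]
    if cascade_loci:
        variants = simulate.simulate_variant_table(
            cascade_loci,
            fam_samples,
            n_noise=config.n_noise_variants,
            seed=config.seed,
        )
        variants = wes_filter.genotype_qc(variants)
        trace = wes_filter.filter_cascade(variants, cascade_loci, fam_samples)
        with open(out / "cascade.tsv", "w") as fh:
            fh.write("stage\tcount\n")
            for name, count in trace.stages:
                fh.write(f"{name}\t{count}\n")
        manifest["artifacts"]["cascade"] = "cascade.tsv"
        manifest["cascade_survivors"] = [v.key for v in trace.survivors]
    stage("wes_filter")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    import logging

    logging.getLogger(__name__).info("stage timings: %s", timings)
    return manifest


def _merge_genotypes(a, b):
    """Concatenate two cohorts typed on identical marker maps."""
    from .pedio import GenotypeMatrix

    if [m.name for m in a.markers] != [m.name for m in b.markers]:
        raise ValueError("marker maps differ between families")
    return GenotypeMatrix(
        markers=list(a.markers),
        samples=list(a.samples) + list(b.samples),
        calls=np.concatenate([a.calls, b.calls], axis=0),
    )
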