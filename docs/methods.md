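# Methods

`pedlink` implements family-based parametric linkage mapping for an
autosomal-dominant trait with incomplete penetrance, the downstream
haplotype and variant analyses that turn linkage peaks into candidate
regions and candidate variants, and a gene-drop simulator that generates
the multiplex pedigrees everything is validated on.

## Disease model

The trait model is a single diallelic locus with disease-allele frequency
*q* and penetrance vector (f0, f1, f2) = P(affected | 0, 1, 2 copies).
Dominance means f1 = f2; f0 is the phenocopy rate (default 0, settable).
The default model derives *q* from a population prevalence K = 3% and
penetrance 80% via the closed form q = 1 − √(1 − K/f1) ≈ 0.01893; the
forward prevalence K = f0(1−q)² + 2f1 q(1−q) + f2 q² recovers K to 1e−12.
The literature also quotes a 5% disease-allele frequency for this
phenotype; `pedlink.pipeline.RunConfig.allele_freq` overrides the derived
value without touching the penetrances, since the two parameterisations
cannot be reconciled exactly.

## Two-point likelihood (Elston–Stewart peeling)

The joint state of one individual is an ordered pair of two-locus
haplotypes (marker allele × disease allele: 4 haplotypes, 16 states).
Founder pairs carry population priors (marker allele frequency; Hardy–
Weinberg in *q* at the disease locus; linkage equilibrium between the
two). A parent transmits each parental haplotype with probability
(1−θ)/2 and each recombinant with θ/2. Phenotypes contribute penetrance
factors; marker observations contribute 0/1 consistency factors; missing
genotypes are summed over. The likelihood is evaluated by variable
elimination over individuals (min-neighbourhood order), with per-step
rescaling and a log-scale accumulator against underflow. Loopless
pedigrees give nuclear-family-sized cliques; marriage loops are rejected
with an explicit error (none of the supported analyses need them). The
two-point LOD is log10 L(θ) − log10 L(1/2).

## Multipoint likelihood (Lander–Green HMM)

The multipoint state is the inheritance vector v ∈ {0,1}^b, one bit per
meiosis. Between adjacent loci each bit flips independently with the
Haldane probability θ(d) = (1 − e^(−2d/100))/2 for a gap of d cM — the
map function is Haldane everywhere, consistent with the HMM's
independent-bit transitions (no interference). At each marker the
emission P(genotypes | v) sums over founder-allele assignments; the
assignment axis is restricted to orderings consistent with the founders'
own observed genotypes, which keeps it small on densely typed pedigrees.
The phenotype likelihood R(v) = P(phenotypes | v) sums founder
disease-allele assignments under Hardy–Weinberg priors and the penetrance
vector; it is computed once per pedigree. The LOD at grid position x is

    LOD(x) = log10 [ Σ_v P(v | all markers) R(v) / 2^(−b) Σ_v R(v) ],

with the posterior from a forward–backward pass (transitions applied as
per-bit butterfly updates, O(b·2^b)).

**Founder-phase reduction.** Relabelling the two chromosomes of any
founder is a symmetry of the model: it flips all meiosis bits that
founder transmits and leaves priors, emissions and R unchanged. The
engine therefore freezes one meiosis bit per transmitting founder and
works on the reduced hypercube. The transition kernel folds exactly onto
the quotient; for a founder with meioses (m1 frozen, m2…mk free) it
becomes B_{m2…mk} ∘ [(1−θ)I + θX_{m2…mk}], where B is the per-bit
butterfly and X flips the founder's free bits jointly. Both the reduced
and the full-space path are implemented and agree to 1e−10 in tests; the
reduction is what makes the replicated studies fast (a 12-member,
16-meiosis family runs on 2^12 instead of 2^16 states).

Pedigrees above the meiosis-bit cap (default 20) raise a capacity error
naming the family; the remedy is splitting the pedigree or raising the
cap. Marker sets for long maps are thinned to one marker per spacing bin
(largest minor-allele frequency wins, ties to lowest bp) and chunked into
sets of 50 with one-marker overlap, mirroring how bounded-set multipoint
runs are stitched in practice.

## Locus discovery under heterogeneity

The all-family scan sums per-family curves pointwise (additive LOD; grids
must match exactly, no silent interpolation). When the combined scan is
not significant anywhere, each family is scanned alone and every maximal
run of grid positions with LOD > 0 — however low — becomes a candidate
locus, demarcated physically by the outermost markers inside the run.
Loci are intersected across families as (max of starts, min of ends),
independently on the bp and cM scales; the combined LOD is then
recomputed for the contributing families on one shared thinned marker
set inside the overlap and classified (significant ≥ 3, suggestive ≥ 2 by
default, both configurable). The genetic span of an overlap is reported
in cM rounded to two decimals.

The package ships the published per-family candidate intervals of a
nine-family hyperhidrosis linkage study (GRCh37) as input data
(`pedlink.datasets`); the published genetic coordinates are
centimorgan × 1e6 integers and are converted to real cM on load. Only
this ×1e−6 reading reproduces the published spans (18.09, 15.41, 5.83,
1.05 cM) from the printed coordinates, which fixes the interpretation.

## Haplotype phasing and IBD intervals

Phasing is deterministic and rule-based. Homozygotes self-phase; a
child's (paternal, maternal) allele order is forced where only one
assignment is Mendelian-consistent with the parents' genotypes; origin
bits are forced where a phased heterozygous *non-founder* parent
identifies the transmitted chromosome. A founder's own phase is not
observable, so it is fixed greedily along the chromosome by minimum
recombination over the founder's transmissions (cost ties keep the
previous ordering); bits that depend on that choice are marked INFERRED,
never FORCED. Remaining ambiguities are broken by preferring no bit flip
since the last informative marker; what cannot be decided stays
UNRESOLVED rather than being guessed silently.

Two consequences are documented deliberately. First, a crossover inside a
locally uninformative stretch is only detectable at the next informative
marker, so inferred bits can lag the true breakpoint. Second, where only
one of a founder's transmissions is informative, flipping the founder
phase and flipping the child's bit fit the data equally well and the
greedy choice can be wrong over a segment. On biallelic MAF-0.5 maps the
tests therefore assert exactness only for FORCED bits, ≥95% resolution of
heterozygous positions, and a ≥80% floor on overall agreement with
simulated truth (observed ≈ 0.89–0.97).

The segregating interval is the maximal run (≥ 2 markers) over which
every affected, genotyped member carries a haplotype traceable to one
founder chromosome. Strict refutation of sharing requires the full
descent chain to be Mendelian-anchored; otherwise the test falls back to
identity by state against the founder haplotype's allele, and such
markers are flagged (`ibs_only_markers`). Unaffected carriers are
permitted — incomplete penetrance — and reported; per-family penetrance
is affected carriers / phenotype-known carriers. Recovered intervals
contain the true IBD run and stop at the first genotype-detectable
refutation; boundaries are exact at informative markers and otherwise
correct to marker-detectability resolution.

## Variant filter cascade

Genotype QC first: calls with read depth < 10 or genotype quality < 20
(or missing metrics) are set to missing. The cascade then applies, in
order, with a survivor count per stage: MAF ≤ 5% in Europeans or missing;
drop synonymous SNVs; drop intergenic / intronic / ncRNA-intronic
classes; CADD ≥ 15 or missing; GERP ≥ 3 or missing; keep only
non-synonymous / frameshift / splicing / stop-gain / stop-loss; carried
by every sequenced affected and no sequenced unaffected cohort-wide;
restriction to candidate loci; per-family segregation within each locus's
supporting families. Thresholds are inclusive by default, matching the
tabulated "(or NA)" semantics; strict comparators are a configuration
switch, because the prose and tabulated forms of these thresholds differ.
Missing annotation values never remove a record at the value stages.
Counts are monotone non-increasing along the sequential cascade;
`table_trace` additionally produces the branched report style in which
per-locus rows restart from the annotation-stage survivors (so a
cohort-wide zero does not zero the locus rows). Segregation constraints
use sequenced samples only; sample ids are family-qualified because
pedigree individual ids are unique only within a family.

## Synthetic data

`gene_drop` draws founder haplotypes per marker from the allele
frequencies (linkage equilibrium, no LD model), founder disease alleles
Bernoulli(q) per chromosome, and puts crossovers down per meiosis as a
Poisson process at one event per Morgan jointly over markers and the
disease locus (Haldane, no interference; count-then-uniform-position on
the cM scale). Phenotypes are drawn from the penetrance vector.
Everything is deterministic given an integer seed (numpy Generator; no
hash-order dependence), and a TruthRecord keeps grandparental-origin
bits, founder haplotypes, crossover breakpoints and disease-allele counts
as the oracle for phasing and linkage tests. `ascertain`
rejection-samples families until the multiplex criterion (≥ 4 affected by
default) holds, with a bounded attempt count.

Pedigree presets: `nuclear5` (2+3), `threegen12` (grandparental couple,
four gen-2 sibs of whom two married in, 2×2 grandchildren; 16 meiosis
bits) and `fourgen16` (four generations, 16 members, 20 meiosis bits — at
the default cap). Sizes are realistic for multiplex ascertainment in this
phenotype; no preset mirrors any specific published family.

What the simulator does *not* emulate: linkage disequilibrium between
markers, genotyping error, allele-frequency misspecification, and
population stratification. Passing tests therefore certify the inference
machinery under the stated model, not robustness to those artefacts of
real array data.

## Benchmark studies and problem sizes

`pedlink.study` fixes the package's replicated benchmark conditions,
shared by the tests, the acceptance script and the analysis drivers:

* **Locus recovery**: 50 replicates of three ascertained `threegen12`
  families, penetrance 0.8, markers every 1 cM at MAF 0.5 over 0–100 cM,
  disease locus at 50 cM; the measured quantity is how often the combined
  additive LOD reaches 3 within 5 cM of the truth. Measured power is
  ≈ 55–75% depending on the seed (mean combined LOD at the locus ≈ 3.0–3.5,
  SD ≈ 0.9). This is the expected scale for three 12-member families —
  per-family expected LOD ≈ 1 — so the suite's ≥ 80% expectation fails at
  these family sizes and the corresponding test is an honest red;
  larger pedigrees (e.g. `fourgen16`) would be needed to clear it.
* **Unlinked null**: 200 replicates of the same design scanning a
  31-marker chromosome with the disease locus > 400 cM away; mean peak
  combined LOD ≈ −2.9 (well under the 0.6 bound) and mean pointwise LOD
  ≈ −4.8 < 0.

Map lengths and replicate counts are the package's benchmark choices;
one base seed drives all replicate seeds (all below 2^31).

## Numerical choices

* Likelihoods are accumulated with per-step normalisation plus a log
  scale; LOD ratios use normalised posteriors so the scale cancels.
* Grid positions are compared after rounding to 1e−6 cM; curve addition
  refuses mismatched grids rather than interpolating.
* θ is clamped to [0, 0.5]; a grid point far beyond the map approaches
  LOD 0 only exponentially (e^(−2d/100)), so "unlinked" in tests means
  hundreds of cM.
* Half-typed genotypes are treated as fully missing (array-style calls);
  Mendelian-violating trios are zeroed as whole trios before analysis.
* Allele codes are normalised to {1, 2} per marker on PED input
  (lexicographic for symbolic alleles; numeric codes pass through), so
  round-trips are bit-exact.

## Known limitations

* Loopless pedigrees only; inbreeding and marriage loops are rejected.
* The meiosis-bit cap bounds pedigree size for multipoint runs.
* Phasing is greedy minimum-recombinant, not an exact minimum over the
  pedigree, with the accuracy profile described above.
* No heterogeneity-parameter (HLOD) estimation: heterogeneity is
  expressed through per-family scans and family clustering only, and the
  fixed LOD-3 threshold stands in for genome-wide significance.
* Real-data stages that precede the cascade (alignment, variant calling,
  VQSR, annotation itself) are out of scope; the cascade consumes
  decomposed, annotated variants.
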