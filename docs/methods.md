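# Methods

This note documents the models behind `polypat`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter when interpreting results.

## The biological model

Grass gametophytic self-incompatibility (GSI) is controlled by two
unlinked multiallelic loci, S and Z. A haploid pollen grain expressing
alleles (s, z) is rejected by a pistil with diploid genotypes
{S₁, S₂} / {Z₁, Z₂} **iff** s ∈ {S₁, S₂} **and** z ∈ {Z₁, Z₂}; any single
mismatch lets the grain through (`is_compatible`). Two consequences shape
everything downstream: a live plant can never be SI-homozygous under
strict SI (the fertilizing pollen would have had to doubly match), and
compatibility is asymmetric in the cross direction, because the pollen
side is haploid while the pistil side is diploid.

## Synthetic data generator

`simulate_founders` builds a mapped founder population: 21 chromosomes ×
150 cM with equally spaced markers by default, alternate-allele
frequencies uniform on a configurable MAF window, and diploid S/Z
genotypes forced heterozygous whenever more than one allele segregates.
Two haplotype models are available:

* **independent** (default): every marker allele is an independent
  Bernoulli draw from its frequency. There is no linkage disequilibrium;
  this is the right substrate for testing parentage, QC and diversity
  statistics, whose behavior should not depend on LD.
* **bottleneck** (`n_ancestral_haplotypes = A`): each founder haplotype is
  a mosaic copied from A ancestral haplotypes, switching ancestry between
  adjacent loci with probability 1 − exp(−g·d/100) for map distance d cM
  and `copying_generations` g (default 4). This emulates a breeding
  population descended from a handful of plants and produces LD that
  decays with distance. Because SI loci sit under intense balancing
  selection, their allelic lineages are ancient and their flanking
  haplotypes deeply diverged; the generator emulates this by giving each
  S (and Z) allele a lineage profile near its locus — every profile
  column is a random non-trivial binary partition of the k lineages, as
  any variant arising on a deep allelic genealogy must be — which an
  ancestral haplotype copies with probability exp(−d / 4 cM). Markers
  immediately at an SI locus therefore tag the segregating lineages, and
  the tagging fades within a few centimorgans. Without this feature no
  marker carries information about SI genotype sharing and association
  mapping of the loci is impossible in principle.

`make_gametes` performs meiosis with Haldane crossovers (probability
(1 − e^(−2d/100))/2 between adjacent loci); the S and Z alleles ride on the
haplotype segments containing their map positions, so marker–SI
cotransmission follows the map.

`simulate_polycross` draws, per mother and seed, a pollen donor with
probability proportional to fecundity (a stand-in for inflorescence
count; the demo and recovery experiments draw fecundity from
lognormal(0, 0.6), giving the several-fold spread between weak and
prolific pollen parents that polycross nurseries show). Under SI
enforcement an incompatible grain is discarded and both donor and gamete
are redrawn (mass-action pollen competition; a gamete-only mode exists).
Self-pollination is excluded by default — under strict SI self pollen
always doubly matches — and a `selfing_rate` exists solely to exercise the
selfing detector with SI off. Seeds that find no compatible pollen within
`max_pollen_attempts` (200) are skipped and counted.

`simulate_gbs` overlays the observation process: total depth per call is
negative-binomial (shape 2 by default — strongly overdispersed, as
restriction-site based libraries are), reads report the alternate allele
with probability g/2 flipped at a 0.5% per-read error, and the emitted
record keeps raw allele depths plus a provisional call. Zero depth is
missing; all depth-based *filtering* is left to the QC stage.

What the generator does **not** emulate: polyploid dosage (inheritance is
strictly disomic, the chromosomes merely number 21), pollen-tube growth
kinetics and style-age effects, flowering-time assortment (only
approximable through fecundity weights), post-zygotic seed failure (all
rejection is prezygotic — the field data cannot distinguish these, and
neither can a test built on this generator), and reference-bias or
paralog-collapse artifacts of real GBS alignment.

## Quality control

Calls are masked before any marker statistics: homozygous calls need
total depth ≥ 4 (below that a true heterozygote too easily shows one
allele), heterozygous calls need at least one read of each allele by
default. The stricter two-reads-of-each-allele switch
(`min_het_reads_each=2`) exists because with deep data a single stray
error read otherwise fabricates heterozygotes: at 20× and 0.5% per-read
error roughly 9% of homozygote calls would acquire a bogus contrasting
read, and the end-to-end association experiment (below) uses the strict
rule for its deeply sequenced parents for exactly this reason. Thresholds
are interpreted strictly as stated: markers keep missingness < 0.70 and
MAF > 0.01; individuals are dropped above 0.95 missingness. The
reliability index is the sum of z-scored call rate and z-scored mean
depth (a zero-variance component contributes 0); the parentage panel
takes the 2500 top-index markers among those with missingness ≤ 0.50 and
MAF ≥ 0.02, with lexicographic tie-breaks for determinism.

## Parentage model

Per locus, observed genotypes follow a mistyping mixture: with
probability e the observation is an independent Hardy–Weinberg draw.
The LOD of a candidate father is
Σ ln [ P(o | m, f) / P(o | m, random male) ] over typed loci, with missing
genotypes marginalized (a missing father or offspring call contributes
exactly 0). All 4×4×4 per-locus tables are precomputed so scoring is a
gather, and e is floored at 10⁻⁴ during scoring (even if the user asks
for 0) so a single contradictory locus cannot veto a candidate with −∞;
exact e = 0 arithmetic remains available to tests via `floor_error=False`.
Delta — best minus runner-up LOD — is calibrated by simulating offspring
under the same thinning/error regime (`n_sim` defaults to 10,000, which
keeps calibration under a minute; the classical 250,000 is honored via
config) and choosing the smallest Delta whose exceeders are correct at
the requested confidence (0.95 strict / 0.80 relaxed). When no thresholds
are supplied, assignment reports every scored offspring at the relaxed
tier; offspring typed at fewer than `min_typed_loci` (300) markers are
never assigned.

## Diversity statistics

Shannon's H is computed over families with count > 0 using natural logs;
a balanced set of k families attains exactly ln k, so
`min_crosses_for_diversity(H)` = the smallest k with ln k ≥ H (guarded
against floating-point noise at exact powers). Ordered families count
nonzero cells of the female × male matrix; unordered families pool
reciprocals. The "theoretical maximum" for 89 parents uses all 89² = 7921
cells including selfs, matching ln 7921 ≈ 8.98; both self-inclusive and
self-exclusive conventions are available. The fecundity correlation is
Pearson's r between inflorescence count and ln(progeny) over successful
fathers only (ln is undefined at zero, and unsuccessful fathers carry no
count information beyond the zero itself).

## Association model

Pair encoding follows single-locus GSI logic at each biallelic marker:
the ordered pair (female, male) codes +1 iff the male carries an allele
absent from the female (some pollen class escapes), −1 otherwise. All
nine genotype combinations are fixed by this rule; self pairs are −1
everywhere. Missing parent calls are first filled by sampling from each
marker's observed genotype frequencies — deliberately simple, unbiased
for allele frequency, and adequate while parent missingness stays
moderate (≲ 10%); it adds attenuation noise rather than bias, which is
why the recovery experiment keeps parent calls clean rather than leaning
on the imputer.

The scan fits y = Xβ + g + sτ + ε with g ~ N(0, σ²_g K). K is the
centered cross-product relationship matrix (VanRaden normalization
Σ2p(1−p) for {0,1,2} dosages; marker count for the ±1 pair codes).
Variance components are estimated once by REML under the marker-free null
(eigendecomposition of K, 21-point log-grid plus bounded scalar
refinement) and reused for every marker — the P3D shortcut. Each marker
is then a generalized-least-squares t-test whose residual scale is refit
from that marker's model, so with K = I and vanishing σ²_g the p-values
are exactly ordinary least-squares F-tests (the engine's oracle check).

Fixed effects X: for the parent-level models B–D (phenotype = progeny
matrix PC1–3, computed with parents as rows, columns centered, unscaled),
X holds the intercept plus the five leading marker-matrix principal
components, the standard structure correction. For the pair-level model
A (7921 pseudo-individuals), marker-matrix PCs turn out to be the wrong
structure correction on two counts, found during implementation: the
SI-region code columns are mutually correlated blocks, so a leading PC
can *be* the S- or Z-lineage contrast and silently absorb the very signal
being tested; and no marker-derived covariate can capture non-genetic
parent main effects (fecundity, per-mother sampling depth), which
otherwise inflate the scan's tails into spurious genome-wide
discoveries on no-SI null data. Model A therefore uses
female-parent and male-parent indicator factors (2P − 2 columns) as X:
the natural "population structure" of a pseudo-individual is its parental
composition, projecting these out removes all parent main effects
exactly, and marker tests become pure female × male interaction tests —
the component of variation that gametophytic SI generates. With factor
covariates the same no-SI nulls produce zero genome-wide discoveries.

Multiple testing uses Storey–Tibshirani q-values (π₀ from the cubic
smoother over λ ∈ {0.05,…,0.95}, falling back to Benjamini–Hochberg
π₀ = 1 whenever the estimate is unstable or fewer than 100 p-values are
available), applied genome-wide and separately within designated
SI-candidate chromosomes.

## The recovery experiment

`polypat.experiments.si_recovery_replicate` runs the whole chain at a
size chosen to finish in well under a minute per replicate: 60 parents,
14 chromosomes × 214 markers (≈ 3000), k_S = k_Z = 4, bottleneck founders
(16 ancestral haplotypes), 33 seeds per mother (≈ 1980 progeny), parents
at 20× and progeny at 6.5× depth, strict contrasting-read het rule,
panel-based paternity assignment (no Delta gating; assignment accuracy is
itself reported and sits near 1.0), then the model-A scan with factor
covariates. It reports the map distance from each SI chromosome's
minimum-p marker to the true locus and the genome-wide FDR discovery
count.

Interpretation caveat: with four SI alleles a biallelic marker can only
express a two-group partition of the allelic lineages, so even a marker
in perfect LD with the locus captures a minority of the exact-sharing
signal; depending on the founder draw, the best achievable single-marker
interaction effect is not always separable from the largest of the ~200
null markers on the same chromosome. Localization of a given locus to
10 cM therefore succeeds in most but not all replicates, and the joint
S-and-Z event less often. A no-SI run of the same pipeline yields
genome-wide discovery counts consistent with the nominal FDR (zero in
almost all replicates). Passing these tests shows the chain recovers
strong SI architecture from its own observation model; it does not certify
power on real GBS data, where LD structure, allele numbers and sampling
are all less favorable.

## Reproducibility

Every stochastic stage takes a seed; the pipeline driver derives
per-stage seeds from one global seed by hashing the stage name, so stages
are independently reproducible and identical configurations give
identical artifacts (the manifest records versions, parameters and
per-stage counts). Coordinates are 1-based (VCF convention); genetic
positions are floats in cM, exported to bp as round(cM × 10⁶) + 1.
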