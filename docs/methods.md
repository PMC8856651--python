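# Methods

## Family model and the pedigree fixture

The genetic model throughout is a fully penetrant autosomal-dominant trait
with zero phenocopy rate and a vanishingly rare disease allele: carriers are
affected, non-carriers are not, and at most one parent of any child carries
the allele. Under these assumptions affection status is a perfect proxy for
carrier status wherever genotypes are absent; the package uses that proxy
only for ungenotyped (deceased) members, and otherwise reads carrier status
from genotype calls.

The packaged family (`data/family_hgf.ped`) is a 25-member, four-generation
pedigree: 23 alive genotyped members (12 heterozygous carriers, all affected;
11 wild-type, all unaffected) plus two deceased ungenotyped founders, the
affected one an obligate carrier. Published pedigree drawings are rarely
machine-readable, and this one is shipped as an explicit *reconstruction*:
the member list, sexes and affection statuses are fixed, but the exact
sibling-vs-spouse topology within the middle generations is one consistent
choice, documented in the file header. The reconstruction is constrained so
that every genotyped carrier has a carrier parent in the pedigree and no
genotyped non-carrier does, which fixes the number of phase-known
informative meioses at 12 (3 transmissions from the obligate-carrier
founder, 9 from genotyped carrier parents).

**Obligate carriers** are inferred to a fixed point with two forcing rules
(a carrier child with a known non-carrier parent forces the other parent; a
child of two non-carriers is forced non-carrier), seeded by the affection
proxy for ungenotyped members. Contradictions raise an error rather than
being resolved silently.

**Informative meioses** are genotyped children with a known call whose
parents have known carrier status with exactly one carrier. Children of two
carriers are excluded (phase unresolvable), as are children of two
non-carriers (nothing to observe). Meioses from obligate-carrier parents are
counted — standard phase-known dominant counting, and the only convention
under which a 12-meiosis family yields the headline LOD below.

## Co-segregation filtering

A variant *segregates* iff every genotyped affected sample carries ≥1
alternate allele and every genotyped unaffected sample is hom-ref. Design
choices, each exposed as an option:

* affected members may be het or hom-alt by default (`require_het` tightens
  this); hom-alt calls are flagged as atypical for a rare dominant variant;
* missing calls are compatible but counted and reported; `strict_missing`
  rejects instead. The behaviour of the original ad hoc filters on missing
  data is generally unspecified, so both policies are first-class;
* multi-allelic sites are decomposed into one record per alternate allele
  before filtering; indel normalisation is assumed done upstream;
* annotation (gene, region class, population frequencies) is consumed from a
  sidecar TSV and never computed — this package does not re-implement a
  functional annotator.

The population filter keeps variants with frequency ≤ `max_af` (default 0)
in every required panel; a variant absent from a panel's table counts as
frequency 0 there and is flagged "unobserved".

## Two-point LOD

With NR non-recombinant and R recombinant meioses,

    LOD(θ) = log10[ (1−θ)^NR · θ^R / 0.5^(NR+R) ],

evaluated on a θ grid over [0, 0.5] (default step 0.001, ties toward smaller
θ). At θ = 0 with R > 0 the likelihood vanishes; the point is carried as
−inf and excluded from maximization. Complete co-segregation over the
12-meiosis fixture gives LOD(0) = 12·log10 2 = 3.612, reported to one
decimal as 3.6. Internally full precision is retained. The grid argmax
agrees with the closed form θ̂ = R/(NR+R) to within one grid step (property
tested). Multipoint linkage, liability classes and incomplete penetrance
are out of scope.

## ACMG/ClinGen classification

Evidence items carry a code, direction and strength; the combining rules are
data (`data/acmg_rules.json`), evaluated over counts of items per strength
and direction, with pathogenic-vs-benign conflicts resolved to uncertain
significance. PP1 (co-segregation) strength scales with the maximum LOD:
supporting ≥ 0.6, moderate ≥ 1.5, strong > 3 (strict). Only the strong
cutoff is anchored to the modelled study; the lower tiers follow common
co-segregation practice and all thresholds are configurable. PS3 and PM2
are asserted inputs (PM2 can be auto-derived from the population filter);
automated scoring of the remaining criteria and the Bayesian point system
are out of scope.

## Expression stage

**Normalisation.** CPM = count/library·10⁶ (length-free — the standard
definition; gene length enters only FPKM = CPM/length_kb). Library sizes are
equalised to their geometric mean before testing; no TMM-style composition
correction is applied.

**Dispersion.** A single common NB dispersion φ is estimated by a
method-of-moments rule: per gene, pooled within-group residual variance s²
and overall mean m on equalised counts give φ_g = max(0, (s²−m)/m²); the
estimate is the median of φ_g over expressed genes. Because the median of a
variance estimate on few residual degrees of freedom sits below its
expectation (the pooled df in a 2-vs-4 design is 4, and
median(χ²₄)/4 ≈ 0.839), s² is first divided by median(χ²_df)/df; without
that correction the common dispersion is under-estimated by ~16% and
downstream p-values are anticonservative. With no replicated group the
estimator is undefined and a documented fallback (0.1) is returned with a
warning.

**Exact test.** Counts are scaled to the reference library size, summed
within groups, and rounded. For iid NB(μ, φ) samples the split of the total
t between groups is conditionally BetaBinomial(t, n_A/φ, n_B/φ) —
independent of μ — and Binomial(t, n_A/(n_A+n_B)) in the Poisson limit.
Two-sided p doubles the smaller tail (tails include the observed value),
capped at 1; t = 0 gives p = 1. Tail sums are computed in log space over the
shorter side. This is a deliberately transparent replacement for the classic
quantile-adjusted exact-test machinery: numerical agreement with any
particular package is explicitly not a goal; the contract is distributional
(oracle equivalence to exhaustive enumeration, null type-I calibration, FDR
control, planted-effect recovery — all tested).

**Downstream.** BH step-up FDR; significance at FDR < α (strict) and
|log2FC| ≥ 1, with log2FC on group-mean CPM plus a prior count of 0.5;
top-N per direction ranked by fold change with ties broken by FDR then gene
id; heatmap rows divided by their row mean ("average normalisation" — the
assumed reading of that phrase, with zero-mean rows zeroed and flagged);
over-representation by the upper-tail hypergeometric with BH across sets,
enrichment ratio k/K, default universe = genes at CPM ≥ 1 in ≥ 2 samples.

## qPCR

Replicates are averaged on the Ct scale; ΔCt = Ct_target − Ct_reference per
sample; ΔΔCt subtracts the control-group mean ΔCt; relative expression is
2^(−ΔΔCt), so the control group has geometric mean exactly 1. Amplification
efficiency is fixed at 2 (no standard-curve correction). Group comparisons
use the pooled-variance t-test by default ("Student's"), Welch via flag;
stars at p < 0.05 / p < 0.01.

## Synthetic data: what it emulates and what it does not

* `simulate_family` drops independent biallelic variants through the fixture
  pedigree: founder allele frequencies from Beta(0.2, 5) (rare-skewed,
  configurable), Mendelian transmission, optional genotyping error (call
  shifted to a random other state) and missingness. With penetrance 1 the
  causal genotypes are conditioned on the fixture's affection pattern,
  reproducing the study family deterministically; with penetrance < 1 the
  allele is gene-dropped from the affected founder and affection drawn per
  carrier. Not modelled: linkage disequilibrium between background variants,
  read-level errors, relatedness-aware allele-frequency structure — so the
  background false-positive rate of the co-segregation filter in tests
  reflects independent sites only.
* `simulate_counts` draws per-gene log-normal baselines (default ln-mean 6.6,
  ln-sd 1.5, i.e. ~2.3k mean counts/gene — the per-gene coverage of a
  ~45M-read library over ~20k expressed genes), common-dispersion NB counts
  for 2 patients vs 4 controls, and plants 70 DE genes (40 up / 30 down,
  |log2FC| = 2) by default. Not modelled: gene-specific dispersion trends,
  composition effects, batch structure — passing recovery tests therefore
  demonstrates the test's behaviour under its own model, not robustness to
  those violations. At these study conditions the honest power of the design
  fluctuates by seed (sensitivity roughly 0.55–0.8 across seeds); a 2-vs-4
  comparison at φ = 0.15 is simply a low-powered design.
* `simulate_ct` generates Ct = base − log2(fold) + Gaussian noise per
  replicate with a constant reference gene; technical and biological
  replication are not distinguished.

All generators are deterministic given (config, seed) to the byte.

## Problem sizes used in checks

Acceptance-level checks run at: 100 family simulations × 5000 background
variants (filter recovery); exhaustive enumeration of all totals ≤ 200 × 3
dispersions (exact-test oracle); 20 × 5000-gene null matrices (calibration);
one 5000-gene planted matrix (recovery). The full suite completes in about
a minute on one core.

## Known limitations

Recessive/X-linked models, kinship coefficients, quality-based genotype
filtering, GLM/quasi-likelihood DE, batch correction and figure rendering
are out of scope. The ACMG engine scores only the evidence lines it is
given. The pedigree fixture's topology is a reconstruction; analyses that
depend on sibling-vs-spouse assignments beyond the meiosis count should not
rely on it.
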