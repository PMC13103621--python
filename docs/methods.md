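# Methods

## Scope and data model

All statistics operate on a `GenotypeMatrix`: a samples × sites matrix of
alternate-allele dosages with a per-sample ploidy vector (2 or 4) and a
per-site annotation table (chrom, pos, ref, alt, QD, FS, MQ). Dosage is
the only genotype information used anywhere — allele phase, read depth
and allele balance are never modelled. VCF 4.2 is the interchange format;
genotypes are unphased (`/`-separated) at the sample's ploidy, with
`./././.`-style missing calls.

## Segregation models and the simulator

The simulator emulates *post-calling* genotype data for three segregation
hypotheses. Per site, an alternate-allele frequency p is drawn from a
Beta(a, b) founder distribution; the default Beta(0.8, 0.8) gives the
U-shaped site-frequency spectrum typical of SNP discovery panels (most
sites near-fixed, a minority at intermediate frequency). Dosages are then:

- `diploid_hw`: Binomial(2, p) per individual;
- `tetrasomic`: Binomial(4, p) — autotetraploid, random pairing of all
  four homologs;
- `disomic`: sum of two independent Binomial(2, ·) subgenome draws.
  A fraction `subgenome_divergence` of sites is differentially fixed
  (subgenome frequencies 1 and 0, so every individual has dosage 2);
  the remaining sites place all segregation in one subgenome at
  min(1, 2p) with the other fixed for the reference. This
  maximal-divergence placement makes the disomic pattern maximally
  distinct from the tetrasomic one, which is the contrast the
  classification is designed around.

Clonal populations replicate one drawn founder genotype. Pedigree
offspring are formed from one gamete per parent: 2 homologs drawn without
replacement from 4 (tetrasomic), one per subgenome (disomic), or 1 of 2
(diploid). Missingness is i.i.d. per genotype call — simpler than
per-sample dropout and sufficient to exercise every presence/missingness
filter. QD/FS/MQ annotations are drawn from pass/fail mixtures with
*planted counts*: `round(fraction × n_sites)` sites per criterion,
disjointly assigned, so filter survivor counts are known exactly.

What the simulator does **not** emulate: linkage (sites are independent
given their positions), demographic structure of wild populations,
read-level error, depth-dependent genotype uncertainty, or null alleles.
Passing tests therefore demonstrate correctness of the estimators and
filters under their stated models, not robustness to genotyping error in
real panels.

## Filter cascade

Thresholds follow standard GATK hard-filter practice with exact boundary
semantics: removal on QD < 2.0, FS > 60, MQ < 40 (strict — a site at
exactly a threshold survives); presence ≥ 0.80 inclusive; missingness
removal strictly above 0.20; thinning gap ≥ 10,000 bp. Records missing an
annotation pass that criterion unless `drop_unannotated` is set.

Decisions made where the procedure was genuinely open:

- **Singleton** means total minor-allele dosage equal to 1, the natural
  unit in mixed-ploidy data (a single simplex tetraploid is a singleton;
  one duplex carrier, dosage 2, is not). A carrier-count mode
  (`mode="carriers"`) is provided.
- **Thinning** is the greedy first-kept-wins scan per chromosome. It is
  deterministic and matches common practice; no optimal-subset search.
- **Intersection** of the diploid- and tetraploid-called sets keys on
  (chrom, pos, ref, alt); `position_only=True` relaxes to positions,
  matching `bcftools isec` defaults. Genotype payloads are taken from the
  callset matching each sample's sheet ploidy.
- **Stage order**: hard filter → intersection → presence/biallelic, then
  three branches (least-missing top-N for coancestry;
  singleton/missingness for the PHYLIP export; thinning for the
  structure export). Whether the presence screen ran before or after the
  intersection in comparable published workflows is usually unstated;
  the order here is a package default, and every stage is an independent
  function so any order can be composed.
- Every stage is idempotent, and `FilterReport` counts telescope; the
  thinning stage asserts its own gap postcondition on every run.

## Inheritance-mode classification

For a sample group sharing one called ploidy, the observed spectrum is
the per-site pair (p, g₀..g_k), with p the dosage-weighted group-internal
allele frequency and g_c the fraction of called genotypes at dosage c.
Sites with fewer than 2 called genotypes are skipped; sites monomorphic
within the group are excluded from fitting (every model predicts the same
degenerate spectrum there).

Candidate surfaces: tetrasomic Binomial(4, p); disomic in the
maximal-divergence one-parameter form (p₁ = min(1, 2p), p₂ = max(0, 2p−1);
explicit (p₁, p₂) accepted); diploid Binomial(2, p). Diploid-called
groups are fitted against Binomial(2, p) and against both tetraploid
surfaces collapsed to presence classes (0 / het / k). Forcing
p₁ = p₂ = p reduces the disomic model to the tetrasomic one exactly —
used as an equivalence oracle in the tests.

The fit statistic is RMSE over (site, class) cells. Chi-square-style
weighting was rejected: under the disomic surface many expected cells are
exactly 0, making inverse-expectation weights unstable. The verdict is
the smallest-RMSE model; a tetrasomic verdict with five-class score
> 0.5 is labelled "tetrasomic (strong)". The five-class score uses
p ∈ [0.45, 0.55]: the theoretical criterion is "all five classes at
p = 0.5", and a finite window is required at finite sample size. Groups
with fewer than 10 polymorphic sites raise an explicit insufficient-data
error instead of returning a verdict.

A caveat the package surfaces rather than hides: dosage data alone cannot
distinguish a true diploid genotyped at ploidy 4 (classes {0, 2, 4} via
Binomial(2, p) on half-dosages) from an extreme disomic tetraploid. The
sample sheet's ploidy call disambiguates; both fits are reported.

## Coancestry

Per locus, r̂ₗ = x_ref y_ref/p_ref + x_alt y_alt/p_alt − 1 with
within-individual frequencies x = d/k; biallelic locus weight is 1, so
the multi-locus estimate is the mean over loci called in both
individuals. Expected values for non-inbred Hardy–Weinberg individuals:
E[r̂_self] = 1/k (brute-force enumeration over Binomial(k, p) dosages
confirms this identically in the tests), 0.25 for diploid
parent–offspring, 0 for unrelated pairs.

Panel allele frequencies are dosage-weighted over all called genotypes,
*including* the focal pair — the plain moment estimator. This induces an
O(1/N) downward bias on off-diagonal estimates (≈ −0.01 at N = 100
diploids); `leave_pair_out=True` recomputes frequencies per pair for
sensitivity checks. Loci monomorphic in the panel are excluded; a pair
sharing zero called polymorphic loci gets NaN (flagged, never 0);
negative estimates are reported as-is.

Heatmap ordering: average-linkage hierarchical clustering on 1 − r̂
affinely rescaled to [0, 1], with missing pairs imputed to the panel mean
for ordering only and lexicographic pre-sorting of samples for
deterministic tie-breaking. Only the ordering is part of the contract;
rendering is generic matplotlib.

## Genome size

1C_sample = peak_sample / peak_standard × 1C_standard. Rounding is
decimal half-up everywhere: replicate 1C to 3 decimals, sample means to
2, chained intermediate standards to 3. The chained-standard convention
(3-decimal mean of the intermediate's replicate 1C values) is the one
convention that reproduces published replicate values computed through an
intermediate standard; chaining error relative to a direct measurement is
bounded by 0.0005 × ratio per chaining step. Peaks are inputs — no FCS
parsing or peak detection.

## Exporters

PHYLIP: hom-ref → ref base, hom-alt → alt base, any intermediate dosage →
IUPAC code of {ref, alt} (dosage 1, 2, 3 are indistinguishable — a
nucleotide alignment cannot encode dosage), missing → N. Invariant-column
pruning treats ambiguity codes as uncertainty, as ascertainment-corrected
likelihoods do: a column is pruned when a single base is consistent with
every non-N character (so a column of hom-ref plus heterozygotes is
pruned — it cannot be certified variable). The relaxed-PHYLIP header
always equals the written column count.

structure: one row per allele copy at the cohort's maximum ploidy,
alleles 0/1 sorted, diploids padded with −9 rows, missing genotypes fully
−9 — structure's documented missing-data convention. The tetraploid row
multiset ↔ dosage map is a bijection, verified by round-trip. The
mainparams template records burn-in 200,000 and 1,000,000 MCMC
repetitions; running structure itself is out of scope.

## Problem sizes and determinism

Simulation-based checks use 50 individuals × 5000 sites (20 replicates
per mode) for inheritance recovery, and 50–100 individuals × 5000 loci
for coancestry calibration — sizes at which the estimators' expectations
are resolvable well inside the asserted tolerances. All randomness flows
from a single integer seed through `numpy.random.default_rng`; a fixed
seed and config reproduce VCFs byte-for-byte and pipeline manifests
checksum-for-checksum.

## Known limitations

- No likelihood-based relatedness or inbreeding estimation; the moment
  estimator's variance per pair is substantial at few loci.
- No read-backed ploidy inference (allele-balance methods); ploidy is an
  input from the sample sheet.
- Partial subgenome divergence (0 < divergence < 1) produces disomic
  spectra that approach the tetrasomic surface as divergence → 0;
  classification accuracy degrades accordingly and is only guaranteed at
  the extremes.
- QD/FS/MQ are consumed, never computed from reads; indels are not
  handled.
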