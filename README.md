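# mixploid

Mixed-ploidy SNP analysis for crop population genetics: is a cultivated
plant an autotetraploid, an allotetraploid, or a diploid — and how are its
varieties related?

The package was built around the black pepper (*Piper nigrum*) question:
cultivated pepper is 2n = 52 (tetraploid), long hypothesised to be an
allotetraploid hybrid of Indian *Piper* species. Distinguishing the two
tetraploid origins is possible from SNP genotype data alone, because they
segregate differently. `mixploid` provides the full post-variant-calling
toolchain for that analysis, usable on any mixed diploid/tetraploid SNP
panel:

- **simulate** — synthetic genotype cohorts (VCF + sample sheet) with
  diploid Hardy–Weinberg, tetrasomic (autotetraploid), and disomic
  (allotetraploid, two subgenomes) segregation, clones, pedigrees,
  missingness, and planted QD/FS/MQ annotation distributions.
- **filtering** — the site-selection cascade: GATK-style hard filters
  (QD < 2.0, FS > 60, MQ < 40, strict inequalities), dual-ploidy callset
  intersection, ≥80% presence + biallelic screen, singleton and >20%
  missingness removal, 10 kb LD thinning, least-missing top-N selection.
- **inheritance** — allele-frequency vs genotype-class-frequency spectra
  and Hardy–Weinberg classification of the inheritance mode.
- **coancestry** — Ritland method-of-moments kinship for mixed ploidy,
  with average-linkage ordering for heatmaps.
- **cytometry** — flow-cytometry 1C genome-size estimation with chained
  internal standards.
- **exporters** — relaxed PHYLIP (invariant columns pruned for Lewis
  ascertainment-bias correction) and structure input files.

## The statistics at the core

At a biallelic site with alternate-allele frequency *p*, a tetraploid
individual's dosage *d* ∈ {0..4} follows, under Hardy–Weinberg:

- **tetrasomic** (all four homologs pair at random):
  P(d = c) = C(4, c) p^c (1−p)^(4−c), i.e. Binomial(4, p). At p = 0.5
  all five dosage classes are populated (mass ≥ 1/16 each) — the
  diagnostic signature of an autotetraploid.
- **disomic** (two independent diploid subgenomes at frequencies p₁, p₂):
  d = B₁ + B₂ with Bᵢ ~ Binomial(2, pᵢ). In the maximal-divergence
  parametrization (p₁ = min(1, 2p), p₂ = max(0, 2p−1)), p = 0.5 gives a
  point mass at d = 2: every individual a fixed heterozygote.

Classification fits both surfaces to the observed spectrum by RMSE over
(site, class) cells and reports the five-class score — the fraction of
sites with p ∈ [0.45, 0.55] showing all five classes.

Pairwise relatedness uses the Ritland moment estimator with
within-individual allele frequencies x = d/k (ploidy k):

r̂ₗ = x_ref y_ref / p_ref + x_alt y_alt / p_alt − 1,  averaged over shared
polymorphic loci. Expected values: 1/k for a non-inbred individual with
itself (0.5 diploid, 0.25 tetraploid), 0.25 for diploid parent–offspring,
0 for unrelated — so it works across ploidies without modification.

Genome size: 1C_sample = peak_sample / peak_standard × 1C_standard, with
half-up rounding (3 decimals per replicate, 2 for sample means) and
chained intermediate standards when a sample's genome is too close to the
primary standard.

## Worked example

```bash
python examples/02_inheritance_mode.py
```

```
tetrasomic   -> tetrasomic (strong)    (tetrasomic rmse=0.0383, disomic rmse=0.1189, five-class score 0.91)
disomic      -> disomic                (tetrasomic rmse=0.3236, disomic rmse=0.0000, five-class score 0.00)
diploid_hw   -> diploid                (diploid rmse=0.0349, tetrasomic rmse=0.2034, disomic rmse=0.2580)
```

Each line is one simulated 50-individual × 5000-site panel. The true
segregation model always attains the lowest RMSE; the five-class score is
0.91 for the autotetraploid panel (nearly every mid-frequency site shows
all five dosage classes) and exactly 0 for the allotetraploid one. The
other scripts in `examples/` cover the filter cascade, coancestry with
clones and parent–offspring pairs, genome size, and the full pipeline
(`mixploid run --config …` is the CLI equivalent).

Flow-cytometry genome sizes from the built-in *Piper* peak measurements:

```bash
python examples/04_genome_size.py   # or: mixploid genomesize
```

prints per-replicate 1C values (Kuching 0.863/0.864 pg, Panniyur
0.862/0.862 pg, …) and per-sample means: cultivated *P. nigrum* averages
0.86 pg — twice-diploid content consistent with its tetraploid chromosome
count.

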