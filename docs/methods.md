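# Methods

## Copying model

Imputation uses the diploid Li–Stephens haplotype-copying HMM. Given a
phased reference panel of K haplotypes over M biallelic SNPs, the sample's
two haplotypes are hidden mosaics of panel templates. The state space is
the ordered pair (i, j) ∈ K × K; both chromosomes move independently.

* **Transitions.** Over a physical gap of d bp, a haplotype keeps its
  template with probability (1 − s) + s/K and jumps to each specific other
  template with probability s/K, where s = 1 − exp(−ρ·d). Distances are
  physical base pairs with a constant intensity ρ; no genetic map is
  consumed. Chromosomes are independent chains: the state distribution
  restarts uniform at every chromosome boundary.
* **Emissions.** The copied alleles are observed imperfectly: a template
  allele is miscopied with probability θ per site. The two (possibly
  miscopied) alleles are then scored against the site's genotype
  likelihood triplet L(g). Summing the four miscopy configurations gives
  P(data | i, j) = Σ_{x₁,x₂} m(x₁|aᵢ) m(x₂|aⱼ) L(x₁+x₂),
  m(x|a) = 1−θ if x = a else θ. Likelihood triplets are meaningful up to
  a positive factor; posteriors are invariant to rescaling.
* **Genotype likelihoods.** Sequencing data enter as per-site
  (ref, alt) read counts under a symmetric per-read error e:
  P(alt read | g) = e, ½, 1−e for g = 0, 1, 2. Base qualities are not
  modelled — counts are assumed pre-filtered upstream. Array calls (used
  by the leave-one-out arm) map to 1−ε on the called genotype and ε/2 on
  the other two; a missing call is the flat triplet.

Forward–backward is exact over the K² pair states. The transition kernel
factorizes per haplotype, so one step is O(K²) (partial row/column sums
plus a rank-one term) rather than O(K⁴). The forward pass is rescaled per
site and the scale factors accumulate into the sample log-likelihood; the
backward message is rescaled by its own sum. Genotype posteriors are
assembled from the posterior mass on the three template-allele-sum
classes (both templates ref / mixed / both alt), which is all the
emission model can distinguish. The inner recursions are numba-compiled
with per-element loops; results agree with exhaustive path enumeration to
below 1e-10 on small instances (tested).

### Leave-one-out dosages

The array-side quality measure masks each typed site's own observation
and records the dosage the rest of the chain implies. Because emissions
factorize across sites, the state posterior at site t given all data
*except* t is proportional to (T·F_{t−1}) ⊙ B_t — the forward prediction
before t's emission times the backward message, which by construction
excludes t's emission. One forward–backward pass per sample therefore
yields every masked dosage at once, and the masked observation has
exactly zero influence on its own dosage (tested to 1e-12 under
permutation of the masked call).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| ρ (rho) | 4e-8 | per bp | ≈ 4Nₑr for human-like Nₑ = 10⁴, r = 1e-8 |
| θ (theta) | 1e-3 | per site | template miscopy probability |
| call threshold | 0.90 | posterior | call iff max-posterior genotype ≥ 0.90, else no-call; a tied maximum is a no-call (with a permissive threshold ≤ 0.5 ties break to the lower genotype) |
| e (read error) | 0.01 | per read | typical short-read substitution error |
| ε (array error) | 0.005 | per call | simulated array genotype error |
| array missingness | 0.01 | per call | simulated array no-call rate |

All are exposed in `HMMParams` / `SimConfig` and on the CLI. ρ and θ are
not re-estimated from data; calibration is left to configuration.

## Synthetic data

The generator emulates the inputs of a low-pass-vs-array comparison on
79 diploid individuals:

* **Panel** (`simulate_panel`): M sites at distinct random positions in a
  20 Mb region (defaults K = 200, M = 2000). Per-site target frequencies
  are Beta(0.2, 0.2) truncated to [1/K, 1−1/K] — enriching rare variants
  relative to uniform. Haplotype 0 is drawn i.i.d.; each later haplotype
  copies a mosaic of earlier ones (template switches at 1e-7 per bp,
  fresh frequency-p draws at 2% of sites), creating linkage
  disequilibrium. Monomorphic columns are redrawn along the stored copy
  paths so LD with neighbours survives; an unlucky column is forced to a
  singleton after 100 attempts.
* **Individuals** (`simulate_individual`): each haplotype is a mosaic of
  panel templates with switches at the HMM's own default rate and miscopy
  θ = 1e-3 — deliberately inside the model family, so recovery failures
  indicate implementation defects, not model mismatch. A higher switch
  rate can be passed to probe robustness.
* **Reads** (`simulate_reads`): site depth ~ Poisson(c); each read copies
  a uniformly chosen haplotype's allele and flips with probability e.
  `downsample_counts` thins each read independently with probability f —
  the count-level equivalent of sampling raw reads, exact for Poisson
  depths (thinned Poisson(c) is Poisson(cf)).
* **Array** (`simulate_array`): the true genotype, replaced by one of the
  other two uniformly with probability ε, then masked at the missingness
  rate.

What this does **not** emulate: coalescent-exact genealogies, read
length/fragment structure, base-quality variation, reference bias,
population structure, and genotyping-array ascertainment. Passing tests
demonstrate correctness of the inference and evaluation machinery under
a well-specified generative process — not performance on real cohorts.

## Benchmark design and problem sizes

`run_benchmark` simulates one cohort (K = 200, M = 2000, 79 individuals),
sequences at 1x, thins to the coverage ladder {1, 0.8, 0.6, 0.4},
imputes every sample at every coverage, simulates the array, and
evaluates: stratified concordance ({all, a 216-site "ADME-like" random
subset} × {all, rare, common}), dosage r² per variant binned by
array-measured MAF, and the array leave-one-out r². A single top-level
seed spawns per-stage and per-sample seeds, so reports are bit-identical
across reruns. These sizes keep the full benchmark near two minutes on
one CPU while leaving hundreds of common variants per r² bin.

At seed 1 the benchmark reproduces the expected qualitative behaviour:
PPA, NPA and common-variant r² increase monotonically with coverage and
mean no-call counts fall. One full-scale feature does not carry over to
desk scale: with only 200 copying templates, sequencing imputation r² at
common variants (0.83–0.88 across the ladder) sits slightly *below* the
nearly-error-free array's leave-one-out r² (0.90), whereas with
full-size reference panels low-pass sequencing above 0.4x overtakes the
array. The harness measures both arms either way.

## Numerical and design choices

* **Concordance corner case.** A truth-het called hom-alt is a false
  negative (the variant genotype was not recovered), never a false
  positive; FPs are reserved for non-reference calls at truth hom-ref
  sites. This keeps the partition identities exact
  (tp+fn+no-calls = truth-variant sites; tn+fp+no-calls = truth-ref
  sites). The raw non-ref/non-ref mismatch tally is reported separately
  so alternative conventions can be recomputed.
* **MAF bins.** Left-open intervals (lo, hi] with default edges
  (0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5]; a MAF equal to an edge
  belongs to the bin it closes. "Common" = MAF > 5%. Cohort MAF is
  computed from truth calls excluding no-calls.
* **r² conventions.** Variants monomorphic in truth are undefined (NaN,
  excluded from bin means); a constant dosage at a polymorphic truth
  variant scores 0 (flagged degenerate).
* **Averaging.** PPA/NPA/no-calls are unweighted arithmetic means across
  individuals; an individual with an empty denominator is left out of
  that mean.
* **Allele harmonization.** Site-indexed inputs must agree exactly on
  (chrom, pos, ref, alt); mismatches raise rather than strand-flip.
* **Degenerate inputs.** An all-zero likelihood triplet, or data that
  contradicts certain copying with θ = 0 (vanishing forward probability),
  fails with the offending site named.
* **Panel-size comparisons.** Under this generator, truth individuals
  are mosaics of whatever panel exists, so simply increasing K adds
  copying entropy without adding better templates and does not improve
  r². The meaningful analogue of choosing a richer reference panel is
  imputing the same cohort against the full simulated panel versus a
  subset of its haplotypes; the full panel is never worse (tested).

## Known limitations

Exact O(K²)-per-site inference limits panels to desk scale (hundreds of
haplotypes); no PBWT-style pruning is attempted. Indels and multiallelic
sites are out of scope, as are phasing of the imputed sample, joint
multi-sample imputation, and HLA-specific calling. Counts enter at site
level: alignment, duplicate marking and pileup extraction are upstream.
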