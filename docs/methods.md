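# Methods

## The screen

`memoryscreen` implements multi-gradient permutation survival screening
(MEMORY): a resampling procedure that asks not merely *whether* a gene's
expression stratifies patient survival, but whether that association is
*stable* as the cohort size varies.

Given a TPM expression matrix (genes × samples) and right-censored survival
data, the screen:

1. pre-sets a ladder of subsample sizes ("gradients") — by default ten
   sizes at roughly 10%…100% of the cohort, computed as
   `round_half_up(j·n/10)` with a floor of 10 samples and the last size
   forced to the full cohort;
2. at each gradient draws `N` random subsets without replacement (default
   1000 permutations; one draw is shared by **all** genes so that gene-wise
   outcomes are correlated within a permutation — this correlation is what
   the downstream similarity score exploits);
3. within each drawn subset splits samples into equal-sized low/high halves
   by each gene's median expression (stable rank split: ties keep cohort
   order; the low half gets the extra sample when the subset is odd);
4. records `k[j,i,n] = 1` iff the two-group Mantel–Haenszel log-rank test
   has p < α (default 0.05, strict), else 0. Undefined tests (no events,
   empty group) and degenerate genes (constant in the subset) are coded 0
   and counted in per-gradient diagnostics.

Averaging over permutations gives the significance-probability matrix

    A[i, j] = (1/N) Σₙ k[j, i, n] ∈ [0, 1].

The **saturation gradient** j\* is the smallest j at which some gene
reaches A = 1. Genes with `A[i, j*] > 0.8` (strict) are the GEARs — genes
steadily associated with prognosis. When no gradient saturates, the screen
falls back to the largest gradient and flags the result; an alternative
"sustained" extraction mode instead requires a gene to stay above the
threshold from its first crossing onward.

The log-rank engine is vectorized over genes: one pass sorts the drawn
subset by time, then computes observed-minus-expected event counts and
hypergeometric variances at each distinct death time for a whole block of
group-label vectors at once. A full default screen is on the order of 10⁶
individual tests; the vectorized form runs a 500-gene, 300-sample,
10-gradient, 100-permutation screen in under ten seconds on one CPU.

No multiple-testing correction is applied inside the screen: the
probability threshold itself plays the role of a stability filter, and a
rigorous FDR treatment of the final GEAR catalogue is an explicit
limitation (a Benjamini–Hochberg post-filter on saturation-gradient
p-values can be layered on by the caller; it is off by default).

## Survival-analysis similarity and the core survival network

Two genes that affect prognosis through the same biology tend to be
significant in the *same* permutations at the first (smallest) gradient,
where sampling noise makes significance most variable. With `a`, `b` the
significant-permutation counts of genes A and B and `c` the number of
permutations in which both are significant,

    SAS(A, B) = c / (a + b − 2c + 1).

The formula is implemented exactly as stated. Note it is **not** bounded by
1: identical vectors give `a = b = c`, hence SAS = c. A normalized Jaccard
variant `c / (a + b − c)` is available behind a flag (off by default).

Candidate edges connect every GEAR to every other gene (unordered,
deduplicated). The core survival network (CSN) keeps the top 1000 edges
under a deterministic total order (SAS desc, joint count desc,
lexicographic pair id), so ties at the cutoff are reproducible. **Hub
genes** are the GEAR nodes with mean full-cohort expression strictly above
10 TPM, ranked by degree (ties: SAS-weighted degree, then gene id), top 10
kept.

## Subtype clustering and genomic comparison

Samples are clustered on `log2(TPM + 1)` hub-gene profiles with Ward's
minimum-variance criterion on Euclidean distances (the `ward.D2`
convention; `scipy.cluster.hierarchy` implements exactly this for raw
observations), cut to k = 3 clusters. Clusters are renamed 1…k by ascending
mean hub-gene expression, giving low/medium/high semantics. The procedure
is deterministic and permutation-equivariant.

Subgroups are compared genomically: tumor mutation burden is the per-sample
count of non-silent mutation records (missense, nonsense, nonstop,
frameshift and in-frame indels, splice site, translation start site;
configurable), optionally divided by a capture size in Mb (default 38 when
requested). Differential mutation between two clusters tabulates per-gene
carriers vs non-carriers and applies a two-sided Fisher exact test with
Benjamini–Hochberg adjustment across the genes tested; genes absent from
both clusters are skipped and logged.

## Dependency-score mutation effects

For each gene with mutation calls across cell lines, dependency scores are
contrasted between mutant and wild-type lines:

    D_m  = |s̄_m − s̄_wt|
    S_dm = 2 (s̄_m − s̄_wt) / (s̄_m + s̄_wt)

with a two-sample t-test (Welch by default — group sizes and variances
differ wildly across mutations; Student's pooled test behind a flag). A
mutation is **functional** when p < 0.05 and S_dm > 0.1 (both strict;
boundary values are non-functional), and **subtype-associated functional**
when its carrier frequency additionally differs across molecular subtypes
(p < 0.05). Because dependency scores are frequently negative, `s̄_m + s̄_wt`
can be ≤ 0, where the ratio's sign no longer tracks the mean difference;
such genes are flagged `indeterminate_scale`, excluded from the S_dm
criterion, and therefore never classified functional. Groups with fewer
than two lines are skipped with a recorded reason.

## Synthetic cohorts

The generator produces ground-truthed inputs for every stage. Expression is
log-normal TPM with per-gene `meanlog ~ U(0.5, 3.5)` and `sdlog = 1` — a
spread that straddles the 10-TPM hub filter. The planted prognostic genes
are noisy copies of one latent per-sample "program" signal (correlation
ρ = 0.9), emulating the co-expressed programs (mitosis, immune) that
stability screens of this kind recover; null genes are independent noise.

Survival follows proportional hazards: samples whose latent program
activity is above the cohort median carry `baseline_hazard × HR` (default
HR = 3), the rest the baseline (1/1800 events/day). Event times are
exponential, censoring uniform on (0, 3650] days; the closed form
`P(censored) = (1 − e^{−λC})/(λC)` gives ≈ 43% censoring on a null cohort
and ≈ 30% on the planted preset. Driving the hazard through the shared
program rather than through each gene independently is deliberate: a
product of 20 independent per-gene hazard factors of 3 would span 3²⁰,
extinguishing censoring entirely and burying each gene's marginal effect
under the frailty of the other 19 — no screen could (or should) recover
such a planting. With the program design, each planted gene's median split
approximates the program split, so its log-rank test sees close to the
full hazard ratio, and program members share correlated significance
vectors — precisely the structure SAS is designed to score.

Mutation profiles are Bernoulli carriers with cluster-specific
probabilities emitted as missense records; dependency screens are Gaussian
scores (per-gene means U(0.2, 0.8), noise sd 0.1) with a planted mean shift
in mutant lines (Bernoulli mutation status).

What the generator does *not* emulate: TCGA marginal expression
distributions per cancer type, batch effects, multi-aliquot barcodes,
copy-number/fusion events, non-proportional hazards, or informative
censoring. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not performance on real
cohorts.

## Numerical and design choices

- **Determinism.** A single master seed spawns an independent RNG substream
  per (gradient, permutation) via `SeedSequence(seed, spawn_key=(j, n))`,
  so results are independent of execution order. Drawn indices are sorted
  ascending, which (a) makes every full-cohort draw identical, so the last
  gradient's probabilities are exactly binary, and (b) anchors median-split
  tie-breaking to cohort order. Identical inputs + config + seed give
  byte-identical artifacts (sha256-recorded in the run manifest).
- **p exactly equal to α** codes 0 (the significance rule is strict).
- **Gradient rounding** is round-half-up with a minimum size floor of 10
  and a forced full-size final gradient.
- **Edge and hub ties** are resolved by deterministic total orders (see
  above), so outputs do not depend on storage order.
- **Problem sizes in the test and acceptance runs** (e.g. 100 permutations,
  200–500 genes, cohorts of 120–300) are scaled-down study conditions
  chosen so the whole suite exercises every stage end to end in minutes;
  the method's standard operating point is 1000 permutations.

## Known limitations

- At 100 permutations the saturation rule (first gradient whose best gene
  hits probability 1) is itself noisy: a lucky gene can saturate one
  gradient early, where weaker planted genes have not yet cleared 0.8, so
  GEAR sensitivity varies across seeds (measured 0.55–1.0 on the default
  planted preset, false-positive rate 0 throughout). The method's standard
  1000 permutations stabilizes saturation considerably.
- The SAS formula as stated is unbounded for identical vectors; rankings
  are still well defined, but absolute values above 1 should not be read as
  probabilities. The normalized variant is available when a bounded score
  is needed.
- The screen performs ~10⁶ uncorrected tests; GEAR lists are exploratory
  screens, not confirmatory findings.
- Only the two-group log-rank is supported: no Cox covariate adjustment,
  no interval censoring.
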