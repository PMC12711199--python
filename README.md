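# memoryscreen

Multi-gradient permutation survival screening (MEMORY) for transcriptomic
cohorts, with its downstream survival-similarity network, hub-gene subtype
clustering and CRISPR-dependency mutation scoring.

## The problem

Single survival analyses of gene expression are notoriously unstable: the
same gene can look prognostic, protective, or irrelevant depending on the
cohort and its size. This package screens for **GEARs** — *Genes stEadily
Associated with pRognosis* — by asking whether a gene's median-split
log-rank association with survival is significant *consistently* under
repeated subsampling at increasing cohort fractions.

For gene *i* at sampling gradient *j* (≈10%…100% of the cohort, ten
levels), `N` random subsets are drawn (default `N = 1000`); `k[j,i,n] = 1`
records a significant log-rank test (p < 0.05) in permutation *n*. The
significance-probability matrix is

    A[i,j] = (1/N) · Σₙ k[j,i,n]

and the screen reads GEARs off the **saturation gradient** — the smallest
*j* at which some gene reaches `A = 1` — as the genes with `A > 0.8` there.

Downstream, genes significant in the *same* permutations are scored with
the survival-analysis similarity

    SAS(A,B) = c / (a + b − 2c + 1)

(`a`, `b` significant counts, `c` joint count, first gradient); the top
1000 pairs form the core survival network, whose highest-degree GEARs with
mean expression > 10 TPM are the hub genes. Samples are clustered on
`log2(TPM+1)` hub-gene profiles (Ward/Euclidean, k = 3) into low/medium/
high subtypes, which can be compared by tumor mutation burden and per-gene
Fisher tests. Finally, mutation effects on tumor-cell viability are scored
from dependency screens via `D_m = |s̄_m − s̄_wt|` and
`S_dm = 2(s̄_m − s̄_wt)/(s̄_m + s̄_wt)` with a two-sample t-test
(functional ⇔ p < 0.05 and S_dm > 0.1).

A synthetic-cohort generator (log-normal TPM, proportional-hazards survival
driven by a planted co-expressed prognostic program, subtype-enriched
mutations, mutation-shifted dependency scores) makes every stage testable
with known ground truth. See `docs/methods.md` for the model details and
design choices.

## Worked example

Simulate a 300-sample cohort with 20 planted prognostic genes (hazard
ratio 3), screen it, build the network, and cluster:

```sh
memory simulate --n 300 --genes 500 --planted 20 --seed 7 --out demo/cohort
# wrote synthetic cohort (300 samples x 500 genes) to demo/cohort

memory screen --expr demo/cohort/expression.tsv --surv demo/cohort/survival.tsv \
              --permutations 100 --seed 7 --out demo/screen
# screened 500 genes: 19 GEARs at gradient size 120

memory network --tensor demo/screen/tensor.npz --gears demo/screen/gears.tsv \
               --expr demo/cohort/expression.tsv --out demo/net
# kept 1000 edges; 10 hub genes

memory classify --expr demo/cohort/expression.tsv --hubs demo/net/hubs.tsv \
                -k 3 --out demo/sub
# cluster sizes: 1: 69, 2: 140, 3: 91
```

The screen recovered 19 of the 20 planted genes (`GENE0001`–`GENE0020`)
and no null genes: saturation occurred at 120 samples (40% of the cohort),
where e.g. `GENE0002` had significance probability 0.91. All 10 hub genes
are planted-program members with mean TPM above the 10-TPM filter — e.g.
`GENE0004` with CSN degree 68 and mean 35.6 TPM. The three clusters split
the cohort by program activity (low/medium/high).

`memory run --config run.yaml` executes all stages in one configured,
manifest-producing run (`memory run --help` lists the flags; mutation and
dependency stages are skipped when their inputs are absent). Every run
writes a `manifest.json` with config, input/output sha256 checksums,
timings and diagnostics; identical inputs + seed give byte-identical
outputs.

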