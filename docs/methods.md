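# Methods

## Scan framework

The gene-interaction network is an undirected graph; edge direction, edge
type, and weights are discarded. Distance between genes is the shortest path
length in hops (all edges have unit weight, so breadth-first search gives the
same distances as Dijkstra; `truncated_distances` uses BFS for that reason).
Candidate clusters are circular windows: for each of the `N` genes, the balls
of radius `0..R`, giving `(R+1)·N` windows. Windows with identical member
sets are deduplicated keeping the first (center order, then radius)
representative; since every statistic below depends on the member set only,
deduplication cannot change the scan maximum (asserted against brute-force
enumeration in the tests).

`R` defaults to 4. The choice is justified by `coverage_fraction`: the
fraction of unordered distinct gene pairs within shortest distance ≤ 2R
(unreachable pairs count in the denominator, so coverage honestly reflects
disconnected components). On large interactomes radius 4 covers essentially
all pairs; on the 300-gene synthetic networks used here diameter 8 covers
100%.

## Locality statistic and permutation test

Affected-gene incidences are counted at the gene level: a gene counts once
per subject regardless of how many CNVs hit it (subject gene sets), and
`n1`/`n0` are the network-wide totals over cases/controls. For a window the
locality statistic is the pooled-variance two-proportion z score (the signed
CMAT form); `T` is computed only for windows with case count ≥ 1 and
non-degenerate pooled proportion, including inside permutation replicates.
One-tailed orientation: large positive `T` = case excess (rare CNVs are not
assumed protective).

The scan statistic is the maximum `T`. Ties are broken toward the smaller
member set, then the lexicographically smaller center, then the smaller
radius — deterministic, and biased toward parsimony because circular scans
tend to absorb surrounding null genes into the detected cluster.

The permutation test permutes case/control labels, preserving group sizes;
subjects carry their gene sets with them, so `n1`/`n0` are recomputed per
replicate. The p-value is `(1 + #{null maxima ≥ observed})/(1 + B)`, which is
never exactly 0 and is exactly valid under label exchangeability. If no
window has a positive case count the scan is undefined and p = 1 by
convention. The permutation engine is vectorised (replicate label masks ×
subject-gene matrix × window membership matrix), which is what makes the
replicated evaluations below tractable on one core.

Secondary clusters walk the ranked windows in descending `T`, keep a window
only if it is disjoint from everything already kept, compute its p-value
against the *same* null distribution of scan maxima (hence conservative), and
stop at the first disjoint candidate with p ≥ α (default α = 0.05).

## Disease model

Parameters, with defaults used throughout:

| parameter | meaning | default |
|---|---|---|
| `M` | causal-cluster size (genes) | scenario-specific |
| `p` | per-gene mutation (rare-CNV) probability | 1e-4 |
| `K` | disease prevalence P(D=1) | 0.01 |
| `gamma` | cluster risk ratio (carriers of ≥1 cluster mutation) | grid 1–5 |

Genes mutate independently with constant probability `p`; genotypes are 0/1
(homozygous rare genotypes are negligible at these frequencies and excluded
by construction). With `P0 = (1−p)^M`, prevalence decomposes as
`K = P(D=1|g0)·[P0 + γ(1−P0)]`, giving the baseline risk
`P(D=1|g0) = K/(P0 + γ(1−P0))`; models where `γ·P(D=1|g0) > 1` are rejected
as invalid. Bayes' rule yields the case/control-conditional distributions of
the number of mutated cluster genes, from which:

    E[case]    = γ·M·p / (P0 + γ(1−P0))
    E[control] = M·p·(1 − γ·K/(P0 + γ(1−P0))) / (1−K)

Both closed forms are cross-checked in the tests against an independent
brute-force mean of the conditional pmf. The law of total probability
`K·P(i|D=1) + (1−K)·P(i|D=0) = Binom(M,p)(i)` holds exactly and is asserted.

Simulation draws the cluster-mutation count from the conditional pmf, places
it uniformly over cluster genes, and mutates every non-cluster gene as an
independent Bernoulli(p) — outside the cluster, genotype and disease status
are independent, so the Bernoulli shortcut is mathematically identical to
drawing a count and placing it.

A note on the reference expected-count table this model reproduces: at
cluster size 776 the case values at risk ratios 4 and 5 and the control value
at 5 printed in the original table repeat/shift neighbouring columns
(e.g. case γ=4 repeats the γ=3 value 0.203 while the model gives 0.254, which
the table prints under γ=5); the model's values are reported as computed and
those three cells are excluded from the reproduction tests.

## Synthetic data

Desk-scale stand-ins for the real inputs are generated in code:

- **Network**: Barabási–Albert preferential attachment (default attachment 2),
  connected, heavy-tailed degrees like a protein-interaction network; it does
  *not* reproduce the modular/clique structure, degree correlations, or scale
  (≈13.7k genes) of a curated interactome.
- **Planted cluster**: the circular window whose size is closest to the
  target (exactly a window, so exact recovery — joint power — is attainable,
  mirroring a causal cluster that is itself a distance ball).
- **Cohorts** from the disease model above; **CNV interval calls** and
  **BED-style gene annotations** consistent with a cohort (mapping the calls
  back reproduces the cohort, used as a round-trip test); **GMT gene sets**,
  optionally enriched for a cluster.

Because mutation sites are independent within subjects and the cluster is a
perfect window, passing desk-scale tests demonstrates the statistical
machinery (validity of the permutation test, recovery behaviour, the
closed-form expectations), not performance on real interactomes, where CNVs
span multiple adjacent genes, mutation rates vary per gene, and true clusters
are not circular.

## Evaluation harness

Each simulated dataset is judged against its own permutation critical value,
the `⌈α(B+1)⌉`-th highest of its B null scan maxima (the 50th highest for
α = 0.05, B = 999); rejection requires the observed scan statistic to be
strictly larger. At γ = 1 the rejection proportion is the empirical type I
error. Joint power = rejection AND exact member-set equality with the true
cluster. Sensitivity = |detected ∩ true|/|true|; specificity =
|non-detected ∩ non-true|/|non-true| within the pathway gene universe; by
default every dataset's most likely cluster contributes (the definitions do
not condition on rejection), with an optional rejected-only mode. Grid
evaluations reuse the same per-dataset simulation and permutation random
streams at every risk ratio (common random numbers), so estimated power and
sensitivity rise monotonically with γ without being masked by simulation
noise.

Problem sizes used by the tests and the acceptance script — a 300-gene
network, a ~30-gene planted cluster, 200 cases/200 controls, per-gene
mutation probability 5e-3 (≈1.5 affected genes per subject), 100–200 datasets,
199 permutations — are the package's desk-scale study conditions; they keep
every run to seconds-to-minutes while leaving the binomial Monte-Carlo error
small relative to the acceptance bands (e.g. 2 binomial SEs of α = 0.05 at
200 datasets is ±0.031). The p-value-validity check uses 1500 null datasets
at B = 99 because the empirical level at α = 0.01 needs finer resolution.

## Numerical conventions and edge cases

- BED 0-based half-open coordinates; ≥ 1 bp overlap marks a gene affected;
  duplicate CNV records collapse; calls on chromosomes missing from the
  annotation are skipped with a warning.
- Rare-CNV filtering operates at the affected-gene frequency level (a gene is
  removed from all subjects when affected in ≥ threshold of subjects); the
  threshold 1.0 is an explicit no-op. Locus-level CNV frequency clustering is
  upstream of this package.
- Subjects with empty gene sets are retained: they inform group sizes and
  permutation labels.
- Gene identifiers are opaque case-sensitive strings; no symbol
  normalisation.
- Windows with zero case count are skipped, never assigned T = 0.
- `p`-value and critical-value conventions as above; `critical_value` raises
  when `α(B+1)` exceeds B rather than silently extrapolating.
- Fisher gene-set test: one-tailed hypergeometric via `scipy.stats
  .fisher_exact(alternative="greater")` on the affected-gene table with the
  set in place of the window; p = 1 with a warning when a group has no
  affected genes. Holm/BH via `statsmodels.stats.multitest`.

## Design choices

- The locality statistic is exposed as the single built-in statistic; the
  scan engine depends only on window member sets and per-window count sums,
  so alternative locality statistics (e.g. one-tailed Fisher mid-p, other
  rare-variant collapsing statistics) can be added by replacing the
  vectorised T computation.
- Subject-level windows ("number of subjects with ≥ 1 affected gene in Z")
  are not implemented; the gene-count approach is generally more powerful
  and is the one used here. Flexibly shaped (non-circular) windows and
  directed/weighted distances are likewise out of scope.
- The CLI is deliberately thin — every command is a few lines over the
  library API — and configuration is by flags only; each run's resolved
  configuration and seed are embedded in its output.

## Known limitations

- Permutation p-values assume label exchangeability; confounding (ancestry,
  batch) must be handled upstream or by stratified permutation, which is not
  implemented.
- The circular-window constraint biases detected clusters large around true
  non-circular clusters, reducing specificity; secondary-cluster p-values are
  conservative by construction.
- The simulator's one-variant-one-gene assumption ignores CNVs spanning
  multiple adjacent genes, which in real data induce local correlation that
  the permutation null honours but the disease model does not generate.
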