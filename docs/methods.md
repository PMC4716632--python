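# Methods

## Problem and model

A ChIA-PET experiment yields DNA–DNA interactions mediated by a bait
protein, but says nothing about the co-factor complexes that hold each loop
together. `cmnet` infers those complexes — chromatin maintainer networks
(CMNs) — by treating every interaction's connecting PPI subnetwork as a
"document" of edge tokens and clustering the corpus with a hierarchical
Dirichlet process (HDP), so that the number of CMNs, their edge
compositions, and each interaction's mixture over CMNs are all inferred
jointly.

### Corpus construction

1. **Anchor windows.** TF binding concentrates near the centre of
   ChIA-PET anchors, so peaks are intersected with ±`flank` bp around each
   anchor centre (half-open intervals, ≥ 1 bp overlap). Default
   `flank = 1500` bp, a typical enhancer size; 500–2000 bp are reasonable.
2. **Local networks.** For each interaction, every unordered TF pair
   {s ∈ anchor A, t ∈ anchor B, s ≠ t} is connected through the reference
   PPI; each reference edge is counted once per shortest path traversing
   it, summed over pairs (computed exactly via BFS path counts,
   σ_s(u)·σ_t(v) for edges on shortest s–t paths). A pair recruited on both
   anchors contributes once; pairs in different components contribute
   nothing; interactions whose bag is empty are dropped and counted. A
   `single_path` mode counts one deterministic shortest path per pair
   instead.
3. **Outlier-edge filter.** Document frequency df(e) = fraction of bags
   containing e. Edges with df > 0.80 (hub/shortest-path artefacts,
   general co-factors) or df < 0.05 (noise) are removed, strict
   inequalities on both sides; the vocabulary is re-indexed densely and
   newly empty bags dropped with a count.

### Reference PPI

Public PPI catalogues are noisy and hub-biased, so the reference network
keeps a physical edge only when (i) both proteins are on the nuclear
whitelist and (ii) the pair is co-expressed. Co-expression follows the
weighted-network recipe: w_ij = |Pearson correlation|^β with soft-threshold
power β (5 and 6 reproduce scale-free fits for the MCF7- and K562-style
cohorts that motivated the defaults); the unsigned topological overlap
TOM_ij = (Σ_u w_iu w_uj + w_ij)/(min(k_i,k_j) + 1 − w_ij) summarises
neighbourhood sharing; nodes whose TOM connectivity (row sum) falls below
the median are removed (ties retained; the quantile is configurable, and a
flag switches connectivity to raw adjacency row sums); finally the
adjacency is binarised at `adjacency_cutoff` (default 0.5 — the source
method leaves the binarisation rule open, so it is exposed as a
parameter). Nodes are filtered before binarisation. Genes with constant
expression are rejected by name; fewer than 3 samples is an error.

### HDP and sampler

Three layers: a symmetric Dirichlet base measure H over the V vocabulary
edges (concentration η), the global stick-breaking measure G₀ over CMNs
(concentration γ), and per-interaction measures G_j (concentration α).
Collapsed direct-assignment Gibbs sampling reassigns each token with

    p(z_jn = k | rest) ∝ (n_jk + α g_k) · (n_ke + η)/(n_k + V η)

for active CMNs and ∝ α·g_new/V for a new one; G₀ sticks are resampled
from their Dirichlet posterior given auxiliary table counts (Antoniak
draws). The direct-assignment scheme with auxiliary-variable stick
resampling is the standard sampler implied by the described behaviour
(gradual growth of K); it is the only sampler exposed. Burn-in follows the
original recipe: during the first sweep the sticks are resampled after
every 10 documents, afterwards once per sweep; `burnin_sweeps` is exposed
because the original burn-in length is data-dependent and not fully
specified. All tokens start in one CMN (deterministic initialisation; K
grows as sampling proceeds); empty CMNs are removed and indices compacted;
token multiplicities are expanded to independent tokens (bag-of-words
semantics); categorical draws use inverse-CDF on a single uniform; the RNG
is seeded per fit, so runs are bit-reproducible given (corpus, seed). η, γ
and α are fixed user knobs, never resampled. The per-token loop is
numba-compiled; `max_cmns` (default 512) bounds the working arrays and
raises if exceeded.

Parameter semantics (defaults η = 0.01, γ = α = 1, 1000 sweeps):
smaller η concentrates each CMN on few edges (sparser edge-per-CMN
distributions) and admits more CMNs; γ > 1 spreads G₀ mass so more CMNs
survive; α controls how many CMNs a single interaction can draw from.
Estimators from the final state: β_k(e) = (n_ke + η)/(n_k + V η) and
θ_j(k) = (n_jk + α g_k)/(size_j + α(1 − g_new)), rows renormalised.
Sparsity diagnostics report the fraction of β and θ cells below a
threshold (default 1e-3), K, and mean CMNs per interaction.

A note on degenerate corpora: for a corpus of identical single-token bags
the single-CMN configuration is the posterior mode, but the *sampled* state
retains transient small CMNs contributed by the process prior (each
single-token document resamples its assignment without within-document
reinforcement), so the sampler settles at a small K with one dominant CMN
rather than exactly K = 1. The test suite asserts dominance accordingly.

### Reporting and validation

* **Truncation.** A CMN is reported as the shortest prefix of its edges
  (sorted by β descending, ties by token id) whose cumulative probability
  reaches `coverage`. 40–50 % balances coverage against background-PPI
  degree bias: raising it pulls in more hub edges, which the
  `degree_bias` diagnostic (Pearson correlation of CMN-internal vs
  reference degrees, rank correlation optional) makes visible.
* **Similarity.** sim(p,q) = 1 − JS(p,q) with base-2 logarithms, so the
  scale is exactly [0, 1]; computed on full β vectors (the divergence
  formula ranges over the whole corpus vocabulary).
* **Permutation test.** Peaks are re-placed uniformly on their chromosome
  (lengths preserved; chromosome sizes default to the largest observed
  coordinate) and anchor pairings permuted; the corpus is rebuilt against
  the same reference PPI and the HDP re-fit (usually with reduced sweeps).
  Each observed CMN is compared to every null CMN by the edge-overlap
  hypergeometric test (population E = M(M−1)/2 over the union node set);
  the per-iteration statistic is the best (minimum) overlap p. The
  original flagging rule is verbal, not a formula; the concrete reading
  implemented: a CMN is non-significant when the fraction of iterations
  with a good null reconstruction (best p < 0.05) exceeds a configurable
  α (default 0.05). Empirical p-values use the (r+1)/(n+1) estimator and
  are BH-corrected. The printed source formula for the overlap test has a
  middle term inconsistent with a hypergeometric (population not reduced
  by the first network's size); the standard hypergeometric is
  implemented, matching the test's stated identity.
* **OP test.** For a held-out TF, OP = fraction of claimed interactions
  whose anchor windows contain its signal; the null redraws equally many
  interactions without replacement (default 500 draws).
* **Multi-class ROC.** Planted labels are mapped through
  f(k) = argmax_x sim(planted_k, inferred_x) (ties to the lowest index)
  and scored one-vs-rest by θ columns, macro-averaged; a Hand–Till variant
  is available. Classes absent after mapping are excluded.
* All correction uses Benjamini–Hochberg step-up (the original used an
  external package for the permutation p-values; BH is applied uniformly
  here for consistency with the literature-mining analysis).

## Synthetic data

Two generators make every stage testable without external downloads.

**Planted-CMN corpora** follow the generative model: K CMN edge
distributions are symmetric Dirichlet draws (disjoint-support mode gives
each CMN an exclusive vocabulary block — a sharp, fully checkable regime
used instead of refitting real data); per interaction, mixing proportions
~ Dirichlet(`mixing_alpha`, default 1 = uniform simplex, as the original
profile-sampling distribution is unstated), a network size uniform on
[10, 200] edges inclusive, and each edge token drawn through its CMN
indicator. `dominant_only` samples every edge from the argmax-proportion
CMN, giving exact labels. `subsample_corpus` emulates reduced library
complexity by keeping ceil(fraction·n) bags.

**Genomic fixtures** emulate the raw inputs: uniform anchors on one
synthetic chromosome, per-TF peaks within a configurable offset of anchor
centres with hit probability 0.6 by default, a Watts–Strogatz small-world
(or planted-module) PPI over TFs plus bystander proteins, expression with
contiguous correlated blocks aligned to the PPI lattice, and a nuclear
whitelist. What these fixtures do **not** emulate: read-level noise, peak
width/strength distributions, genomic covariates (GC, mappability),
correlated TF co-binding, or realistic PPI degree distributions — so
passing tests demonstrate algorithmic correctness and statistical
behaviour under the model's own assumptions, not performance on real
libraries.

## Problem sizes used in the checks

The automated checks run, per seed: planted-CMN recovery with 5
disjoint-support CMNs over a 300-edge vocabulary, 300 interactions of
10–200 edges, η = 0.01, γ = α = 1, 500 sweeps (5 seeds); corpus-size
trends with 11 overlapping planted CMNs (Dirichlet 0.1), dominant-only
bags of 2–10 edges at corpus sizes 100/300/600 — network sizes are scaled
down together with corpus sizes so that the smallest corpus is genuinely
data-poor and the accuracy-vs-size trend is measurable rather than
saturated; hyperparameter trends (γ 0.5 vs 3, η 0.01 vs 1) on a 150-bag
corpus at 200 sweeps, 5 seeds each. `scripts/acceptance.py` uses the
recovery conditions above plus a 60-interaction genomic fixture whose
held-out-TF signal is synthesised where ≥ 2 of its PPI partners co-bind
(a co-factor recruitment model), giving the OP test a planted association
to detect.

## Known limitations

* Real protein/gene namespaces must be reconciled by the caller; no
  identifier mapping is bundled.
* The permutation test refits the HDP per iteration and is the dominant
  cost at scale; reduced sweeps for null fits are supported and logged.
* Shortest-path counting is exact but unweighted; confidence-weighted
  PPIs are out of scope.
* Inferred CMNs can only contain proteins present in the reference PPI,
  and degree-1 proteins rarely appear on shortest paths — the reference
  construction thresholds trade candidate recall against hub noise.
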