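# Methods

This note documents the statistical model behind `netmark`, the defaults
and why they are what they are, the numerical choices, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Differential statistics

For gene *i* with positive-group mean x̄⁺, negative-group mean x̄⁻ and
pooled standard error of the difference se_i, the moderated statistic is

    d_i = (x̄⁺ − x̄⁻) / (se_i + s0),

where the fudge factor s0 is the median of the per-gene standard errors —
it keeps near-constant genes from dominating the ranking. q-values come
from group-label permutations (default 200; all distinct assignments are
enumerated when fewer exist): for a threshold t, the estimated false
discovery rate is the median permuted count of |d| ≥ t divided by the
observed count, and q_i is the smallest FDR over thresholds at or below
|d_i| (a suffix minimum over the descending |d| order, so q is monotone in
|d|; tied |d| values share one q). q is clipped to (1e−16, 1]; the floor
exists because the weighting takes log₁₀ q, and finite permutation sets
routinely produce estimated FDRs of exactly zero. Permutation masks attach
to sorted sample identities, so reordering input columns cannot change q.
A Welch-t/Benjamini–Hochberg alternative with the same output contract is
available for sensitivity analysis (`welch_bh_qvalues`).

## Network weighting

Node significance is the log-scale normalisation
s_i = log₁₀ q_i / log₁₀ q_min, where q_min is the smallest q among network
genes: s = 1 at the most significant gene, 0 at q = 1, monotone in between.
Edge weight is the endpoint mean w_ij = (s_i + s_j)/2 ∈ [0, 1]; a geometric
mean variant is provided (`geometric_edge_weight`) — it damps the
"leakage" of significance onto edges with one insignificant endpoint, at
the cost of under-weighting genuinely mixed edges. Both are pure functions
of (q_i, q_j, q_min) and interchangeable without touching the search.

## Module search

Seeds are all network triangles, ranked by mean edge weight (ties broken
by sorted gene names, making the order platform-independent). Growth is
greedy: among the neighbours of the current set S, add the one with the
largest positive gain, stop when none improves the measure or a size cap
(default 50, a runaway guard) is reached.

The default gain is the increase of the size-normalised local modularity

    Q_α(S) = W_in(S) / |S|^α,

where W_in is the internal edge weight. At α = 1 the greedy ascends
exactly the module score reported downstream (W_in/|S|), and acceptance of
a candidate v reduces to a transparent rule: v joins while its connection
k_vS exceeds roughly α/|S| times the module's internal weight — the
candidate must bring at least (α times) the module's per-gene average.
Larger α therefore yields tighter modules ("resolution"); as α → 0 any
positive connection is accepted and growth runs to the cap.

A configuration-model alternative,
gain = k_vS/W_T − α·k_v·k_S/W_T² (W_T the total node strength, k_v the
candidate's strength, k_S the summed strength of S), is implemented and
fully tested. It is *not* the default because with significance-derived
weights its strength-proportional null is systematically blind to
weakly-connected background genes: acceptance reduces to
k_vS/k_v > α·k_S/W_T, and a background neighbour whose single edge into the
module carries leaked significance beats genuine members on that ratio at
every α — in benchmarks it either freezes seeds or accretes background to
the size cap, never recovering a planted module. It remains appropriate
for networks whose weights measure interaction strength.

Redundancy is controlled at the source: a seed whose three genes are
already covered by accepted modules is skipped, and a freshly grown module
overlapping an accepted one above 0.5 (overlap = shared/min; the same
functional used in merging) is discarded in favour of the earlier,
better-seeded module. Without this, the dense triangle coverage of a
significant region produces a hundred-plus near-duplicates whose later
fixpoint merge snowballs into one giant module. A `seed_rank_limit`
(pipeline default 200) caps the search at the strongest-ranked seeds —
low-weight seeds contribute only runaway background modules and runtime.

The greedy loop is an exact incremental implementation of the declared
gain (a compiled kernel for the default strategy); its equivalence to a
brute-force oracle that recomputes every candidate's gain from the
definition at every step is asserted over hundreds of random graphs.

## Significance

The null model permutes gene q-values uniformly across the network and
recomputes edge weights; topology, every degree, the q multiset and hence
the normalisation anchor q_min are all preserved. The full search runs on
each of (default) 100 permuted networks. A module's empirical p-value is
the fraction of null module scores at least as large as its own, ties
counting against the module; the cutoff is 0.05.

By default the null pool is *rank-matched*: with k observed modules, each
permutation contributes its top-k scores. The observed list is the
redundancy-filtered cream of its landscape; pooling every null module
regardless of rank dilutes the null with each permutation's weakest
modules and inflates observed pass rates several-fold in no-signal data
(measured). Rank-matching restores observed/null exchangeability —
measured pass fractions on null cohorts are ~0–8% at cutoff 0.05 — and
coincides with the plain pooled fraction when list compositions match;
plain pooling remains available (`rank_matched=False`).

## Merging

Overlap between modules is c/min(a, b) — shared genes relative to the
smaller module, so a nested module always merges — with Dice 2c/(a+b) as a
configurable alternative. Merging unions the highest-overlap pair first
and iterates to a fixpoint: no output pair overlaps above the threshold
(default 0.5). Cross-analyte merges are tagged `merged`; merged modules'
scores and p-values are cleared, as they are no longer comparable to
single-network nulls.

## Classification

Gene values are z-scored gene-wise across **all** patients (sample sd,
n−1); this mirrors the global normalisation of the activity framework but
technically lets test samples influence per-gene scale — a documented
leak, switchable to training-only (`zscore_basis="train"`). A module's
activity in a sample is Σz/√n over its member genes present in the
analyte. In combined mode every module yields two features (expression and
methylation activity); single-analyte modes keep the native analyte.

The classifier is a soft-margin SVM with the inhomogeneous quadratic
kernel (x·x′ + 1)², C = 1. Features are standardised on the training rows
inside the classifier: activity columns differ by an order of magnitude in
scale and would otherwise dominate the polynomial kernel. Recursive
feature elimination ranks features by the change in the SVM's dual margin
term αᵀHα when the feature is masked from the support vectors (for the
linear kernel, |w|), removes the lowest-ranked feature per iteration, and
returns the subset with the best cross-validated accuracy (ties favour
fewer features). The selection CV is repeated stratified k-fold (k = 5 or
the smallest class count, 8 repeats, fixed seed); leave-one-out is
available but its accuracy lattice of 1/n steps produces long ties that
collapse the selected subset.

Evaluation is paired leave-one-out cross-validation: the positives are a
fixed held-out panel (default 21, the longest-surviving held-out
patients); per repeat, an equal number of negatives is drawn from the
held-out pool and paired 1:1 with the positives by a shuffled index; each
fold trains on the remaining pairs and tests the held-out pair. The
reported accuracy is the mean ± sd over (default) 100 repeats. All marker
sets are evaluated on identical panels (one shared seed), so comparisons
between them are paired. Classifiers are retrained within every fold.

The alpha sweep (`pipeline.alpha_sweep`) runs the full pipeline per α and
selects the α with the best combined-marker accuracy (ties → smaller α).
The pipeline default α = 0.8 was fixed this way on the reference synthetic
conditions; the library-level `SearchConfig` default stays at the neutral
α = 1.0.

## Synthetic cohorts

`SyntheticCohortSpec` defaults define the reference benchmark: 1,500 genes
in a preferential-attachment network of ≈6,000 interactions
(duplication–divergence available), six planted modules of 6–12 genes
wired as a spanning tree plus extra internal edges (≈1.5× size), a group
mean-shift of 2 within-group sd in both analytes, 20+20 patients, unit
noise, and a weak negative expression–methylation coupling (−0.1) through
a shared per-gene latent factor. Survival times are drawn so the groups
fall cleanly beyond the 2.5/0.5-year extreme-selection thresholds.

Heterogeneity options: `penetrance` activates each planted module in a
given positive patient with fixed probability; `subtype_probs` structures
activation into expression-/methylation-/dual-responder subtypes
(emulating analyte-defined tumor subtypes such as methylator phenotypes);
`survival_activity_link` ties survival to pathway burden. The split-analyte
classification scenario (`split_analyte_spec`) uses subtypes
0.35/0.35/0.30 with per-module activation 0.9 and effect 4 sd in a
42-positive / 60-negative cohort: a single-analyte classifier is blind to
roughly a third of the positives while per-gene discovery power on the
21+21 training extremes remains comfortable (d ≈ 3). An earlier design
with independent per-module activation was discarded: it makes the ideal
decision rule a six-way OR that no quadratic SVM can realise from 40
training samples, so the combined classifier's advantage existed in the
Bayes limit but not in practice; subtype-structured activation is both
more realistic and learnable.

What the generator does **not** emulate: platform noise models and
bounded beta-value distributions; edge-wise methylation correlation
between interacting genes (each gene's profiles are independent of its
neighbours' unless planted together — the connected-pair diagnostic
therefore reports enrichment only on data that actually carries it);
probe-level structure, missingness patterns, batch effects, and censoring.
Passing benchmarks on these cohorts shows the machinery is correct and
calibrated under the stated model, not that real-cohort accuracy will
match.

## Numerical and determinism choices

- q floor 1e−16; permutation-FDR clipped to [floor, 1].
- All ties (seed ranking, neighbour choice, extreme selection, merge
  order) break lexicographically, so runs are platform-independent.
- Every stochastic stage draws its seed from the single master seed in a
  fixed order; the JSON run report contains no wall-clock fields and is
  byte-identical across runs of the same configuration.
- Constant gene profiles: correlation recorded as 0 with a flag; z-scores
  set to 0 with a flag — genome-wide summaries never abort.
- Empirical p-values of 0 are stored as 0.0 (the defined fraction); with N
  null scores they should be read as "< 1/N".

## Benchmark problem sizes

The test suite runs the heavy benchmarks at reduced size (3 recovery
cohorts / 6 null cohorts at 40 permutations; 4 classification cohorts at
15 permutations and 10 repeats) so the default suite completes in minutes;
`scripts/acceptance.py` uses 10 recovery and 20 null cohorts at the full
100 permutations and 20 classification cohorts (25 permutations, 20
repeats), with the label-free classifier check averaged over 6 feature
draws × 100 repeats. Thresholds are identical in both.

## Known limitations

- The all-sample z-score basis (default, matching the activity framework)
  is a mild information leak; use `zscore_basis="train"` for strict
  separation.
- The pooled-vs-rank-matched null choice matters only in near-degenerate
  significance landscapes (no signal, one dominant gene); with real signal
  they agree closely.
- Greedy growth is order-dependent by construction; the redundancy filter
  keeps the best-seeded representative rather than an optimal cover.
- Merging is not order-independent in pathological overlap patterns; the
  highest-overlap-first rule makes it deterministic.
- Two-class, unpaired designs only; no block permutation, no survival
  regression, no multiple-testing correction across modules beyond the
  empirical cutoff.
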