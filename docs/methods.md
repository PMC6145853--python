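# Methods

## Model

A cohort of P subject-condition profiles is represented as a hybrid matrix
**X** (P × L), each row the concatenation of a functional connectome's
upper-triangle edges (L_FC = n(n−1)/2 Pearson correlations in [−1, 1]) and
the masked structural-correlation edges (L_SC values in [−1, 1]). The
working assumption is the linear ICA generative model

    X ≈ A · T + E,

with K ≪ P statistically independent, non-Gaussian edge-space sources
(*hybrid traits*, rows of T) mixed by per-profile weights A, plus noise E.
FastICA cannot order or scale its sources, so traits are unit-normalized
(scale lives in the weights) and all matching is by absolute Pearson
correlation with explicit sign alignment.

Bringing SC into the same range as FC uses the *structural correlation*:
for each structurally connected pair (i, j), the Pearson correlation of
rows i and j of the log-compressed SC (`w → log10(1+w)`, zeros fixed, so
typical streamline counts land in ≈ [0, 5]). By default the full rows enter
the correlation (including the zero diagonal and the mutual entries
(i,i),(i,j)); `exclude_pair_entries=True` drops columns i and j first, the
stricter matching-index convention. The two differ by O(1/n) for connected
pairs; the default is the more literal reading of the transform, the option
is exposed because the choice is genuinely open. Pairs where any involved
row is constant have no defined correlation and are a hard error rather
than silent NaNs.

The structural correlation matrix is dense, so it is restricted to the
population common-edge mask (pairs nonzero in *every* subject's SC,
intersection semantics). Unmasked pairs are structurally absent — not zero
observations — which is why SC-side percentiles and joint masks are always
computed over masked edges only.

## Decomposition and robustness

PCA reconstruction at a cumulative explained-variance target (default
0.90) denoises X while keeping its scale: columns are mean-centered, the
smallest k leading components reaching the target are kept, and the means
re-added. ICA then consumes the reconstructed matrix, transposed, so that
sources live in edge space; symmetric (parallel) fixed-point iteration with
the log-cosh (tanh) contrast, tol 1e−4, max 500 iterations.

Each of `n_runs` (default 100) runs draws a balanced bootstrap cohort —
`n_per_condition` (default 10) distinct subjects per condition, no subject
repeated across conditions within a run — via randomized greedy assignment
with an exact bipartite-matching fallback, then fits ICA with a run-specific
seed spawned deterministically from the master seed.

**Convergence policy.** A run that exhausts `max_iter` is flagged, counted
in the diagnostics, but *kept* for clustering by default
(`discard_nonconverged=False`). The reason is structural: when the model
order M exceeds the number of genuinely non-Gaussian sources, the surplus
components span an (approximately) Gaussian subspace in which the
fixed-point update direction vanishes in expectation, so the *run-level*
criterion can essentially never be met at any tolerance — while the
informative components stabilize within a few iterations. Cross-run
replication, not the per-run flag, is the stability criterion here; truly
unstable components simply fail to cluster. (Purely Gaussian sources are
unidentifiable by ICA in principle; no claim is made about them.)

**Robustness clustering** is greedy: pool all components, repeatedly seed a
cluster with the component matched (|r| ≥ `r_thresh`, default 0.5) in the
most other runs, let every run contribute at most its best-matching
component, sign-align members to the seed, average them (the stored trait
is the exact mean of its sign-aligned members), and average weights per
profile over the member runs that actually sampled that profile — profiles
never sampled get a missing weight, not zero. Clusters below `freq_thresh`
(default 0.50 of usable runs) are dropped; output is sorted by frequency.
Ties in seed selection break to the first-pooled component, making the
procedure deterministic.

**Model order.** M has no gold standard. `select_model_order` scans a
range, scoring each M by the number of robust traits whose weight ICC
reaches a threshold (default 0.5), breaking ties by higher mean ICC of
robust traits, then smaller M; an all-zero scan returns the smallest
candidate with a warning.

## Task sensitivity

One-way random-effects intraclass correlation with conditions as groups:
ICC = (MSB − MSW)/(MSB + (k₀ − 1)·MSW), k₀ = (N − Σkᵢ²/N)/(g − 1) (the
balanced-design k when group sizes are equal). ICC is invariant to shifting
and positively rescaling all weights, is ≤ 1, and can be negative (groups
more variable inside than between). Requirements — at least two groups
with two or more finite values, not all values identical — are enforced as
errors. Which of the classical ICC case conventions a given study used is
often ambiguous; the one-way case 1 form is the natural fit when
"conditions are raters", and the sensitivity flag threshold (default 0.5)
is configurable rather than hard-wired.

## Null model

Degree-preserving randomization rewires two disjoint edges
(a,b),(c,d) → (a,d),(c,b) only when all four endpoints are distinct and
neither target edge exists; weights travel with their edge. n, |E|, the
degree sequence and the weight multiset are conserved exactly. Swaps are
counted as *accepted* rewires, with an attempt cap of 100× the request for
graphs too constrained to mix (a triangle admits no legal swap and returns
unchanged, flagged). The dissimilarity curve (1 − Jaccard of edge sets vs
accepted swaps, averaged over replicate seeds) is non-decreasing in
expectation and justifies a swap budget by its plateau; the default budget
is 50,000 swaps.

## Trait mapping

Percentiles use numpy's linear-interpolation convention and strict
exteriority (value < P_lo or > P_hi), so values 1..100 at (5, 95) select
exactly the bottom and top five. The joint FC-SC mask is the elementwise
AND of the FC-block and SC-block extreme masks mapped to node pairs —
reading "the product of extreme values" as a product of binary indicators —
and is invariant to a global sign flip of the trait when the bounds are
symmetric. Per-block (rather than whole-vector) percentiles are used
because the two blocks have different dispersions and the SC block is
defined only on the mask. Nodal strength is the masked-edge count per node
and satisfies Σ strength = 2 × |mask|.

## Synthetic cohorts

The generator mirrors the standard study design: a cross-sectional cohort
of 8 conditions × 10 distinct subjects (80 profiles), K = 5 planted traits
of which 2 are task-sensitive. Planted trait vectors are RSN-block
structured — positive within a home network, negative between the home and
a partner network, plus jitter — orthogonalized per block and scaled to a
common RMS amplitude (`trait_scale`, default 0.1, safely inside the FC
range after mixing). Weights are Gaussian (`weight_sd` 0.12); sensitive
traits get per-condition means spread over `condition_shift` = 2 standard
deviations (a permuted linear ramp), which puts their population ICC near
0.6–0.7 while insensitive traits sit near 0 — the regime the method is
meant to discriminate. Edge noise is i.i.d. normal with sd = 0.2 ×
`trait_scale`. Under these defaults the 90%-variance PCA order lands around
40 of 80 possible components, i.e. the denoising step is genuinely active.

Level B emits raw connectomes: FCs de-vectorize the hybrid FC rows; SCs
share a stochastic-block core (within-RSN density 0.6, between 0.12, so
the common-edge mask ≈ 18% of pairs and equals the core exactly, since
per-subject extra edges almost surely never coincide across the whole
cohort), log-normal weights, and per-subject log-weight modulation of each
trait's structural block by that subject's weight (`sc_coupling` 0.5 in
log10 units per unit weight). The row-correlation transform is not
invertible, so level B guarantees qualitative recovery (the FC halves match
planted traits at |r| ≳ 0.95; SC halves reproduce the block pattern, not
exact values). Setting `randomize_core_swaps` rebuilds the same cohort on a
degree-preserved rewiring of the core with FC matrices bit-identical —
a matched pair isolating the contribution of structural topology.

What the generator does *not* emulate: spatial embedding and
distance-dependent connectivity, heteroscedastic or spatially correlated
measurement noise, subject-specific parcellation differences, and any
biophysics of the BOLD signal. Passing tests therefore demonstrate the
correctness and sensitivity of the *machinery* under the stated generative
model, not performance on real imaging data.

## Problem sizes and determinism

Synthetic validation uses 64-node (default) and 32/24-node (reduced)
cohorts so that complete multi-seed experiments — e.g. 20 master seeds of
the full 20-run decomposition, or 100 replicates of the ICC discrimination
— run in minutes on one CPU; the quantities being checked (recovery
correlations, ICC separation, mask counts) are scale-free or reported with
their problem size. All randomness flows from a master seed through
`numpy.random.SeedSequence` spawning, per-run seeds are recorded in every
report, and reruns with the same seed are bit-identical.

## Known limitations

- The greedy one-member-per-run clustering is order-dependent in
  pathological near-threshold configurations; it is deliberately simple and
  deterministic rather than a full similarity-matrix (ICASSO-style)
  clustering.
- Weight recovery for a profile is undefined if no member run of a trait
  sampled it (NaN, dropped from ICC with the group-size guard).
- Alternative FC/SC range normalizations (absolute value, max-division,
  L1/L2 norms) are out of scope; the structural-correlation route is the
  one implemented.
- The ICC is descriptive; no permutation p-values or multi-way designs.
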