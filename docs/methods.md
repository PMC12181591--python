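# Methods

This note documents the models, conventions and numerical choices behind
`cogconnectome`, and what the synthetic-data validation does and does not
demonstrate.

## Synthetic cohorts

The generator draws each of the six age × reserve cells from a
multivariate normal over the 47 battery variables. Gaussian data are the
natural generative family here: the downstream pipeline consists of
cohort z-scoring and Pearson correlation, both of which are exactly
parameterized by the first two moments, so any covariance regime the
analysis can distinguish is representable.

The planted correlation matrix is block-constant over the five cognitive
modules: `r_intra` on same-module pairs, `r_inter` on cross-module pairs,
1 on the diagonal. Per-pair structure beyond that is deliberately not
modelled (a full-matrix override hook exists for callers that need it);
block-constant correlations already span the qualitative regimes of
interest — modular (r_inter ≪ r_intra), dedifferentiated
(r_inter ≈ r_intra) and globally weakened (both small). The constructor
verifies positive semidefiniteness (smallest eigenvalue ≥ −1e−10) and
rejects otherwise, naming the offending group; eigenvalue clipping is
available but only when explicitly enabled.

Baseline levels are `r_intra = 0.45`, `r_inter = 0.15` — values in the
range typically seen for correlations among related neuropsychological
scores, giving connectomes that are connected at 20% density and clearly
modular. Variables in the procedural-memory and processing-speed modules
are emitted with flipped sign (raw timing-like scales, lower = better), so
the preprocessing inversion step is exercised end-to-end. Demographics are
drawn independently within each cell's band: ages uniform on the cell's
closed interval, WAIS-III Information uniform on 16–26 (high reserve) or
4–15 (low), MMSE 24–30, FAQ 0–5, BDRS subscales 0–1 in half-point steps —
i.e. every simulated participant passes the eligibility screen unless the
caller injects violations.

Three named scenarios drive the validation suite:

* **null** — all six cells share identical parameters (exchangeability
  holds; used for type-I-error calibration);
* **dedifferentiation** — one cell (late middle age, low reserve) has
  `r_inter` raised to 93% of `r_intra` (planted loss of module
  specificity);
* **stable_reserve** — the three high-reserve cells share one regime; the
  low-reserve cells drift with age: dedifferentiated at late middle age
  (0.55/0.45), globally weakened in the elderly (0.25/0.08), plus module
  mean deficits (−0.4, −0.8 z on all modules except procedural memory),
  which also plants the age × reserve MANOVA interaction.

What passing tests on these cohorts shows: the pipeline's inferential
machinery is calibrated (null) and sensitive (planted effects) under the
model it assumes. What they do not show: robustness to features of real
cognitive data the generator omits — skewed or discretized raw scores,
floor/ceiling effects, missingness, per-pair correlation structure, and
demographic confounding between reserve, sex and education.

## Preprocessing conventions

* z-scores use the whole included cohort (not per group) and the sample-SD
  convention (`ddof=1`); `ddof=0` is available, the difference is in the
  third decimal at cohort sizes of a few hundred.
* z-scoring happens after the eligibility filter and before
  stratification.
* The reserve split threshold defaults to the cohort median of the
  WAIS-III Information score (15 in the reference cohort, 15.5 in
  symmetric synthetic cohorts); a fixed integer threshold can be passed.
  Scores strictly above the threshold are "high".
* Age bins are closed integer intervals 37–50 / 51–64 / 65–78;
  non-integer ages are floored; out-of-range ages are an error listing
  the offending ids.
* Eligibility exclusions record the first failing criterion in the fixed
  order MMSE, FAQ, BDRS, then optional boolean screen columns
  (`mci_free`, `right_handed`, `mri_clear`, `no_exclusionary_condition`)
  which are AND-ed in when present — the package makes no clinical
  judgement itself.

## Connectome construction and thresholding

Negative correlations are *removed* (set to zero / absent), not taken in
absolute value. Density is defined over all `n(n−1)/2` node pairs. The
edge count at density `d` uses round-half-away-from-zero; ties in weight
are broken by ascending node-pair label order, giving a deterministic
total order and hence a *nested* density stack (the graph at density d is
a subgraph of every denser level). When a connectome has fewer positive
correlations than the target edge count, all positive edges are kept and
the realized density is logged.

The 20–60% sweep in 1% steps is the default analysis window;
`select_density_range` can recompute it for a new cohort as the smallest
density whose pooled-cohort graph is connected up to the largest density
with σ ≥ 1.

## Graph measures

All binary measures operate on the thresholded graphs; network strength is
the only weighted measure (mean nodal sum of correlation weights).

* **Global efficiency**: mean of 1/d over ordered pairs; unreachable pairs
  contribute 0, so the measure is defined on disconnected graphs.
* **Local efficiency**: mean over nodes of the global efficiency of the
  neighbour-induced subgraph; nodes of degree < 2 contribute 0 (same
  convention for the clustering coefficient).
* **Characteristic path length**: mean over *reachable* ordered pairs
  (efficiency-style exclusion); the number of excluded pairs is logged.
  This choice matters only below the connectivity bound of the sweep.
* **Modularity**: Newman's spectral method — recursive bisection along the
  leading eigenvector of the generalized modularity matrix, each split
  refined by Kernighan–Lin-style single-node moves (up to 15 sweeps),
  stopping when no split increases Q. Eigendecompositions use dense
  symmetric solvers, so results are deterministic; the `seed` argument is
  accepted for interface stability. Tests check the returned partition
  against exhaustive enumeration on small graphs and against igraph's
  leading-eigenvector implementation.
* **Small-worldness**: σ = (C/C_rand)/(L/L_rand) with reference values
  averaged over an ensemble of degree-preserving double-edge-swap
  randomizations (Maslov–Sneppen; 10·|E| attempted swaps per reference,
  invalid proposals skipped). Ensemble size defaults to 50 for standalone
  curves and 10 inside permutation loops (recorded in result metadata).
  Graphs that admit no swap (e.g. complete graphs) reproduce themselves,
  giving σ = 1 exactly. Rewiring randomness uses an inline xorshift64*
  stream seeded from the caller's seed — deterministic across platforms.

Hot paths (BFS over the nested stack, rewiring ensembles) are numba
kernels using per-node uint64 neighbour bitsets, which restricts those
fast paths to ≤ 64 nodes; larger graphs fall back to generic kernels.

## Permutation comparison

The exchangeable unit is the participant: each permutation pools both
groups' rows, re-splits at the original sizes, rebuilds both connectomes
and recomputes the measure at every density. Two-tailed p-values use the
add-one convention `p = (1 + #{|Δperm| ≥ |Δobs|})/(1 + nperm)`, which never
returns 0. The pooled rows are put in a canonical sort order and the
smaller group size is drawn first, so swapping the group labels negates
the observed difference but leaves the p-values exactly unchanged.

A density-resolved measure is *stable significant* when p < α (default
0.05) at ≥ 10 of the 41 grid densities. Strength is density-free and gets
a single p-value; the stability rule does not apply to it. No correction
across the 45 tests of the full design is applied by default, matching
the stability-rule-only approach; per-comparison seeds derive from the
master seed via `SeedSequence(master, spawn_key=(comparison, measure))`,
so extending the design never changes existing results.

Default permutation counts are 1000 (100 for σ). The simulation-based
validation runs at reduced, stated scales chosen to keep a full check
practical on one CPU: type-I calibration at 40/group, 500 permutations,
200 replicate cohorts (the add-one test at nperm = 500 has achievable
level 25/501 ≈ 0.0499); planted-effect power at 50/group with 200
(modularity) / 100 (σ) permutations over 20 replicates; the acceptance
script uses 200/200/100/100/50 permutations for the five measures in its
nine-contrast sweep. p-value resolution at these counts (≥ 1/501) is far
below the 0.05 threshold the stability rule consumes.

## Cohort statistics

The MANOVA enters age (3 levels) and reserve (2 levels) as between-subject
factors with the five module composites as responses and reports Wilks' Λ
with Rao's F (numerator df = 10 for the interaction), computed via
statsmodels. With unbalanced cells the interaction term is identical under
type-II and type-III sums of squares; follow-up per-module ANOVAs use
type II (switchable). With a single response the routine reduces exactly
to the univariate interaction F (Λ = SSE/(SSE+SSH)). Canonical
discriminant functions come from the generalized eigenproblem
`H v = λ E v` on the interaction's hypothesis and error matrices; the
first function's sign is fixed so that positive values correlate with
higher overall composite performance. A sensitivity entry point adds sex
and tests the three-way interaction. Descriptives report per-cell n,
% women, mean (SD) of age, MMSE, WAIS and composites, Spearman ρ for
MMSE–age and education–WAIS, and a χ² (no continuity correction) of sex ×
group.

## Known limitations

* Group-level connectomes only; there is no individual-level cognitive
  connectome in this framework, so reserve enters as a dichotomy rather
  than a continuous moderator.
* The Gaussian generator cannot express distributional features of raw
  neuropsychological scores (see above); conclusions about calibration on
  real data require the real data.
* The spectral modularity optimizer is a deterministic heuristic; on small
  graphs it occasionally sits a few hundredths below the exhaustive
  optimum (bounded in tests), which is immaterial for group *differences*
  computed with the same algorithm on both sides.
* σ estimates carry ensemble noise; inside permutation tests this noise is
  part of the randomization and is reflected in the permutation null.
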