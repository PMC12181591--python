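# cogconnectome

Group-level **cognitive connectome** analysis: correlation networks built
over a neuropsychological test battery, graph-theoretical measures across a
density sweep, and permutation-based comparison of age × cognitive-reserve
groups.

## The problem

During ageing, cognitive functions decline at different rates, and
cognitive reserve — an individual's capacity to withstand age-related
decline, here proxied by the WAIS-III Information (crystallized
intelligence) score — modulates that decline. One way to study the joint
organization of cognition is to treat the cognitive test battery itself as
a network: nodes are the 47 cognitive variables of the battery, and edges
are Pearson correlations of those variables across the participants of a
group. Comparing the topology of these *cognitive connectomes* between
groups (three age bins × two reserve levels) reveals whether reserve
stabilizes the covariance structure of cognition across age.

`cogconnectome` implements that analysis as a reusable, tested pipeline,
together with a synthetic cohort generator with planted modular covariance
so every stage can be validated without access to clinical data.

## Method summary

1. **Eligibility screen** — MMSE ≥ 24, FAQ < 6, BDRS total < 4 (with the
   personality-subscale exception: total ≥ 4 tolerated when ≥ 70% of it
   comes from the "changes in personality, interests and drive" subscale
   and the other two subscales are each ≤ 1.5).
2. **Preprocessing** — all 47 variables z-scored with whole-cohort mean/SD;
   procedural-memory and processing-speed variables sign-inverted so higher
   z is always better; module composites as mean z per module; participants
   stratified into EMA (37–50), LMA (51–64), ELD (65–78) × high/low reserve
   by a median split of the WAIS-III Information score.
3. **Connectomes** — per group, `w_ij = max(0, pearson(x_i, x_j))`,
   self-connections removed; proportional thresholding keeps the top
   `k = round(d·n(n−1)/2)` edges at each density `d` of the 20–60% sweep
   (1% steps, 41 levels, nested by a deterministic edge ranking).
4. **Graph measures** — network strength (weighted), global efficiency,
   local efficiency, modularity *Q* (Newman spectral partitioning with
   Kernighan–Lin-style refinement) and small-worldness
   σ = (C/C_rand)/(L/L_rand) against degree-preserving edge-swap
   randomizations.
5. **Group comparison** — participant-permutation tests (default 1000
   permutations; 100 for σ) at every density, two-tailed add-one p-values;
   a difference counts as *stable* only when p < 0.05 at ≥ 10 of the 41
   densities.
6. **Cohort statistics** — 2-way MANOVA (Wilks' Λ, Rao's F) of the age ×
   reserve interaction on the five module composites, canonical
   discriminant functions, follow-up per-module ANOVAs, descriptives.

## Worked example

```python
from cogconnectome import (make_fixture, permutation_test, build_connectome,
                           network_strength, modularity, build_stack)
from cogconnectome.preprocess import preprocess_pipeline, group_score_matrix

# synthetic cohort in which one cell (late middle age, low reserve) has lost
# module specificity: cross-module correlations raised to ~ intra-module level
cohort = make_fixture("dedifferentiation", seed=7, n_per_group=50)
z, strat, excluded = preprocess_pipeline(cohort)
print(f"included {len(z)} participants, reserve threshold {strat.split_threshold}")

a = group_score_matrix(z, strat, ("LMA", "low"))
b = group_score_matrix(z, strat, ("EMA", "low"))
conn_a = build_connectome(a, group=("LMA", "low"))
conn_b = build_connectome(b, group=("EMA", "low"))
print(f"network strength: LMA-low {network_strength(conn_a):.2f}, "
      f"EMA-low {network_strength(conn_b):.2f}")
q_a = modularity(build_stack(conn_a).graph_at(0.30))[0]
q_b = modularity(build_stack(conn_b).graph_at(0.30))[0]
print(f"modularity at 30% density: LMA-low {q_a:.3f}, EMA-low {q_b:.3f}")

result = permutation_test(a, b, measure="modularity", n_perm=200, seed=0)
print(f"stable significant: {result.stable_significant} "
      f"({result.significant_densities}/41 densities with p < 0.05)")
```

Output:

```
included 300 participants, reserve threshold 15.5
network strength: LMA-low 13.45, EMA-low 13.11
modularity at 30% density: LMA-low 0.175, EMA-low 0.431
stable significant: True (41/41 densities with p < 0.05)
```

The dedifferentiated group's connectome is markedly less modular
(0.175 vs 0.431 at 30% density): raised cross-module correlations dissolve
the community structure, and the permutation test flags the difference as
stable across the entire density range.

A command-line interface mirrors the library
(`cogconnectome simulate | preprocess | connectome | measures | compare |
stats | run-all`); `run-all` writes cohort snapshot, stratification, six
connectome matrices, tidy measure curves, all 45 comparison records and the
MANOVA results into a run directory with a manifest.

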