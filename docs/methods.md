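# Methods

This note records the model conventions, defaults and design choices behind
`scnet`, and what the synthetic validation does and does not establish.

## The analysis object

A structural covariance network is estimated per *group*, not per subject:
node = brain region, edge weight = correlation of the two regions' volumes
across the group's subjects. Group comparison therefore cannot use
subject-level variance and relies on label permutation (below).

**Regions.** The default atlas has 56 regions: 9 amygdala nuclei and 19
hippocampal subfields per hemisphere, the vocabulary produced by
FreeSurfer's joint hippocampus–amygdala segmentation. Canonical tokens are
lower-case hyphenated names prefixed by hemisphere
(`right_hippocampus-amygdala-transition-area`); an alias table maps
FreeSurfer's output spellings (`HATA`, `GC-ML-DG-head`,
`Corticoamygdaloid-transitio`, …) onto them, and `Whole_*` aggregate rows
are skipped on ingestion. Atlas order (left amygdala, right amygdala, left
hippocampus, right hippocampus) fixes matrix row/column order everywhere.

**Units.** Absolute volumes and TIV are mm³. Normalization is
`v% = 100 · v / TIV` per subject; it is refused on an already-normalized
cohort because the operation is not idempotent. Whole-structure totals are
computed as subfield sums where needed (the alternative — FreeSurfer's own
whole-structure estimate — is not available from subfield tables alone).

## Network construction

**Partial correlation given covariates.** Edge *(i, j)* is the Pearson
correlation of the OLS residuals of regions *i* and *j* on an intercept,
age (years, uncentered — centering does not change residual correlations)
and sex (a single {0, 1} regressor, female = 0 by default and configurable,
since input tables code sex inconsistently). Regions are *not* conditioned
on the other 54 regions: with n ≈ 35 subjects and 56 regions the inverse
covariance matrix is not estimable, and the pairwise-given-covariates
convention is what group-level SCN toolboxes compute.

**Weight policy.** Correlations in [−1, 1] are mapped to edge weights by
`zero_negative` (default; negative covariance has no path semantics in the
weighted measures), `absolute`, or `keep` (signed, valid only for measures
that need no path lengths). The diagonal is always zero and matrices are
exactly symmetric (upper triangle mirrored).

**Density thresholding.** Binary graphs keep the `round(d · N(N−1)/2)`
strongest edges for each density *d* in the default grid 0.10–0.90 (step
0.10). Ties at the cutoff are broken by ascending (i, j) index order —
correlation weights rarely tie, but the rule makes runs reproducible and
edge sets nested along the grid. If fewer positive edges exist than
requested, all positive edges are used and a warning logged.

## Graph measures

Conventions follow the BRAPH/BCT family:

* **Distances:** weighted edge length `1/w`; Dijkstra all-pairs;
  unreachable pairs are `+inf`. Binary graphs reduce to hop counts.
* **Characteristic path length:** mean over ordered reachable pairs; a
  disconnection warning is attached when pairs are excluded.
* **Global efficiency:** mean of `1/d` with `1/inf = 0`.
* **Eccentricity / radius / diameter:** per-node max finite distance, its
  min and max; the scalar "eccentricity" reported in tables is the node
  mean (it then lies between radius and diameter). On disconnected graphs
  these use the largest component.
* **Clustering (Onnela):**
  `C_i = 2/(k_i(k_i−1)) Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}`, `ŵ = w/max(w)`;
  degree-< 2 nodes get 0. Reduces exactly to triangles/triples on 0/1
  matrices. **Transitivity** is the ratio of summed triangle intensity to
  summed connected triples. Note the max-normalization makes mean
  clustering scale-invariant: it measures weight *heterogeneity* relative
  to the strongest edge, so a uniformly weaker network has *lower*
  clustering mainly through its noisier relative weights (this matters for
  interpreting group differences; see the generator rationale below).
* **Local efficiency:** node mean of the global efficiency of each node's
  neighbor subgraph (original weights; < 2 neighbors contributes 0).
* **Betweenness:** Brandes accumulation (igraph's C implementation, which
  matches the normalized Brandes definition exactly), divided by
  `(N−1)(N−2)/2` so values lie in [0, 1].
* **Modularity:** Louvain maximization of weighted Newman Q, 8 seeded
  restarts with the best Q kept — single-run Louvain can stall at one
  community on small graphs (observed on 5-cycles, Q = 0 vs optimum
  0.111). Deterministic given the seed.
* **Assortativity:** Pearson correlation of endpoint strengths over edges,
  each edge contributing both orientations (on binary graphs strength =
  degree, the classical coefficient). Zero endpoint variance (regular
  graphs) yields an explicit *undefined* flag, never a silent NaN.
* **Small-worldness:** σ = (C/C_null)/(L/L_null) with null values averaged
  over 100 (default) degree-preserving rewired surrogates (double-edge
  swaps, 10·|E| attempts, igraph rewiring seeded through the stdlib
  `random` generator); for weighted graphs the observed weight multiset is
  shuffled onto the rewired topology. A complete graph has no alternative
  topology, so its surrogates keep the observed edges (binary complete
  graphs give σ = 1 exactly). Surrogates that disconnect use
  reachable-pair path lengths.

Every measure is validated against brute-force oracles (exhaustively on
all connected graphs with ≤ 5 nodes, and on random weighted graphs with
≤ 8 nodes) and for exact binary reduction; see `tests/test_acceptance.py`.

## Group inference

**Permutation tests.** Subjects are reassigned to pseudo-groups of the
original sizes (sampling without replacement); the *entire* estimation
pipeline — covariate residualization within pseudo-group, network, measure
— is re-run per relabeling, so the null reflects the full procedure.
Two-sided p uses the add-one estimator
`(1 + #{|Δ_perm| ≥ |Δ_obs|})/(n_perm + 1)`; p is never exactly 0 and is
bounded below by `1/(n_perm+1)`. The reported interval is the 2.5th/97.5th
percentile band of the *permuted* differences — a null band that brackets
0, matching how such tables are conventionally reported. A permutation
producing a degenerate network (zero-variance region, no positive edges)
is redrawn with a logged count. All 13 global measures share one
permutation stream, so they are evaluated on identical relabelings.

**Multiplicity.** The 56 per-region betweenness tests are corrected by
Benjamini–Hochberg step-up FDR; the 13 global measures are reported with
raw p (the convention in the motivating literature, where a global
p = .047 is called significant). Both behaviors are configurable. BH is
*not* idempotent in general (BH of (0.1, 0.9) is (0.2, 0.9); applying it
again gives (0.4, 0.9)), so the implementation is checked against a
hand-coded step-up oracle and for order-equivariance rather than for
idempotence.

**Clinical correlations.** Pearson r with two-sided t-based p per region ×
variable, computed within the patient group, flagged at p < .05
(uncorrected, as is conventional for these exploratory tables).

## Synthetic cohort generator

The generator exists because the motivating study's volumes are available
only on request; it emulates the cohort's *statistical shape* so every
pipeline stage, and the inference calibration, can be tested end to end.

Per subject: age ~ U(18, 35) years, sex ~ Bernoulli(0.5), TIV ~ Normal
(1.45 × 10⁶ mm³, sd 1.3 × 10⁵, truncated at ±3 sd). Region volume in %TIV
= region mean + β_age·age + β_sex·sex + noise_sd·ε, with defaults
β_age = −5 × 10⁻⁵ %TIV/yr, β_sex = 5 × 10⁻⁴ %TIV, noise_sd = 0.002 %TIV,
and flat region means summing to ~0.12% (amygdala) and ~0.235%
(hippocampus) per side — the scale of reported whole-structure totals.
Volumes are converted to absolute mm³ through the subject's TIV (inverting
the pipeline's normalization); negative draws are resampled with a logged
count (a > 5σ event at the defaults).

The noise vector ε is drawn from an **explicit target correlation matrix**
(symmetric square root of Σ; Σ is eigenvalue-checked for positive
semi-definiteness at construction). Σ is built from a block layout:
`within_block_r` inside a block, `between_block_r` across blocks.

**Why the default layout is a single whole-system block.** Reported
group-level SCN matrices for these regions are near-uniformly strong
(average strength ≈ 39 of a possible 55 → mean edge ≈ 0.7, transitivity
≈ 0.98), i.e. one dominant covariance level rather than visible module
structure. Simulation also shows that under max-normalized Onnela
clustering a *minority* of within-block pairs cannot move the group mean
clustering in a stable direction — with an 8-block layout the planted
0.7-vs-0.4 within-block difference produced no detectable (or
wrong-signed) clustering differences at n = 35/34. With the whole-system
block, `within_block_r` is the group's global covariance level, and
lowering it in the patients (via `plant_group_difference(…,
"clustering_shift", 0.3)` → 0.7 vs 0.4) lowers their mean clustering and
average strength exactly as the clinical reports describe. An anatomical
8-block layout (amygdala / hippocampal head / body / tail–fimbria–fissure
per hemisphere, `anatomical_block_assignment`) remains available for
structured simulations and anchors the hub experiment.

**Hub shift.** `plant_group_difference(…, "hub_shift", m)` carves the
designated hub's anatomical block out of the shifted group's Σ: members'
correlations drop to 0.15 with each other and 0.05 with the rest of the
network, while member–hub stays at 0.35 and hub–outside at 0.60 (values
grid-searched inside the PSD-feasible region for an 8-member block in a
0.7 background). Shortest paths within the block and from the block
outward then run through the hub, raising its betweenness in the shifted
group only; `m` interpolates linearly between base and full carve.

**What passing tests show — and don't.** The generator matches the
analysis model exactly: Gaussian noise, exactly linear covariate effects,
homogeneous correlation levels, no site/scanner effects, no segmentation
failures, no volume outliers, and group differences injected only through
the covariance structure. Calibration and power results (type-I error in
[0.02, 0.09]; ≥ 80% power for the 0.7-vs-0.4 shift; hub recovered in the
top-5 betweenness differences in ≥ 80% of replicates at n = 35/34)
therefore validate the *pipeline*, not the robustness of SCN analysis to
real-data violations of those assumptions.

## Numerical and reproducibility choices

* Exact symmetry by construction (upper triangle mirrored), diagonals
  forced to 0; correlations clipped to [−1, 1].
* A region whose residual standard deviation is ≤ 1e−12 × the volume scale
  is treated as zero-variance (a constant column's OLS residuals are
  rounding noise ~1e−17, not exactly 0) and reported by name.
* All randomness (permutations, Louvain restarts, rewiring nulls, weight
  shuffles, cohort draws) descends from explicit integer seeds via
  `numpy.random.SeedSequence`; pipeline reruns with the same config and
  seed are byte-identical, and every report carries the config hash.
* Simulation sizes in the test suite and acceptance script (200
  calibration replicates × 200 permutations; 50 power/recovery/FDR
  replicates; exhaustive oracle checks on ≤ 5 nodes and 100 random graphs
  on ≤ 8 nodes) were chosen to give stable rates while keeping a full run
  in a few minutes on one CPU.

## Known limitations

* Pairwise partial correlation (given covariates) is not a conditional
  independence graph over regions; with n ≪ N no such graph is estimable.
* The weighted local-efficiency values of near-complete correlation
  networks are not comparable across weight policies or to binary values
  at a fixed density; compare like with like.
* The density sweep can request more edges than the zero-negative network
  possesses at high densities; the realized density is then lower (logged).
* `keep` (signed) weights support only the measures that need no path
  lengths; path-based measures refuse negative weights rather than
  silently reinterpreting them.
* Group-level permutation p-values with n_perm = 1000 have a resolution
  floor of ~0.001; CIs are null percentile bands, not confidence intervals
  for the observed difference.
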