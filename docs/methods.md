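# Methods

This note documents the statistical model, the algorithmic choices, the
tunable parameters, and what the synthetic benchmark does and does not
establish.

## Discretization of expression

Expression values are log-scale.  For each feature (gene or miRNA) the mean
μ̄ and sample standard deviation *s* (n−1 denominator) are computed over
**all** samples — tumor and adjacent non-tumor — ignoring missing cells, so
each transcript gets its own cutoffs and an equal chance of entering patient
graphs.  A tumor value is tagged UP above μ̄ + t·s and DOWN below μ̄ − t·s.
The z-threshold t (default **1.0**, dimensionless) controls graph density:
under pure noise a fraction ≈ 2Φ(−t) of cells is tagged (≈ 32% at t = 1), and
raising t can only remove tags (tag sets are nested in t).  Zero-variance and
single-observation features are never tagged (their z-score is undefined),
and no judgment is made on missing values — a missing tumor cell is always
untagged rather than imputed.

miRNA probe-level rows may be collapsed to features by the per-sample median
over mapped probes (a collapsed cell is missing only when all probes are);
gene rows pass through unless a probe map is supplied.

## Template graph

Each candidate miRNA→gene pair is scored by the Pearson coefficient over the
samples where both vectors are observed; pairs with fewer than 3 joint
observations or a constant vector are skipped.  Significance is a one-tailed
permutation test in the direction of sign(r): the target vector is permuted
(n_perm = 1000 by default) and the tail fraction computed with add-one
smoothing, p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), ties counted inclusively
(mirrored for negative r).  When the number of distinct permutations is at
most 5000 the tail is enumerated exactly instead.  Each pair draws its
permutations from a deterministic substream keyed by the pair's identifiers,
so results do not depend on pair order.  Benjamini–Hochberg FDR is applied
separately to each miRNA's target list, mirroring the per-miRNA multiple
comparisons control of the correlation screen; edges with q ≤ q_threshold
(default **0.05**) are kept and isolated nodes dropped.

**Known limitation.**  Because the tail is chosen from the observed sign, the
p-value is anti-conservative under the null: P(p ≤ α) ≈ 2α (a sign-directed
one-tailed test is equivalent to a two-sided test at half the nominal level).
We keep the sign-directed convention because a fixed a-priori tail would
discard all positively correlated target relationships; users who need
calibrated type-I error should halve q_threshold.

## Patient graphs

A patient graph contains the patient's tagged transcripts and every template
edge whose sign is consistent with the endpoint tags — a positive edge needs
equal tags, a negative edge opposite tags.  Tagged nodes with no consistent
incident edge are retained (only untagged nodes are removed); they simply
cannot join patterns of size > 1.  Consequently a patient graph is a
deterministic function of its tag row and the template, and deleting a tag
can only shrink the graph.

## Closed frequent subgraph mining

Node labels carry transcript identity *and* tag.  Two structural facts then
simplify mining without changing its output:

* subgraph isomorphism collapses to identity containment — a pattern occurs
  in a patient graph iff all its tagged nodes do;
* every patient graph contains all tag-consistent template edges between its
  nodes, so a pattern's edge set is implied by its node set (a pattern with
  fewer than the implied edges has a supergraph — the implied one — with the
  same support, hence is never closed).

Mining therefore enumerates connected subsets of the tagged-node universe
(adjacency = tag-consistent template edges).  Each connected subset is
visited exactly once by ESU-style exclusive-neighborhood extension with a
fixed total order on (feature, tag) nodes; support is the popcount of
intersected per-node patient bitsets, and branches are pruned as soon as the
intersection drops below minSup (support is anti-monotone).  Closedness is
checked against connected supergraphs only, via one-node extensions: if any
adjacent node keeps the support unchanged the pattern is not closed.  This
immediate-extension test is equivalent to the full definition by a path
argument — any connected proper supergraph of equal support contains a
one-step connected extension of equal support.  The test suite verifies exact
agreement with a brute-force enumerator on hundreds of random instances, and
cross-checks support counting against a generic subgraph-isomorphism matcher.

Parameters: `min_support` (absolute count, or a fraction of patients
converted by ceiling — 0.066 of 196 patients gives 13; default fraction
**0.05**), and `min_gene_nodes` (default **4**), applied *after* closure
because filtering during the search would change which patterns are closed.
Pattern significance permutes, independently per feature, the assignment of
its tags across patients and recounts the joint support (add-one smoothed,
default 1000 permutations); patterns are reported with their p but not pruned
by default.  All patterns merge into a single co-module — the exact union of
node and edge sets — which both de-duplicates heavily overlapping patterns
and defines the feature set for clustering.  A per-patient occurrence score
(fraction of a pattern's nodes present with matching tag) supports heatmap
style reporting.

## Mixture model

Patients are clustered on the tumor expression of co-module transcripts with
a K-component diagonal Gaussian mixture in which all genes share one standard
deviation σ_g and all miRNAs share another σ_m.  Sharing the scales keeps the
parameter count at (K−1) + K·(G+M) + 2, which stabilizes clustering at
cohort sizes of ~100–200 patients and damps the influence of low-variance
noisy features; features are treated as conditionally independent given the
cluster.  Missing cells are marginalized exactly: a patient's density is the
product of univariate normals over its observed cells only, which is the
correct EM treatment of the diagonal model under missing-at-random.

EM details: responsibilities are computed in log-space (logsumexp); the
M-step updates mixing weights as mean responsibilities, means from
responsibility-weighted observed values (cells with zero responsibility mass
fall back to the pooled feature mean), and each shared variance from pooled
responsibility-weighted squared residuals over all observed cells of that
block, floored at **10⁻⁴** to prevent degenerate collapse.  Initialization
draws per-patient responsibilities from a symmetric Dirichlet(1); the best of
`n_restarts` (default **20**) runs by final log-likelihood is kept, each
restart seeded from a spawned substream so fits are reproducible.
Convergence: relative log-likelihood change below **10⁻⁶** or 500 iterations;
the within-run log-likelihood path is non-decreasing, and the reported
log-likelihood is evaluated at the returned parameters.  Assignments are
argmax responsibilities with ties to the lowest index.  Model selection
maximizes BIC = 2·log L − p·ln N over a K range (default 1–4).

## Evaluation

* **Bootstrap stability**: B (default **100**) subsets of ⌈0.7·N⌉ patients
  drawn without replacement (a with-replacement flag exists), the mixture
  refitted on each at the reference K; refit labels are aligned to the
  reference clustering by maximum-agreement matching (assignment problem on
  the contingency table, which for K = 2 reduces to majority orientation).
  A patient's score is the fraction of subsets containing it in which the
  aligned label equals the reference label; patients never drawn get a
  missing score.  Sampling without replacement is used because the resamples
  are fixed 70% sub-cohorts.
* **Partition agreement**: Rand index (agreeing pairs over all pairs) and the
  Hubert–Arabie adjusted Rand index from the pair-count contingency table;
  the degenerate all-pairs-agree case returns 1.  A `disagreement` helper
  reports the count and percentage of patients labeled differently after
  optimal alignment.
* **Clinical enrichment**: per binary covariate, a 2×2 clusters × levels
  table tested with Fisher's exact test — right-tailed for enrichment,
  two-sided (point-probability rule) for cohort comparisons; NA patients are
  excluded per covariate and single-level covariates skipped.  The right
  tail is on the (cluster 0, first level) cell, so the orientation of the
  question is the caller's: test the flipped table for the opposite
  direction.  Covariates with more than two levels must be dichotomized
  upstream.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes: paired tumor /
non-tumor samples (one of each per patient), per-feature log-scale baselines
(genes ~ N(8,1), miRNAs ~ N(6,1)) with i.i.d. Gaussian noise (sd **1.0**),
K = 2 balanced subgroups, and 2 planted modules of 2 miRNAs × 6 genes, each
dysregulated in exactly one subgroup: in that subgroup's tumor samples the
module miRNAs shift down by `effect` (default **3·noise_sd**) and its target
genes up, with mild per-feature jitter (sd 0.3·effect) on the shift.  The
jitter is drawn independently per feature so that features remain
conditionally independent given the subgroup — matching the mixture model's
assumption; miRNA–target anti-correlation then arises through the subgroup
structure (|r| ≈ 0.6 at the defaults).  The candidate list contains every
planted pair plus 50 decoy pairs between unrelated features; 5% of cells are
missing at random; a binary clinical covariate is drawn at subgroup-specific
rates (0.75 vs 0.25).  Defaults: 100 patients, 60 genes, 12 miRNAs.

In this regime a full module pattern (miRNA + 4–6 genes jointly tagged)
occurs in roughly 5–10% of patients, which is why the default support
fraction is 0.05 — the same order as the thresholds a real cohort of this
design would need.  What passing tests show: the pipeline recovers planted
pairs, module membership, subgroup count and labels, and is bootstrap-stable
when the planted structure is well separated and the noise model is honest.
What they do not show: robustness to platform/batch effects, probe-level
artifacts, non-Gaussian heavy-tailed expression, correlated missingness, or
modules shared across overlapping subgroups — none of which the generator
emulates.

## Numerical and degenerate-input conventions

Ties in permutation statistics count toward the tail (conservative); sampled
permutation p-values are add-one smoothed and therefore never zero; the
exhaustive mode returns the exact tail fraction.  Fractional support converts
to an absolute threshold by ceiling.  Empty pattern lists yield NaN summary
ratios; the occurrence score of an empty pattern is an error; stability is
missing for patients never resampled; ARI of two trivial partitions is 1.
Cluster-assignment ties break to the lowest index.  All stages accept one
root seed and derive named substreams (CRC-keyed `SeedSequence` spawn keys),
so artifacts are bit-reproducible and stage order does not perturb streams.

## Problem sizes

The bundled tests and the acceptance script run entirely on generated data at
desk scale — 100-patient cohorts, tens of features, 200–1000 permutations,
100 bootstrap refits, and ≥ 50 randomized miner-vs-brute-force instances with
templates of ≤ 12 nodes and ≤ 10 patients, where exhaustive enumeration is
feasible as an oracle.
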