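# Methods

## Activity normalization and classification

Raw records carry one measurement each (IC50 or Ki, µM after exact unit
conversion from {nM, µM, mM, M}). Comparability across assays is achieved
by dividing each value by the activity of that assay's control compound;
when a publication reports no control, a 20 µM fallback is used — a
typical thiourea IC50 against jack bean urease. The dimensionless ratio
is classified strictly: ratio < 1 (more potent than the control) ⇒
active, ratio ≥ 1 ⇒ inactive, so the boundary case ratio = 1.0 is
inactive. Records described only as "inactive" with no value are imputed
an excess concentration of 1000 µM *before* normalization, placing them
deep in the inactive regime (ratio 50 against a 20 µM control) without
inventing potency information. IC50 and Ki are pooled on the ratio scale;
the measurement type is kept for provenance only.

Structure standardization uses RDKit's MolStandardize pipeline (the
maintained port of MolVS): sanitize/normalize/reionize, counterion and
solvent removal, then neutralization of residual charges. Tautomers are
deliberately not canonicalized — distinct tautomer drawings keep distinct
InChIKeys, matching the curation-level assumption that tautomer-duplicate
entries are rare and visible downstream as Tc = 1 pairs. Records are
rejected, never silently dropped, when: the SMILES fails to parse
(`parse_error`); a non-organic element (anything outside H, B, C, N, O,
F, Si, P, S, Cl, Se, Br, I — configurable) remains after counterion
stripping (`metal_complex`, covering covalent and coordinated metals); or
more than one organic fragment remains (`mixture`). Note that common
solvents (e.g. ethanol) are part of the fragment-removal list, so
"compound.ethanol" is kept as the compound — only genuine multi-component
records are mixtures.

Deduplication groups by InChIKey and keeps the most potent (minimum)
ratio, on the grounds that the best measured activity is the one a
medicinal chemist would act on; ratio ties break on the lexicographically
smallest reference id for determinism. Species are unioned, the earliest
year is kept, and the merged record count is reported. Whether "most
potent" should compare raw values or control-normalized ratios is
genuinely open when controls differ; ratios are used, consistent with the
classification scale.

## Fingerprints, similarity, clustering

Compounds are 1024-bit, radius-2 Morgan fingerprints (bit collisions
accepted; no count vectors). Similarity is the Tanimoto coefficient;
`Tc(empty, empty)` is defined as 0 rather than RDKit's 1, since two
molecules with no hashed environments share no evidence of similarity
(logged when it occurs).

Two clustering modes serve different questions:

* **Spontaneous** (diversity): complete-linkage agglomeration on distance
  1−Tc, cut at 0.6. Complete linkage makes the cut semantics exact: every
  intra-cluster pairwise distance is ≤ 0.6. The resulting cluster count
  is the diversity statistic; it is permutation-invariant. An alternative
  reading of the cut (global dendrogram height vs per-cluster max
  distance) coincides for complete linkage, which is why that linkage is
  used.
* **Family** (interpretation): Ward linkage on Euclidean distance over
  the raw 0/1 bit vectors at fixed k, scanned over 20–80 for large sets.
  No transformation is applied to the bit vectors. The codified k-selection
  heuristic picks the k maximizing the number of cohesive clusters
  (min intracluster Tc ≥ 0.5) subject to a smallest-cluster size ≥ 3,
  ties to the smallest k; it returns the full per-k diagnostic table so a
  human can override (`force_k`).

Cluster cohesion is summarized by the minimum and median Tc over all
member pairs; a singleton reports min = median = 1.0 by convention (a
single compound is perfectly self-similar). Cluster scaffolds are maximum
common substructures with `ringMatchesRingOnly=True`, a 60 s per-cluster
timeout, and an empty-but-flagged result on timeout or disjoint members —
a missing scaffold never aborts the pipeline.

## Cliffs and hubs

All unordered pairs with Tc strictly above 0.6 are enumerated all-vs-all
(O(n²) Tanimoto evaluations — desk-scale up to a few thousand compounds;
no locality-sensitive shortcut). Each pair is categorized by the two
classes (both-active / both-inactive / cliff); the three categories
partition the pair set. The fold change `max(ratio_a, ratio_b) /
min(ratio_a, ratio_b)` ranks cliffs on the control-adjusted scale, so
cross-assay pairs remain comparable. Hub profiling counts opposite-class
cliff partners per compound; at ≥ 10 partners (configurable) an active is
a *dead end* and an inactive a *safe bet*. Ten is the lower end of the
hub-degree range the analysis is designed to surface.

## Rule extraction

A Gini decision tree capped at depth 10 is fit to the full descriptor
schema (20 descriptors: size, lipophilicity, H-bonding, topology,
complexity, and ten functional-group counts). The tree is descriptive —
it is never exposed as a predictor for new compounds. Each populated
leaf's root-to-leaf path becomes a candidate rule predicting the leaf
majority class; per-feature bounds are first merged to the tightest one,
integer-count splits are rendered in count terms (`fr_X ≤ 0.5` → `fr_X =
0`, `> 0.5` → `> 0`), and conditions are then greedily dropped — keeping
the drop that most increases coverage — while the rule's empirical
precision on the dataset stays ≥ 0.80. This deterministic path-pruning
variant of anchor extraction reproduces the count/precision bookkeeping
of tabulated anchors exactly and is fully testable; perturbation-based
anchor refinement is deliberately out of scope. Candidates that never
reach the threshold are discarded, duplicates merged, and output ranked
by coverage. Precision is reported to one decimal, rounded half-up
(96.875 → 96.9), the convention used for every percentage in the
package.

Feature relevance is Friedman's one-vs-all H statistic: with empirical
partial dependences estimated on ≤ 500 seeded-subsampled rows, H is the
variance of (full response − additive decomposition into the feature's
term plus the rest term), normalized by the variance of the full
response, clipped to [0, 1]. Constant predictions define H = 0. The
estimator costs n² model evaluations per feature, hence the row cap.

## Synthetic data: what it emulates, what it does not

The generator builds compounds as disubstituted elaborations of eight
drug-like cores (benzamides, diaryl ureas/thioureas, heteroaryl amides —
chemotypes typical of urease-inhibitor series), one core per scaffold
family. Activity lives on the log-ratio scale, where the ratio < 1 cutoff
maps exactly to log-ratio < 0: each family has a base log ratio, each
substituent a shift, and records are emitted as `control ·
exp(log_ratio + noise)` with Gaussian noise (default sd 0.3 log units, a
moderate inter-assay scatter). The emitted table reproduces the messiness
curation must handle: references with controls at 15/20/25 µM, 10% of
records missing the control (only where the true control equals the 20 µM
fallback, so truth stays exact), 15% duplicate records under different
reference ids, 5% of true inactives reported only qualitatively, a
species mix dominated by jack bean urease, and years over 1990–2021.

Planted truth: *cliffs* are planted by flipping the log-ratio sign of
selected compounds; a planted cliff pair is a flipped compound plus a
single-substituent neighbour with |log ratio| ≥ 0.6 on both sides
(margin chosen ≈ 2σ of the default noise so planted cliffs are
detectable in principle, not borderline) and Tc > 0.6 verified on the
final standardized structures at generation time. The *rule* is planted
by granting a −4 log-unit bonus to compounds carrying both a thiol and a
sulfonamide substituent; this combination is forced into every family's
enumeration so the conjunction `fr_SH > 0 AND fr_sulfonamd > 0 ⇒ active`
always has support. Two stock configurations are study conditions:
the default (family potency dominates; used for cliff, clustering and
curation checks) and `rule_planted` (all families inactive-leaning,
damped substituent effects, no flips; the conjunction is the only
activity signal, the condition under which rule extraction is exercised).

What the generator does *not* emulate: real structural diversity (eight
cores vs hundreds of literature scaffolds — family-recovery ARI under the
default, deliberately similar anilide cores is therefore moderate, ~0.6,
and reaches 1.0 only for well-separated chemotypes), tautomer/stereo
duplication, activity trends over time, correlated assay biases, or any
actual published structure. Passing recovery tests therefore demonstrates
the pipeline's correctness on data with known answers, not performance
claims about literature data.

## Numerical and reporting conventions

* Percentages: one decimal, half-up (`decimal.Decimal`), everywhere.
* All stage outputs sorted deterministically (InChIKey, cluster id, pair
  key); ties always have an explicit tie-break rule.
* One master seed per pipeline run; per-stage seeds derived via
  `numpy.random.SeedSequence` and recorded in the report.
* t-SNE coordinates (perplexity `min(30, (n−1)/3)`, PCA init, 500
  iterations) are reporting-only and never feed downstream statistics.
* Acceptance-style reruns (`scripts/acceptance.py`) use 300-compound
  libraries and five noise seeds — sizes at which every stage, including
  the O(n²) pair scan and MCS per cluster, completes in seconds on one
  core while leaving all statistics well-resolved.

## Known limitations

* PAINS/Brenk alerts come from RDKit's built-in FilterCatalog (pinned by
  the installed RDKit version); user-supplied `name<TAB>SMARTS` catalogs
  are supported but the built-ins are not re-shipped as files.
* The family-census SMARTS (`data/groups.smarts`) are editable defaults;
  family counts depend on these definitions and are not canonical.
* Lipinski "pass" defaults to the strict zero-violation reading; the
  classic ≤ 1-violation variant is a flag.
* No 3-D treatment anywhere: no conformers, docking, pharmacophores, or
  stereochemistry-aware similarity.
* The decision tree memorizes the training set by design (descriptive
  SAR); its accuracy is a memorization diagnostic, not generalization.
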