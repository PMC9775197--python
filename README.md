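# ureascape

Chemical-space, activity-cliff and rule-extraction analysis for urease
inhibitor bioassay data.

Urease hydrolyses urea into ammonia and CO2; inhibiting it matters both for
agriculture (soil nitrogen loss) and medicine (*Helicobacter pylori*,
urinary stones). Decades of inhibition data are scattered across
literature, patents and ChEMBL with heterogeneous assays, controls, units
and species. `ureascape` is a library for turning such compound-assay
tables into a curated, analysis-ready dataset and then profiling its
structure-activity landscape:

* **Curation** — structure standardization (salt stripping,
  neutralization), rejection of metal complexes and mixtures, exact unit
  conversion to µM, normalization of IC50/Ki values against each assay's
  control (ratio = IC50/control, 20 µM thiourea-typical fallback),
  activity classification (ratio < 1 ⇒ active), imputation of qualitative
  "inactive" records at 1000 µM, and InChIKey deduplication keeping the
  most potent measurement.
* **Chemical space** — 1024-bit radius-2 Morgan fingerprints; Tanimoto
  similarity `Tc(a,b) = |a∧b| / |a∨b|`; Murcko scaffolds; t-SNE embedding;
  comparison against a reference SMILES library (exact InChIKey overlap vs
  near neighbors at Tc > 0.6).
* **Profiling** — 2-D descriptors (MW, logP, HBD/HBA, TPSA, BertzCT
  complexity, molar refractivity, solubility estimate, functional-group
  counts), rule-of-5 filtering, PAINS and Brenk structural alerts,
  SMARTS-based functional-family censuses, temporal trends, and
  cross-species activity concordance.
* **Clustering** — complete-linkage clustering on 1−Tc cut at 0.6 (the
  cluster count is a diversity statistic) and Ward/Euclidean family
  clustering at fixed *k* with cohesion statistics (min/median
  intracluster Tc) and maximum-common-substructure scaffolds
  (ring atoms matched to ring atoms only).
* **Activity cliffs** — all pairs with Tc > 0.6, split into linear-SAR
  pairs vs cliffs (opposite classes); *safe bets* (inactive hubs with many
  active analogues) and *dead ends* (the reverse) by cliff degree.
* **Rules** — a depth-≤10 Gini decision tree on descriptors, from which
  anchor-style conjunctive IF-THEN rules are extracted by greedy
  path-pruning at a 0.80 empirical-precision threshold, reported with
  coverage counts `(N_actives, N_inactives, N, precision %)`; per-feature
  Friedman one-vs-all H statistics quantify non-additive (interaction)
  effects.
* **Synthetic libraries** — a generator that emulates the structure of
  literature bioassay data (scaffold families, heterogeneous controls,
  duplicates, qualitative inactives, multi-species mix) with planted
  ground truth: known families, activity cliffs verified at Tc > 0.6, and
  a descriptor conjunction that drives activity. Every pipeline stage is
  therefore testable end to end without any external download.

## Worked example

`examples/extract_rules.py` generates a library in which activity is
driven by a planted thiol-AND-sulfonamide conjunction, fits the activity
tree and extracts rules:

```
training accuracy: 1.000
rules extracted:   3

  IF fr_sulfonamd = 0 THEN inactive  [N=210, precision 100.0%]
  IF fr_SH = 0 THEN inactive  [N=199, precision 100.0%]
  IF fr_sulfonamd > 0; fr_SH > 0 THEN active  [N=10, precision 100.0%]

planted rule recovered verbatim: True

feature interaction (one-vs-all H):
     feature  h_statistic
       fr_SH     0.632676
fr_sulfonamd     0.632676
       MolWt     0.000000
```

The planted conjunction surfaces as its own rule covering exactly the 10
compounds that carry both groups, and the two rule descriptors show strong
interaction (H ≈ 0.63) while an uninvolved descriptor shows none. The
other scripts in `examples/` walk through curation, chemical-space
mapping, cliff detection and the full pipeline the same way. A thin CLI
(`ureascape curate|space|profile|cluster|cliffs|rules|synth|run`) wraps
the same functions for shell use.

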