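"""End-to-end orchestration: curate -> profile -> space -> cluster ->
cliffs -> rules from a single YAML config, with a consolidated JSON report.

Every number in the report is recomputable from the stage CSVs written next
to it; the report adds nothing of its own. All randomness flows from one
master seed, from which per-stage seeds are derived and recorded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import chemspace, cliffs, clustering, curation, profiling, rules
from ._utils import pct

logger = logging.getLogger(__name__)

STAGES = ("curate", "profile", "space", "cluster", "cliffs", "rules")


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    raw_csv: str
    out_dir: str
    stages: tuple[str, ...] = STAGES
    default_control_um: float = curation.DEFAULT_CONTROL_UM
    tc_threshold: float = 0.6
    max_dist: float = 0.6
    family_k: int | str = "auto"
    k_range: tuple[int, int] = (20, 80)
    min_degree: int = 10
    max_depth: int = rules.MAX_DEPTH
    precision_threshold: float = rules.PRECISION_THRESHOLD
    reference_smiles: str | None = None
    embed: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not Path(self.raw_csv).exists():
            raise FileNotFoundError(self.raw_csv)
        if self.reference_smiles is not None and not Path(self.reference_smiles).exists():
            raise FileNotFoundError(self.reference_smiles)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        # derived, recorded per-stage seeds; keep below 2**31
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2**31)
        )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all enabled stages in dependency order; returns the report dict.

    Stage CSVs and ``report.json`` land in ``config.out_dir``. A stage
    failure aborts with the stage named in the exception; outputs of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
    }
    state: dict[str, Any] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, report, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s complete", stage)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(f"stage {needed_by!r} requires stage {stage!r} to run first")
    return state[key]


def _stage_curate(config: PipelineConfig, state, report, out: Path):
    records = curation.read_raw_csv(config.raw_csv)
    curated, normalized, rejects = curation.curate(records, config.default_control_um)
    curated.to_csv(out / "curated.csv", index=False)
    rejects.to_csv(out / "rejects.csv", index=False)
    normalized.to_csv(out / "normalized_records.csv", index=False)
    state["curated"], state["normalized"] = curated, normalized
    n_active = int((curated["activity_class"] == "active").sum())
    report["curate"] = {
        "n_raw_records": len(records),
        "n_rejected_records": len(rejects),
        "n_compounds": len(curated),
        "n_active": n_active,
        "n_inactive": len(curated) - n_active,
        "pct_active": pct(n_active, len(curated)),
    }


def _stage_profile(config: PipelineConfig, state, report, out: Path):
    curated = _require(state, "curated", "curate", "profile")
    descriptors = profiling.descriptor_table(curated["canonical_smiles"])
    descriptors.insert(0, "inchikey", curated["inchikey"].to_numpy())
    descriptors.to_csv(out / "descriptors.csv", index=False)
    filt = profiling.filter_report(curated, descriptors[profiling.DESCRIPTOR_NAMES])
    filt.to_csv(out / "filter_report.csv", index=False)
    census = profiling.group_census(curated)
    census.to_csv(out / "group_census.csv", index=False)
    trends = profiling.temporal_trends(curated)
    trends.to_csv(out / "temporal_trends.csv", index=False)
    n_multi, n_disc, pct_disc = profiling.species_concordance(state["normalized"])
    state["descriptors"] = descriptors
    active = curated["activity_class"] == "active"
    clean_active = int((filt["clean"] & active.to_numpy()).sum())
    report["profile"] = {
        "n_lipinski_pass": int(filt["lipinski_pass"].sum()),
        "n_pains_flagged": int((filt["pains_alerts"] != "").sum()),
        "n_brenk_flagged": int((filt["brenk_alerts"] != "").sum()),
        "n_clean": int(filt["clean"].sum()),
        "n_clean_active": clean_active,
        "pct_clean_active": pct(clean_active, int(active.sum())),
        "n_multi_species": n_multi,
        "n_species_discordant": n_disc,
        "pct_species_discordant": pct_disc,
    }


def _stage_space(config: PipelineConfig, state, report, out: Path):
    curated = _require(state, "curated", "curate", "space")
    fps = chemspace.fingerprints(curated["canonical_smiles"])
    sim = chemspace.similarity_matrix(fps)
    state["fps"], state["similarity"] = fps, sim
    state["fp_matrix"] = chemspace.fingerprint_matrix(curated["canonical_smiles"])
    scaffolds = [chemspace.murcko_scaffold(s) for s in curated["canonical_smiles"]]
    space_report: dict[str, Any] = {
        "n_murcko_scaffolds": len({s for s in scaffolds if s}),
    }
    if config.embed and len(curated) >= 3:
        coords = chemspace.embed_2d(state["fp_matrix"], seed=config.stage_seed("space"))
        emb = curated[["inchikey", "activity_class"]].copy()
        emb.insert(1, "x", coords[:, 0])
        emb.insert(2, "y", coords[:, 1])
        emb.to_csv(out / "embedding.csv", index=False)
    if config.reference_smiles:
        n_exact, n_near, per = chemspace.compare_to_reference(
            curated, config.reference_smiles, config.tc_threshold
        )
        per.to_csv(out / "reference_comparison.csv", index=False)
        space_report["n_reference_exact"] = n_exact
        space_report["n_reference_near"] = n_near
    report["space"] = space_report


def _stage_cluster(config: PipelineConfig, state, report, out: Path):
    curated = _require(state, "curated", "curate", "cluster")
    sim = _require(state, "similarity", "space", "cluster")
    classes = curated["activity_class"].tolist()
    smiles = curated["canonical_smiles"].tolist()
    spont_labels, n_spont = clustering.spontaneous_clustering(sim, config.max_dist)
    spont_summary = clustering.summarize_clusters(spont_labels, sim, classes)
    spont_summary.to_csv(out / "spontaneous_summary.csv", index=False)
    cluster_report = {"n_spontaneous_clusters": n_spont}

    k_cfg = config.family_k
    lo, hi = config.k_range
    if len(curated) > hi:
        if k_cfg == "auto":
            k, diagnostics = clustering.select_k(
                state["fp_matrix"], sim, classes, range(lo, hi + 1)
            )
            diagnostics.to_csv(out / "k_diagnostics.csv", index=False)
        else:
            k = int(k_cfg)
    else:
        k = None if k_cfg == "auto" else int(k_cfg)
    if k is not None and 2 <= k <= len(curated):
        fam_labels = clustering.family_clustering(state["fp_matrix"], k)
        fam_summary = clustering.summarize_clusters(fam_labels, sim, classes, smiles)
        fam_summary.to_csv(out / "family_summary.csv", index=False)
        assign = curated[["inchikey"]].copy()
        assign["spontaneous_cluster"] = spont_labels
        assign["family_cluster"] = fam_labels
        assign.to_csv(out / "cluster_assignment.csv", index=False)
        state["family_labels"] = fam_labels
        cluster_report["family_k"] = int(k)
    else:
        assign = curated[["inchikey"]].copy()
        assign["spontaneous_cluster"] = spont_labels
        assign.to_csv(out / "cluster_assignment.csv", index=False)
        logger.warning("family clustering skipped: dataset too small for k selection")
    state["spontaneous_labels"] = spont_labels
    report["cluster"] = cluster_report


def _stage_cliffs(config: PipelineConfig, state, report, out: Path):
    curated = _require(state, "curated", "curate", "cliffs")
    sim = _require(state, "similarity", "space", "cliffs")
    pairs = cliffs.enumerate_similar_pairs(curated, config.tc_threshold, sim)
    pairs.to_csv(out / "pairs.csv", index=False)
    classes = dict(zip(curated["inchikey"], curated["activity_class"]))
    profiles = cliffs.cliff_profiles(pairs, classes, config.min_degree)
    profiles.to_csv(out / "cliff_profiles.csv", index=False)
    state["pairs"] = pairs
    report["cliffs"] = {
        "n_pairs": len(pairs),
        **{f"n_{c}": n for c, n in cliffs.pair_category_counts(pairs).items()},
        "n_dead_ends": int((profiles["role"] == "dead_end").sum()),
        "n_safe_bets": int((profiles["role"] == "safe_bet").sum()),
    }


def _stage_rules(config: PipelineConfig, state, report, out: Path):
    curated = _require(state, "curated", "curate", "rules")
    descriptors = _require(state, "descriptors", "profile", "rules")
    X = descriptors[profiling.DESCRIPTOR_NAMES]
    y = curated["activity_class"].to_numpy()
    model = rules.train_activity_tree(
        X, y, config.max_depth, seed=config.stage_seed("rules")
    )
    extracted = rules.extract_rules(model, X, y, config.precision_threshold)
    rules.rules_to_frame(extracted).to_csv(out / "rules.csv", index=False)
    interactions = rules.interaction_table(
        model, X, seed=config.stage_seed("rules")
    )
    interactions.to_csv(out / "interactions.csv", index=False)
    state["rules"], state["tree_model"] = extracted, model
    top = extracted[:5]
    report["rules"] = {
        "training_accuracy": model.training_accuracy,
        "n_rules": len(extracted),
        "top_rules": [
            {
                "conditions": "; ".join(str(c) for c in r.conditions),
                "predicted_class": r.predicted_class,
                "n_total": r.n_total,
                "precision_pct": r.precision_pct,
            }
            for r in top
        ],
        "max_h_statistic": float(interactions["h_statistic"].max()) if len(interactions) else 0.0,
    }


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "profile": _stage_profile,
    "space": _stage_space,
    "cluster": _stage_cluster,
    "cliffs": _stage_cliffs,
    "rules": _stage_rules,
}
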