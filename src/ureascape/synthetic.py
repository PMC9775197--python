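"""Synthetic bioassay libraries with planted ground truth.

The generator emulates the structure of a curated-from-literature urease
inhibition dataset without reproducing any real compound: scaffold families
of varying cohesion (one disubstituted core per family), heterogeneous assay
controls around a thiourea-typical 20 uM, duplicate measurements across
references, qualitative "inactive" entries without a value, and a
multi-species record mix dominated by jack bean urease.

Ground truth is planted on the log-ratio scale, where the active/inactive
cutoff (ratio < 1) maps exactly to log-ratio < 0:

* each family has a base log ratio; each substituent shifts it;
* *activity cliffs* are planted by flipping the sign of the log ratio of
  selected compounds, so single-substituent neighbours (Tc > 0.6, verified
  at generation time on the final structures) sit on opposite sides of the
  activity cutoff;
* an interpretable *rule* is planted by giving compounds bearing a chosen
  substituent combination a strong activity bonus, so a descriptor
  conjunction (e.g. thiol AND sulfonamide present => active) holds by
  construction.

Truth is keyed by InChIKey after the generated structures pass through the
same standardization used in curation, so every pipeline output joins
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import chemspace
from .curation import RawActivityRecord, standardize_structure

#: Disubstituted core templates, one scaffold family each. The cores are
#: elaborated, drug-like chemotypes (benzamides, diaryl ureas/thioureas,
#: heteroaryl amides) so that single-substituent analogues stay similar
#: (Tc > 0.6), as in real inhibitor series. None contains a thiol or
#: sulfonamide, which are reserved for the planted-rule substituents.
DEFAULT_CORES = [
    "Cc1cc(C(=O)Nc2ccc({a})cc2)ccc1{b}",       # N-aryl toluamide
    "O=C(Nc1ccc({a})cc1)c1ccc({b})cn1",        # pyridine carboxanilide
    "O=C(Cc1ccc({a})cc1)Nc1ccc({b})cc1",       # phenylacetanilide
    "O=C(Nc1ccc({a})cc1)Nc1ccc({b})cc1",       # diaryl urea
    "S=C(Nc1ccc({a})cc1)Nc1ccc({b})cc1",       # diaryl thiourea
    "Cc1oc(C(=O)Nc2ccc({a})cc2)cc1{b}",        # methylfuran carboxanilide
    "Cc1n[nH]c(C(=O)Nc2ccc({a})cc2)c1{b}",     # methylpyrazole carboxanilide
    "O=C(Nc1ccc({a})cc1)c1ccc({b})c2ccccc12",  # naphthamide
]

#: Substituent fragments (attachable by SMILES concatenation) and their
#: planted log-ratio shifts. Negative = potency-enhancing.
DEFAULT_SUBSTITUENT_EFFECTS = {
    "Cl": -0.2,
    "F": -0.1,
    "Br": -0.3,
    "O": 0.4,                 # phenol/hydroxyl
    "OC": 0.2,                # methoxy
    "N": -0.4,                # amino
    "CO": 0.3,                # hydroxymethyl
    "C(=O)O": 0.5,            # carboxylic acid
    "C(=O)OC": 0.3,           # methyl ester
    "NC(=S)N": -1.0,          # thiourea
    "NC(=O)N": -0.6,          # urea
    "S": -0.5,                # thiol
    "S(=O)(=O)N": -0.4,       # sulfonamide
    "NN": -0.7,               # hydrazine
    "[N+](=O)[O-]": 0.6,      # nitro
    "NC(=O)C": 0.1,           # acetamido
    "C(=O)NO": -0.8,          # hydroxamic acid
    "CCCCCC": 0.7,            # hexyl chain
    "C(C)C": 0.4,             # isopropyl
    "C#N": 0.2,               # nitrile
}

#: Family base log ratios (alternating active- and inactive-leaning).
DEFAULT_FAMILY_BASES = [-1.2, 1.0, -0.8, 1.4, -1.5, 0.8, -1.0, 1.2]

#: Species record mix: jack bean dominates, a tail of other ureases.
DEFAULT_SPECIES_WEIGHTS = {
    "Canavalia ensiformis": 0.68,
    "unknown": 0.12,
    "Helicobacter pylori": 0.10,
    "Sporosarcina pasteurii": 0.07,
    "Canavalia gladiata": 0.03,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults are the package's study conditions."""

    n_compounds: int = 300
    n_families: int = 6
    core_scaffolds: tuple[str, ...] = tuple(DEFAULT_CORES)
    substituent_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUENT_EFFECTS)
    )
    family_base_log_ratio: tuple[float, ...] = tuple(DEFAULT_FAMILY_BASES)
    cliff_fraction: float = 0.05
    #: planted cliffs only involve compounds whose |log ratio| is at least
    #: this margin, so both sides of a cliff sit clearly off the cutoff
    cliff_margin: float = 0.6
    noise_sd: float = 0.3
    duplicate_rate: float = 0.15
    qualitative_inactive_rate: float = 0.05
    species_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_WEIGHTS)
    )
    control_um: float = 20.0
    missing_control_rate: float = 0.1
    year_range: tuple[int, int] = (1990, 2021)
    #: substituent combination that triggers the planted rule bonus
    rule_substituents: tuple[str, str] = ("S", "S(=O)(=O)N")
    rule_shift: float = -4.0
    seed: int = 0

    @classmethod
    def rule_planted(
        cls, n_compounds: int = 240, noise_sd: float = 0.0, seed: int = 0
    ) -> "SyntheticConfig":
        """A configuration where the planted rule is the dominant signal.

        All family bases are inactive-leaning and substituent effects are
        damped, so the only actives are compounds carrying the rule
        substituent pair. This is the study condition for rule-extraction
        checks; the default configuration, where family potency dominates,
        is the study condition for cliff and clustering checks.
        """
        return cls(
            n_compounds=n_compounds,
            family_base_log_ratio=(1.0,) * len(DEFAULT_CORES),
            substituent_effects={
                k: 0.3 * v for k, v in DEFAULT_SUBSTITUENT_EFFECTS.items()
            },
            cliff_fraction=0.0,
            noise_sd=noise_sd,
            seed=seed,
        )

    def __post_init__(self):
        if self.n_compounds < 1 or self.n_families < 1:
            raise ValueError("need at least one compound and one family")
        if self.n_families > len(self.core_scaffolds):
            raise ValueError("more families than core scaffolds")
        if self.n_families > len(self.family_base_log_ratio):
            raise ValueError("more families than base log ratios")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, p in [
            ("cliff_fraction", self.cliff_fraction),
            ("duplicate_rate", self.duplicate_rate),
            ("qualitative_inactive_rate", self.qualitative_inactive_rate),
            ("missing_control_rate", self.missing_control_rate),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


#: Descriptor conditions equivalent to carrying both rule substituents.
PLANTED_RULE_CONDITIONS = (("fr_SH", ">", 0.0), ("fr_sulfonamd", ">", 0.0))
PLANTED_RULE_CLASS = "active"


@dataclass
class PlantedTruth:
    """Ground truth for a generated library, keyed by final InChIKey."""

    compounds: pd.DataFrame  # inchikey, smiles, family_id, true_log_ratio, true_class
    cliff_pairs: list[tuple[str, str]]
    rule_conditions: tuple = PLANTED_RULE_CONDITIONS
    rule_class: str = PLANTED_RULE_CLASS

    def class_of(self) -> dict[str, str]:
        return dict(zip(self.compounds["inchikey"], self.compounds["true_class"]))


def _single_substituent_change(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return (a[0] == b[0]) != (a[1] == b[1])


def generate_library(
    config: SyntheticConfig | None = None,
) -> tuple[list[RawActivityRecord], PlantedTruth]:
    """Generate a raw bioassay record table plus its planted truth.

    Deterministic for a fixed config (one seeded generator drives every
    draw). Compounds are core x substituent x substituent enumerations,
    allocated round-robin to families; activity values are
    ``control * exp(true_log_ratio + noise)``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    subs = sorted(cfg.substituent_effects)
    eff = cfg.substituent_effects
    n_per_family = math.ceil(cfg.n_compounds / cfg.n_families)
    n_combos = len(subs) ** 2
    if n_per_family > n_combos:
        raise ValueError(
            f"requested {n_per_family} compounds/family but only {n_combos} "
            "core x substituent combinations exist"
        )

    # --- build compounds and their true log ratios
    compounds = []  # dicts with smiles, family, combo, log_ratio, rule_hit
    seen_keys: set[str] = set()
    for fam in range(cfg.n_families):
        template = cfg.core_scaffolds[fam]
        base = cfg.family_base_log_ratio[fam]
        # the rule substituent pair is always represented in every family so
        # the planted conjunction has support wherever it is evaluated
        rule_combos = [
            ia * len(subs) + ib
            for ia in range(len(subs))
            for ib in range(len(subs))
            if {subs[ia], subs[ib]} == set(cfg.rule_substituents)
        ]
        sampled = [int(c) for c in rng.permutation(n_combos) if int(c) not in rule_combos]
        combo_order = (rule_combos + sampled)[:n_per_family]
        for combo in combo_order:
            ia, ib = divmod(int(combo), len(subs))
            sub_a, sub_b = subs[ia], subs[ib]
            smiles = template.format(a=sub_a, b=sub_b)
            canonical, inchikey = standardize_structure(smiles)
            if inchikey in seen_keys:  # symmetric combos can collide
                continue
            seen_keys.add(inchikey)
            rule_hit = {sub_a, sub_b} >= set(cfg.rule_substituents)
            log_ratio = base + eff[sub_a] + eff[sub_b]
            if rule_hit:
                log_ratio += cfg.rule_shift
            compounds.append(
                {
                    "inchikey": inchikey,
                    "smiles": canonical,
                    "family_id": fam,
                    "combo": (ia, ib),
                    "true_log_ratio": log_ratio,
                    "rule_hit": rule_hit,
                }
            )
    compounds = compounds[: cfg.n_compounds] if len(compounds) > cfg.n_compounds else compounds

    # --- plant cliffs by flipping signs (never on rule compounds, never on
    # near-cutoff compounds where the flip would be meaningless)
    n_flips = int(round(cfg.cliff_fraction * len(compounds)))
    flippable = [
        i
        for i, c in enumerate(compounds)
        if not c["rule_hit"] and abs(c["true_log_ratio"]) >= cfg.cliff_margin
    ]
    flipped_idx = set(
        rng.choice(flippable, size=min(n_flips, len(flippable)), replace=False).tolist()
    )
    for i in flipped_idx:
        compounds[i]["true_log_ratio"] *= -1.0

    for c in compounds:
        c["true_class"] = "active" if c["true_log_ratio"] < 0 else "inactive"

    # --- verify planted cliff pairs on the final structures
    fps = chemspace.fingerprints([c["smiles"] for c in compounds])
    cliff_pairs: list[tuple[str, str]] = []
    for i in sorted(flipped_idx):
        for j, other in enumerate(compounds):
            if j == i or other["family_id"] != compounds[i]["family_id"]:
                continue
            if not _single_substituent_change(compounds[i]["combo"], other["combo"]):
                continue
            if other["true_class"] == compounds[i]["true_class"]:
                continue
            if abs(other["true_log_ratio"]) < cfg.cliff_margin:
                continue
            if chemspace.tanimoto(fps[i], fps[j]) > 0.6:
                pair = tuple(sorted((compounds[i]["inchikey"], other["inchikey"])))
                if pair not in cliff_pairs:
                    cliff_pairs.append(pair)

    # --- emit records
    species_labels = list(cfg.species_weights)
    species_p = np.array([cfg.species_weights[s] for s in species_labels], dtype=float)
    species_p /= species_p.sum()
    ref_controls = {}  # reference -> control concentration
    records: list[RawActivityRecord] = []
    rid = 0
    for c in compounds:
        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        n_records = 1 + int(rng.random() < cfg.duplicate_rate)
        qualitative = (
            c["true_class"] == "inactive"
            and rng.random() < cfg.qualitative_inactive_rate
        )
        for rep in range(n_records):
            rid += 1
            ref = f"ref_{c['family_id']}_{int(rng.integers(0, 3))}"
            if ref not in ref_controls:
                # heterogeneous controls around the thiourea-typical value
                ref_controls[ref] = float(
                    rng.choice([cfg.control_um, cfg.control_um * 0.75, cfg.control_um * 1.25])
                )
            control = ref_controls[ref]
            # the control can only be unreported where it equals the global
            # fallback, so normalization stays exact
            report_control: float | None = control
            if control == cfg.control_um and rng.random() < cfg.missing_control_rate:
                report_control = None
            species = str(rng.choice(species_labels, p=species_p))
            if qualitative and rep == 0:
                records.append(
                    RawActivityRecord(
                        record_id=f"r{rid:05d}",
                        smiles=c["smiles"],
                        activity_value=None,
                        activity_type="qualitative_inactive",
                        control_value=report_control,
                        species=species,
                        year=year,
                        reference_id=ref,
                    )
                )
                continue
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            value = control * math.exp(c["true_log_ratio"] + noise)
            records.append(
                RawActivityRecord(
                    record_id=f"r{rid:05d}",
                    smiles=c["smiles"],
                    activity_value=value,
                    activity_type=str(rng.choice(["IC50", "Ki"], p=[0.8, 0.2])),
                    control_value=report_control,
                    species=species,
                    year=year + (rep and int(rng.integers(0, 4))),
                    reference_id=ref if rep == 0 else f"{ref}_dup{rep}",
                )
            )

    truth = PlantedTruth(
        compounds=pd.DataFrame(
            [
                {
                    "inchikey": c["inchikey"],
                    "smiles": c["smiles"],
                    "family_id": c["family_id"],
                    "true_log_ratio": c["true_log_ratio"],
                    "true_class": c["true_class"],
                }
                for c in compounds
            ]
        ),
        cliff_pairs=cliff_pairs,
    )
    return records, truth


def evaluate_recovery(
    truth: PlantedTruth,
    curated: pd.DataFrame | None = None,
    pairs: pd.DataFrame | None = None,
    cluster_labels: dict[str, int] | None = None,
    rules: Sequence | None = None,
) -> dict:
    """Compare pipeline outputs against planted truth.

    Returns a dict with whichever metrics the supplied outputs allow:

    * ``class_accuracy`` and a confusion count dict (curated vs true class);
    * ``cliff_recall`` = planted cliff pairs found / planted (1.0 when none
      were planted) and ``cliff_precision`` = found-and-planted / found
      (coincidental unplanned cliffs lower precision, not recall);
    * ``family_agreement`` = adjusted Rand index of cluster labels vs
      planted families;
    * ``rule_recovered`` = some extracted rule matches the planted
      descriptor conjunction verbatim (order-insensitive).
    """
    out: dict = {}
    if curated is not None:
        merged = curated.merge(truth.compounds, on="inchikey", how="inner")
        if len(merged) != len(curated):
            raise KeyError(
                f"{len(curated) - len(merged)} curated compounds missing from truth"
            )
        confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for pred, true in zip(merged["activity_class"], merged["true_class"]):
            if true == "active":
                confusion["tp" if pred == "active" else "fn"] += 1
            else:
                confusion["fp" if pred == "active" else "tn"] += 1
        out["confusion"] = confusion
        out["class_accuracy"] = (confusion["tp"] + confusion["tn"]) / len(merged)
    if pairs is not None:
        found = {
            tuple(sorted((a, b)))
            for a, b, cat in zip(pairs["inchikey_a"], pairs["inchikey_b"], pairs["category"])
            if cat == "cliff"
        }
        planted = {tuple(sorted(p)) for p in truth.cliff_pairs}
        out["cliff_recall"] = (
            len(found & planted) / len(planted) if planted else 1.0
        )
        out["cliff_precision"] = len(found & planted) / len(found) if found else 0.0
        out["n_planted_cliffs"] = len(planted)
        out["n_found_cliffs"] = len(found)
    if cluster_labels is not None:
        keys = [k for k in truth.compounds["inchikey"] if k in cluster_labels]
        if not keys:
            raise KeyError("no overlap between cluster labels and truth")
        fam = truth.compounds.set_index("inchikey").loc[keys, "family_id"]
        out["family_agreement"] = float(
            adjusted_rand_score(fam.to_numpy(), [cluster_labels[k] for k in keys])
        )
    if rules is not None:
        planted_conditions = {
            (name, cmp_, float(thr)) for name, cmp_, thr in truth.rule_conditions
        }
        out["rule_recovered"] = any(
            r.predicted_class == truth.rule_class
            and {(c.feature, c.comparator, float(c.threshold)) for c in r.conditions}
            == planted_conditions
            for r in rules
        )
    return out
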