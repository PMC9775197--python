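"""Physicochemical descriptors, drug-likeness and structural-alert filters,
functional-group census, temporal trends and cross-species concordance.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Fragments, Lipinski, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from ._utils import pct
from .curation import StructureError

logger = logging.getLogger(__name__)

#: Descriptor schema; every compound gets exactly these keys.
DESCRIPTOR_NAMES = [
    "MolWt",
    "MolLogP",
    "NumHDonors",
    "NumHAcceptors",
    "TPSA",
    "NumRotatableBonds",
    "NumAromaticRings",
    "BertzCT",
    "MolMR",
    "ESOL",
    "fr_NH1",
    "fr_NH0",
    "fr_Ar_OH",
    "fr_Al_OH",
    "fr_N_O",
    "fr_Ar_N",
    "fr_aryl_methyl",
    "fr_hdrzine",
    "fr_sulfonamd",
    "fr_SH",
]

#: Integer-valued descriptors (counts); used by rule rendering.
COUNT_DESCRIPTORS = frozenset(
    ["NumHDonors", "NumHAcceptors", "NumRotatableBonds", "NumAromaticRings"]
    + [n for n in DESCRIPTOR_NAMES if n.startswith("fr_")]
)


def _esol(mol: Chem.Mol, logp: float, mw: float, rotb: int) -> float:
    # Delaney-style estimated aqueous solubility (log mol/L)
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotb - 0.74 * ap


def compute_descriptors(smiles: str) -> dict[str, float]:
    """2-D descriptor vector (schema :data:`DESCRIPTOR_NAMES`) for one compound."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rotb = Lipinski.NumRotatableBonds(mol)
    return {
        "MolWt": mw,
        "MolLogP": logp,
        "NumHDonors": Lipinski.NumHDonors(mol),
        "NumHAcceptors": Lipinski.NumHAcceptors(mol),
        "TPSA": rdMolDescriptors.CalcTPSA(mol),
        "NumRotatableBonds": rotb,
        "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "BertzCT": Descriptors.BertzCT(mol),
        "MolMR": Crippen.MolMR(mol),
        "ESOL": _esol(mol, logp, mw, rotb),
        "fr_NH1": Fragments.fr_NH1(mol),
        "fr_NH0": Fragments.fr_NH0(mol),
        "fr_Ar_OH": Fragments.fr_Ar_OH(mol),
        "fr_Al_OH": Fragments.fr_Al_OH(mol),
        "fr_N_O": Fragments.fr_N_O(mol),
        "fr_Ar_N": Fragments.fr_Ar_N(mol),
        "fr_aryl_methyl": Fragments.fr_aryl_methyl(mol),
        "fr_hdrzine": Fragments.fr_hdrzine(mol),
        "fr_sulfonamd": Fragments.fr_sulfonamd(mol),
        "fr_SH": Fragments.fr_SH(mol),
    }


def descriptor_table(smiles_list: Sequence[str], index=None) -> pd.DataFrame:
    """Descriptor vectors for many compounds, one row each."""
    df = pd.DataFrame([compute_descriptors(s) for s in smiles_list], index=index)
    return df[DESCRIPTOR_NAMES]


# ---------------------------------------------------------------------------
# drug-likeness and structural alerts

LIPINSKI_VIOLATION_LABELS = ("MW>500", "logP>5", "hbd>5", "hba>10")


def lipinski_filter(
    descriptors: Mapping[str, float], max_violations: int = 0
) -> tuple[bool, list[str]]:
    """Rule-of-5 check on a descriptor vector.

    A limit value itself is compliant (MW exactly 500 passes). The strict
    reading (zero violations allowed) is the default; ``max_violations=1``
    selects the classic <=1-violation variant.
    """
    violations = []
    if descriptors["MolWt"] > 500:
        violations.append("MW>500")
    if descriptors["MolLogP"] > 5:
        violations.append("logP>5")
    if descriptors["NumHDonors"] > 5:
        violations.append("hbd>5")
    if descriptors["NumHAcceptors"] > 10:
        violations.append("hba>10")
    return len(violations) <= max_violations, violations


_CATALOG_CACHE: dict[str, object] = {}


def _builtin_catalog(name: str) -> FilterCatalog:
    if name not in _CATALOG_CACHE:
        params = FilterCatalogParams()
        params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, name))
        _CATALOG_CACHE[name] = FilterCatalog(params)
    return _CATALOG_CACHE[name]


def load_smarts_catalog(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Load a ``name<TAB>SMARTS`` alert/group catalog file.

    Lines starting with ``#`` and blank lines are skipped; a malformed
    SMARTS raises at load time.
    """
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, smarts = line.split("\t")
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 'name<TAB>SMARTS'") from None
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"{path}:{lineno}: malformed SMARTS {smarts!r}")
        patterns.append((name, query))
    return patterns


def structural_alerts(smiles: str, catalog: str | Path = "Brenk") -> list[str]:
    """Names of alert substructures found in a compound.

    ``catalog`` is ``"PAINS"`` or ``"Brenk"`` (the curated catalogs shipped
    with RDKit, pinned by the installed RDKit version) or a path to a
    ``name<TAB>SMARTS`` file. Names are returned in catalog order.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    if str(catalog) in ("PAINS", "Brenk"):
        cat = _builtin_catalog({"PAINS": "PAINS", "Brenk": "BRENK"}[str(catalog)])
        return [
            cat.GetEntry(i).GetDescription()
            for i in range(cat.GetNumEntries())
            if cat.GetEntry(i).HasFilterMatch(mol)
        ]
    key = f"file:{catalog}"
    if key not in _CATALOG_CACHE:
        _CATALOG_CACHE[key] = load_smarts_catalog(catalog)
    return [name for name, query in _CATALOG_CACHE[key] if mol.HasSubstructMatch(query)]


def filter_report(
    curated: pd.DataFrame,
    descriptors: pd.DataFrame | None = None,
    max_violations: int = 0,
) -> pd.DataFrame:
    """Per-compound Lipinski + PAINS + Brenk report.

    Columns: ``inchikey, lipinski_pass, lipinski_violations, pains_alerts,
    brenk_alerts, clean`` where ``clean`` means no alert from either catalog
    (the dual-filter survival criterion). Alert lists are ';'-joined.
    """
    if descriptors is None:
        descriptors = descriptor_table(curated["canonical_smiles"])
    rows = []
    for (_, comp), (_, desc) in zip(curated.iterrows(), descriptors.iterrows()):
        ok, violations = lipinski_filter(desc, max_violations)
        pains = structural_alerts(comp["canonical_smiles"], "PAINS")
        brenk = structural_alerts(comp["canonical_smiles"], "Brenk")
        rows.append(
            {
                "inchikey": comp["inchikey"],
                "lipinski_pass": ok,
                "lipinski_violations": ";".join(violations),
                "pains_alerts": ";".join(pains),
                "brenk_alerts": ";".join(brenk),
                "clean": not pains and not brenk,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["inchikey", "lipinski_pass", "lipinski_violations", "pains_alerts", "brenk_alerts", "clean"],
    )


# ---------------------------------------------------------------------------
# censuses and trends

def default_group_catalog() -> list[tuple[str, Chem.Mol]]:
    """The bundled functional-family SMARTS catalog (editable data file)."""
    path = resources.files("ureascape.data") / "groups.smarts"
    return load_smarts_catalog(path)


def group_census(
    curated: pd.DataFrame,
    groups: Mapping[str, str] | list[tuple[str, Chem.Mol]] | None = None,
) -> pd.DataFrame:
    """Per-group compound counts and active share.

    ``groups`` maps name -> SMARTS (or pre-parsed queries); defaults to the
    bundled family catalog. Each compound counts once per group regardless
    of how many times the pattern matches.
    Columns: ``group, n_compounds, n_active, pct_active``.
    """
    if groups is None:
        groups = default_group_catalog()
    if isinstance(groups, Mapping):
        parsed = []
        for name, smarts in groups.items():
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"malformed SMARTS for group {name!r}: {smarts!r}")
            parsed.append((name, query))
        groups = parsed
    mols = [Chem.MolFromSmiles(s) for s in curated["canonical_smiles"]]
    active = (curated["activity_class"] == "active").to_numpy()
    rows = []
    for name, query in groups:
        hits = [i for i, m in enumerate(mols) if m is not None and m.HasSubstructMatch(query)]
        n = len(hits)
        n_act = int(active[hits].sum()) if hits else 0
        rows.append(
            {"group": name, "n_compounds": n, "n_active": n_act, "pct_active": pct(n_act, n)}
        )
    return pd.DataFrame(rows, columns=["group", "n_compounds", "n_active", "pct_active"])


def temporal_trends(curated: pd.DataFrame) -> pd.DataFrame:
    """Per-year compound counts and active percentage.

    Compounds without a first_year aggregate under the label ``"unknown"``.
    Columns: ``year, n_compounds, n_active, pct_active``; years ascending,
    unknown last.
    """
    year = curated["first_year"]
    label = year.astype(object).where(year.notna(), "unknown")
    rows = []
    known = sorted({y for y in label if y != "unknown"})
    for y in known + (["unknown"] if (label == "unknown").any() else []):
        grp = curated[label == y]
        n_act = int((grp["activity_class"] == "active").sum())
        rows.append(
            {"year": y, "n_compounds": len(grp), "n_active": n_act, "pct_active": pct(n_act, len(grp))}
        )
    return pd.DataFrame(rows, columns=["year", "n_compounds", "n_active", "pct_active"])


def species_concordance(normalized: pd.DataFrame) -> tuple[int, int, float]:
    """Cross-species activity concordance on the pre-merge record table.

    A compound (InChIKey) measured in >= 2 distinct species is discordant
    when it is classified active in one species and inactive in another
    (per-species class = class of the most potent record in that species).
    Returns ``(n_multi_species, n_discordant, pct_discordant)``.
    """
    per_species = (
        normalized.groupby(["inchikey", "species"])["ratio"].min().reset_index()
    )
    per_species["activity_class"] = per_species["ratio"].apply(
        lambda r: "active" if r < 1 else "inactive"
    )
    n_multi = 0
    n_discordant = 0
    for _, grp in per_species.groupby("inchikey"):
        if grp["species"].nunique() < 2:
            continue
        n_multi += 1
        if grp["activity_class"].nunique() > 1:
            n_discordant += 1
    return n_multi, n_discordant, pct(n_discordant, n_multi)
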