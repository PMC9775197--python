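"""Fingerprints, Tanimoto similarity, scaffolds, 2-D embedding and
reference-library comparison.

Compounds are represented as 1024-bit Morgan (ECFP4-like, radius 2) binary
fingerprints; similarity is the Tanimoto coefficient Tc = |a AND b| / |a OR b|.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.manifold import TSNE

from .curation import StructureError, standardize_structure

logger = logging.getLogger(__name__)

N_BITS = 1024
RADIUS = 2

_generator = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


def morgan_fingerprint(smiles: str) -> DataStructs.ExplicitBitVect:
    """1024-bit, radius-2 Morgan fingerprint of a standardized SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    return _generator.GetFingerprint(mol)


def fingerprints(smiles_list: Sequence[str]) -> list[DataStructs.ExplicitBitVect]:
    return [morgan_fingerprint(s) for s in smiles_list]


def fingerprint_matrix(smiles_list: Sequence[str]) -> np.ndarray:
    """Fingerprints stacked as an (n, 1024) uint8 0/1 matrix."""
    mat = np.zeros((len(smiles_list), N_BITS), dtype=np.uint8)
    for i, fp in enumerate(fingerprints(smiles_list)):
        DataStructs.ConvertToNumpyArray(fp, row := np.zeros(N_BITS, dtype=np.int32))
        mat[i] = row.astype(np.uint8)
    return mat


def tanimoto(a: DataStructs.ExplicitBitVect, b: DataStructs.ExplicitBitVect) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints (molecules with no hashed environments) are
    defined as similarity 0, not 1.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        logger.warning("Tanimoto of two empty fingerprints; returning 0 by convention")
        return 0.0
    return DataStructs.TanimotoSimilarity(a, b)


def similarity_matrix(
    fps: Sequence[DataStructs.ExplicitBitVect],
) -> np.ndarray:
    """Symmetric all-vs-all Tanimoto matrix with unit diagonal."""
    n = len(fps)
    sim = np.ones((n, n), dtype=np.float64)
    empty = [fp.GetNumOnBits() == 0 for fp in fps]
    for i in range(n):
        if i + 1 < n:
            row = DataStructs.BulkTanimotoSimilarity(fps[i], list(fps[i + 1 :]))
            sim[i, i + 1 :] = row
            sim[i + 1 :, i] = row
        for j in range(i + 1, n):
            if empty[i] and empty[j]:
                sim[i, j] = sim[j, i] = 0.0
    return sim


def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold (ring systems + linkers) as canonical SMILES.

    Acyclic molecules have no scaffold and return the empty string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def embed_2d(
    fp_matrix: np.ndarray,
    seed: int = 0,
    perplexity: float | None = None,
) -> np.ndarray:
    """t-SNE embedding of fingerprints into 2-D, one (x, y) per compound.

    Deterministic for a fixed seed. Perplexity defaults to
    ``min(30, (n - 1) / 3)`` so small libraries embed without error.
    Coordinates are for visual reporting only; no downstream statistic may
    consume them.
    """
    n = len(fp_matrix)
    if n < 3:
        raise ValueError(f"need at least 3 compounds to embed, got {n}")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    )
    return tsne.fit_transform(fp_matrix.astype(np.float64))


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a reference library: one SMILES per line, optional tab-separated name."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out.append((parts[0], parts[1] if len(parts) > 1 else f"ref_{i}"))
    return out


def compare_to_reference(
    curated: pd.DataFrame,
    reference: Sequence[tuple[str, str]] | str | Path,
    threshold: float = 0.6,
) -> tuple[int, int, pd.DataFrame]:
    """Compare a curated set against a reference SMILES library.

    Exact overlap is InChIKey identity after the reference is standardized
    with the same pipeline as the dataset; a near neighbor has max Tc
    strictly above ``threshold`` to some reference compound without being an
    exact overlap. Returns ``(n_exact, n_near, per_compound)`` where
    ``per_compound`` has columns ``inchikey, max_tc, exact_overlap,
    near_neighbor``. Unparsable reference entries are skipped with a log line.
    """
    if not isinstance(reference, (list, tuple)):
        reference = read_smiles_file(reference)
    ref_keys: set[str] = set()
    ref_fps = []
    for smi, name in reference:
        try:
            canonical, key = standardize_structure(smi)
        except StructureError:
            logger.warning("skipping unparsable reference entry %r (%s)", smi, name)
            continue
        ref_keys.add(key)
        ref_fps.append(morgan_fingerprint(canonical))
    if not ref_fps:
        logger.warning("empty reference library; all comparisons report zero")
        per = pd.DataFrame(
            {
                "inchikey": curated["inchikey"],
                "max_tc": 0.0,
                "exact_overlap": False,
                "near_neighbor": False,
            }
        )
        return 0, 0, per

    rows = []
    for r in curated.itertuples():
        fp = morgan_fingerprint(r.canonical_smiles)
        if fp.GetNumOnBits() == 0:
            max_tc = 0.0
        else:
            max_tc = float(max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps)))
        exact = r.inchikey in ref_keys
        rows.append(
            {
                "inchikey": r.inchikey,
                "max_tc": max_tc,
                "exact_overlap": exact,
                "near_neighbor": (not exact) and max_tc > threshold,
            }
        )
    per = pd.DataFrame(rows, columns=["inchikey", "max_tc", "exact_overlap", "near_neighbor"])
    return int(per["exact_overlap"].sum()), int(per["near_neighbor"].sum()), per
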