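"""Hierarchical clustering of compound libraries.

Two complementary modes:

* **spontaneous** — complete-linkage agglomeration on Tanimoto distance
  (1 - Tc), cut so every intra-cluster pairwise distance stays below a
  threshold (default 0.6). The resulting number of clusters is a diversity
  statistic: many small clusters means a structurally diverse library.
* **family** — Ward linkage on Euclidean distance over the raw 1024-bit
  fingerprint vectors with a fixed cluster count k (typically scanned over
  20..80), giving broader structural families for inspection.

Each cluster is summarized by its size, minimum and median intracluster
Tanimoto similarity, percentage of actives, and a maximum-common-substructure
(MCS) scaffold computed with ring atoms restricted to match ring atoms.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._utils import pct

logger = logging.getLogger(__name__)

MCS_TIMEOUT_S = 60


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids to contiguous 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def spontaneous_clustering(
    similarity: np.ndarray, max_dist: float = 0.6
) -> tuple[np.ndarray, int]:
    """Complete-linkage clustering cut at a maximum Tanimoto distance.

    Guarantees every intra-cluster pairwise distance (1 - Tc) <= ``max_dist``.
    Returns ``(labels, n_clusters)``; labels are contiguous from 0 in order
    of first appearance. The cluster count is permutation-invariant.
    """
    n = len(similarity)
    if n == 1:
        return np.zeros(1, dtype=np.int64), 1
    dist = 1.0 - np.asarray(similarity, dtype=np.float64)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=max_dist, criterion="distance")
    labels = _relabel(labels)
    return labels, int(labels.max()) + 1


def family_clustering(fp_matrix: np.ndarray, k: int) -> np.ndarray:
    """Ward/Euclidean clustering of raw bit vectors into exactly k families."""
    n = len(fp_matrix)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    Z = linkage(fp_matrix.astype(np.float64), method="ward")
    return _relabel(fcluster(Z, t=k, criterion="maxclust"))


def cluster_summary(
    member_idx: Sequence[int],
    similarity: np.ndarray,
    classes: Sequence[str],
) -> dict:
    """Cohesion and activity statistics for one cluster.

    min/median intracluster Tc are taken over all unordered member pairs;
    a singleton has min = median = 1.0 by convention (a cluster of one
    compound is perfectly self-similar).
    """
    idx = np.asarray(member_idx)
    if len(idx) == 0:
        raise ValueError("cluster must have at least one member")
    if len(idx) == 1:
        min_tc = median_tc = 1.0
    else:
        sub = similarity[np.ix_(idx, idx)]
        pair_tcs = sub[np.triu_indices(len(idx), k=1)]
        min_tc = float(pair_tcs.min())
        median_tc = float(np.median(pair_tcs))
    n_active = sum(1 for i in idx if classes[i] == "active")
    return {
        "size": int(len(idx)),
        "min_intra_tc": min_tc,
        "median_intra_tc": median_tc,
        "n_active": int(n_active),
        "pct_active": pct(n_active, len(idx)),
    }


def cluster_mcs(
    smiles_list: Sequence[str], timeout_s: int = MCS_TIMEOUT_S
) -> tuple[str, int]:
    """Maximum common substructure of a cluster as (SMARTS, heavy-atom count).

    Ring atoms only match ring atoms, so the MCS behaves as a data-driven
    scaffold. On timeout or when no common substructure exists the result
    is ``("", 0)`` — flagged, never an exception.
    """
    if len(smiles_list) < 2:
        raise ValueError("MCS needs at least 2 molecules")
    mols = [Chem.MolFromSmiles(s) for s in smiles_list]
    if any(m is None for m in mols):
        raise ValueError("unparsable SMILES in cluster")
    res = rdFMCS.FindMCS(
        mols,
        ringMatchesRingOnly=True,
        timeout=timeout_s,
    )
    if res.canceled:
        logger.warning("MCS timed out after %ds on %d molecules", timeout_s, len(mols))
    if not res.smartsString or res.numAtoms < 1:
        return "", 0
    return res.smartsString, int(res.numAtoms)


def summarize_clusters(
    labels: np.ndarray,
    similarity: np.ndarray,
    classes: Sequence[str],
    smiles: Sequence[str] | None = None,
    mcs_timeout_s: int = MCS_TIMEOUT_S,
) -> pd.DataFrame:
    """One summary row per cluster, sorted by cluster id.

    Columns: ``cluster_id, size, min_intra_tc, median_intra_tc, n_active,
    pct_active`` plus ``mcs_smarts, mcs_n_atoms`` when SMILES are given
    (singletons report their own structure's heavy-atom count with an empty
    SMARTS).
    """
    rows = []
    for cid in range(int(labels.max()) + 1):
        idx = np.flatnonzero(labels == cid)
        row = {"cluster_id": cid, **cluster_summary(idx, similarity, classes)}
        if smiles is not None:
            if len(idx) >= 2:
                smarts, n_atoms = cluster_mcs([smiles[i] for i in idx], mcs_timeout_s)
            else:
                smarts, n_atoms = "", Chem.MolFromSmiles(smiles[idx[0]]).GetNumHeavyAtoms()
            row["mcs_smarts"] = smarts
            row["mcs_n_atoms"] = n_atoms
        rows.append(row)
    return pd.DataFrame(rows)


def select_k(
    fp_matrix: np.ndarray,
    similarity: np.ndarray,
    classes: Sequence[str],
    k_range: range = range(20, 81),
    min_cluster_size: int = 3,
    cohesive_tc: float = 0.5,
    force_k: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Scan family-cluster counts and pick one by a codified heuristic.

    For each k the diagnostics report the smallest and largest cluster size
    and how many clusters are cohesive (min intracluster Tc >=
    ``cohesive_tc``). The chosen k maximizes the number of cohesive clusters
    among k whose smallest cluster has >= ``min_cluster_size`` members
    (falling back to all k when none qualifies); ties go to the smallest k.
    ``force_k`` overrides the heuristic but still returns the diagnostics,
    so a human can inspect and decide differently.
    """
    n = len(fp_matrix)
    if n <= max(k_range):
        raise ValueError(f"need more than {max(k_range)} compounds, got {n}")
    rows = []
    for k in k_range:
        labels = family_clustering(fp_matrix, k)
        summaries = [
            cluster_summary(np.flatnonzero(labels == cid), similarity, classes)
            for cid in range(k)
        ]
        sizes = [s["size"] for s in summaries]
        rows.append(
            {
                "k": k,
                "min_cluster_size": min(sizes),
                "max_cluster_size": max(sizes),
                "n_cohesive": sum(1 for s in summaries if s["min_intra_tc"] >= cohesive_tc),
            }
        )
    diagnostics = pd.DataFrame(rows, columns=["k", "min_cluster_size", "max_cluster_size", "n_cohesive"])
    if force_k is not None:
        return force_k, diagnostics
    eligible = diagnostics[diagnostics["min_cluster_size"] >= min_cluster_size]
    if eligible.empty:
        eligible = diagnostics
    best = eligible.sort_values(["n_cohesive", "k"], ascending=[False, True], kind="mergesort").iloc[0]
    return int(best["k"]), diagnostics
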