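"""Activity-cliff landscape: similar-pair enumeration, SAR categories, and
safe-bet / dead-end hub profiling.

A *pair* is two curated compounds with Tanimoto similarity strictly above a
threshold (default 0.6). Each pair is either a linear-SAR pair (both active
or both inactive) or an *activity cliff* (opposite classes despite high
structural similarity). Hubs that form many cliff pairs are profiled:

* **dead end** — an active compound whose close analogues are mostly
  inactive (modifying it tends to lose activity);
* **safe bet** — an inactive compound with many active close analogues
  (modifying it tends to gain activity).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import chemspace

PAIR_COLUMNS = ["inchikey_a", "inchikey_b", "tc", "category", "ratio_fold"]
CATEGORIES = ("both_active", "both_inactive", "cliff")


def enumerate_similar_pairs(
    curated: pd.DataFrame,
    threshold: float = 0.6,
    similarity: np.ndarray | None = None,
) -> pd.DataFrame:
    """All unordered compound pairs with Tc strictly above ``threshold``.

    Pairs are keyed ``inchikey_a < inchikey_b`` and categorized from the two
    activity classes; ``ratio_fold`` is the fold difference of the two
    normalized ratios (always >= 1). A precomputed similarity matrix (rows
    aligned with ``curated``) avoids refingerprinting.
    """
    keys = curated["inchikey"].to_numpy()
    classes = curated["activity_class"].to_numpy()
    ratios = curated["ratio"].to_numpy(dtype=float)
    if similarity is None:
        fps = chemspace.fingerprints(curated["canonical_smiles"])
        similarity = chemspace.similarity_matrix(fps)
    n = len(curated)
    ii, jj = np.triu_indices(n, k=1)
    mask = similarity[ii, jj] > threshold
    rows = []
    for i, j in zip(ii[mask], jj[mask]):
        a, b = (i, j) if keys[i] < keys[j] else (j, i)
        if classes[i] != classes[j]:
            category = "cliff"
        elif classes[i] == "active":
            category = "both_active"
        else:
            category = "both_inactive"
        hi, lo = max(ratios[i], ratios[j]), min(ratios[i], ratios[j])
        rows.append(
            {
                "inchikey_a": keys[a],
                "inchikey_b": keys[b],
                "tc": float(similarity[i, j]),
                "category": category,
                "ratio_fold": hi / lo,
            }
        )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs.sort_values(["inchikey_a", "inchikey_b"], kind="mergesort").reset_index(drop=True)


def pair_category_counts(pairs: pd.DataFrame) -> dict[str, int]:
    """Counts per SAR category; the three categories partition all pairs."""
    counts = pairs["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def cliff_profiles(
    pairs: pd.DataFrame,
    classes: pd.Series | dict,
    min_degree: int = 10,
) -> pd.DataFrame:
    """Profile every compound appearing in at least one cliff pair.

    ``cliff_degree`` counts opposite-class cliff partners. A compound with
    degree >= ``min_degree`` is a ``dead_end`` when active and a
    ``safe_bet`` when inactive; below the threshold the role is ``none``.
    Sorted by degree descending, then InChIKey.
    """
    if isinstance(classes, pd.Series):
        classes = classes.to_dict()
    cliff = pairs[pairs["category"] == "cliff"]
    degree: dict[str, int] = {}
    for a, b in zip(cliff["inchikey_a"], cliff["inchikey_b"]):
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    rows = []
    for key, deg in degree.items():
        cls = classes[key]
        if deg >= min_degree:
            role = "dead_end" if cls == "active" else "safe_bet"
        else:
            role = "none"
        rows.append(
            {"inchikey": key, "activity_class": cls, "cliff_degree": deg, "role": role}
        )
    profiles = pd.DataFrame(rows, columns=["inchikey", "activity_class", "cliff_degree", "role"])
    return profiles.sort_values(
        ["cliff_degree", "inchikey"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def top_cliffs(pairs: pd.DataFrame, n: int) -> pd.DataFrame:
    """The n most significant cliff pairs, ranked by activity fold change.

    Ties break on Tc descending, then on the pair key — fully deterministic.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    cliff = pairs[pairs["category"] == "cliff"]
    ranked = cliff.sort_values(
        ["ratio_fold", "tc", "inchikey_a", "inchikey_b"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return ranked.head(n).reset_index(drop=True)
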