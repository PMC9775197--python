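import itertools

import numpy as np
import pytest
from rdkit import Chem

from ureascape import chemspace, clustering
from ureascape.clustering import (
    cluster_mcs,
    cluster_summary,
    family_clustering,
    select_k,
    spontaneous_clustering,
    summarize_clusters,
)
from ureascape.synthetic import SyntheticConfig, generate_library


def brute_force_complete_linkage(dist: np.ndarray, threshold: float) -> int:
    """Naive agglomerative complete linkage, merging until no pair of
    clusters has maximum inter-cluster distance <= threshold."""
    clusters = [{i} for i in range(len(dist))]
    while True:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if d <= threshold and (best is None or d < best[0]):
                best = (d, a, b)
        if best is None:
            return len(clusters)
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]


class TestSpontaneousClustering:
    def test_identical_compounds_single_cluster(self):
        sim = np.ones((4, 4))
        labels, n = spontaneous_clustering(sim)
        assert n == 1 and set(labels) == {0}

    def test_distant_pair_splits(self):
        sim = np.array([[1.0, 0.3], [0.3, 1.0]])  # distance 0.7 > 0.6
        _, n = spontaneous_clustering(sim, max_dist=0.6)
        assert n == 2

    def test_matches_brute_force_oracle(self):
        # 6 compounds in 3 planted structural groups
        smiles = ["CCO", "CCCO", "c1ccccc1O", "c1ccccc1N", "CC(=O)NC", "CC(=O)NCC"]
        sim = chemspace.similarity_matrix(chemspace.fingerprints(smiles))
        labels, n = spontaneous_clustering(sim, max_dist=0.6)
        expected = brute_force_complete_linkage(1.0 - sim, 0.6)
        assert n == expected

    def test_intra_cluster_distances_bounded(self, noiseless_curated):
        curated, _, _ = noiseless_curated
        sim = chemspace.similarity_matrix(
            chemspace.fingerprints(curated["canonical_smiles"][:60])
        )
        labels, n = spontaneous_clustering(sim, max_dist=0.6)
        for cid in range(n):
            idx = np.flatnonzero(labels == cid)
            for i in idx:
                for j in idx:
                    assert 1.0 - sim[i, j] <= 0.6 + 1e-12

    def test_threshold_extremes(self):
        smiles = ["CCO", "CCCO", "c1ccccc1O", "c1ccccc1N", "CC(=O)NC"]
        sim = chemspace.similarity_matrix(chemspace.fingerprints(smiles))
        _, n_zero = spontaneous_clustering(sim, max_dist=0.0)
        assert n_zero == len(smiles)  # all fingerprints distinct
        _, n_one = spontaneous_clustering(sim, max_dist=1.0)
        assert n_one == 1

    def test_count_permutation_invariant(self, noiseless_curated):
        curated, _, _ = noiseless_curated
        sim = chemspace.similarity_matrix(
            chemspace.fingerprints(curated["canonical_smiles"][:40])
        )
        _, n = spontaneous_clustering(sim)
        rng = np.random.default_rng(0)
        perm = rng.permutation(40)
        _, n_perm = spontaneous_clustering(sim[np.ix_(perm, perm)])
        assert n == n_perm


class TestFamilyClustering:
    def test_k_equals_n_gives_singletons(self):
        mat = chemspace.fingerprint_matrix(["CCO", "CCCO", "c1ccccc1", "CC(=O)O"])
        labels = family_clustering(mat, k=4)
        assert sorted(labels) == [0, 1, 2, 3]

    def test_two_planted_families_recovered(self):
        from ureascape.synthetic import DEFAULT_CORES

        # two well-separated chemotypes: diaryl thiourea vs methylfuran amide
        cfg = SyntheticConfig(
            n_compounds=40,
            n_families=2,
            core_scaffolds=(DEFAULT_CORES[4], DEFAULT_CORES[5]),
            noise_sd=0.0,
            seed=9,
        )
        _, truth = generate_library(cfg)
        mat = chemspace.fingerprint_matrix(truth.compounds["smiles"])
        labels = family_clustering(mat, k=2)
        fam = truth.compounds["family_id"].to_numpy()
        # agreement up to label swap
        direct = (labels == fam).mean()
        assert max(direct, 1 - direct) == 1.0

    def test_partition(self, noiseless_curated):
        curated, _, _ = noiseless_curated
        mat = chemspace.fingerprint_matrix(curated["canonical_smiles"][:50])
        labels = family_clustering(mat, k=5)
        assert len(labels) == 50
        assert set(labels) == set(range(5))

    def test_invalid_k(self):
        mat = chemspace.fingerprint_matrix(["CCO", "CCC"])
        with pytest.raises(ValueError):
            family_clustering(mat, k=3)


@pytest.fixture(scope="module")
def small_space(noiseless_curated):
    curated, _, _ = noiseless_curated
    smiles = curated["canonical_smiles"][:40].tolist()
    mat = chemspace.fingerprint_matrix(smiles)
    sim = chemspace.similarity_matrix(chemspace.fingerprints(smiles))
    classes = curated["activity_class"][:40].tolist()
    return mat, sim, classes


class TestSelectK:
    def test_diagnostics_cover_range(self, small_space):
        mat, sim, classes = small_space
        k, diagnostics = select_k(mat, sim, classes, k_range=range(3, 9))
        assert diagnostics["k"].tolist() == list(range(3, 9))
        assert 3 <= k <= 8

    def test_max_cluster_size_monotone(self, small_space):
        mat, sim, classes = small_space
        _, diagnostics = select_k(mat, sim, classes, k_range=range(3, 9))
        sizes = diagnostics["max_cluster_size"].tolist()
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_force_k_override(self, small_space):
        mat, sim, classes = small_space
        k, _ = select_k(mat, sim, classes, k_range=range(3, 9), force_k=5)
        assert k == 5


class TestClusterSummary:
    def test_singleton_convention(self):
        sim = np.eye(3)
        summary = cluster_summary([1], sim, ["active", "inactive", "active"])
        assert summary["min_intra_tc"] == summary["median_intra_tc"] == 1.0
        assert summary["pct_active"] == 0.0

    def test_pair(self):
        sim = np.array([[1.0, 0.4], [0.4, 1.0]])
        summary = cluster_summary([0, 1], sim, ["active", "active"])
        assert summary["min_intra_tc"] == summary["median_intra_tc"] == 0.4
        assert summary["pct_active"] == 100.0

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0, 1, size=(4, 4))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        summary = cluster_summary([0, 1, 2, 3], sim, ["active"] * 4)
        pairs = [sim[i, j] for i, j in itertools.combinations(range(4), 2)]
        assert len(pairs) == 6
        assert summary["min_intra_tc"] == pytest.approx(min(pairs))
        assert summary["median_intra_tc"] == pytest.approx(float(np.median(pairs)))


class TestClusterMCS:
    def test_identical_molecules_full_mcs(self):
        smarts, n_atoms = cluster_mcs(["c1ccccc1O", "c1ccccc1O"])
        assert n_atoms == 7

    def test_toluene_ethylbenzene_core(self):
        smarts, n_atoms = cluster_mcs(["Cc1ccccc1", "CCc1ccccc1"])
        assert n_atoms == 7  # methylbenzene common core

    def test_disjoint_molecules_flagged_empty(self):
        smarts, n_atoms = cluster_mcs(["C", "c1ccccc1"])
        assert (smarts, n_atoms) == ("", 0)

    def test_members_match_their_mcs(self, noiseless_curated):
        curated, _, _ = noiseless_curated
        smiles = curated["canonical_smiles"][:30].tolist()
        sim = chemspace.similarity_matrix(chemspace.fingerprints(smiles))
        labels, n = spontaneous_clustering(sim)
        summary = summarize_clusters(labels, sim, ["active"] * 30, smiles)
        checked = 0
        for row in summary.itertuples():
            if row.size < 2 or not row.mcs_smarts:
                continue
            query = Chem.MolFromSmarts(row.mcs_smarts)
            members = np.flatnonzero(labels == row.cluster_id)
            for i in members:
                assert Chem.MolFromSmiles(smiles[i]).HasSubstructMatch(query)
            checked += 1
        assert checked >= 1
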