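"""Map the chemical space of a synthetic inhibitor library.

Computes Morgan fingerprints, the Tanimoto similarity matrix, Murcko
scaffolds, the spontaneous-clustering diversity statistic and a 2-D t-SNE
embedding.
"""

import numpy as np

from ureascape import chemspace, clustering
from ureascape.curation import curate
from ureascape.synthetic import SyntheticConfig, generate_library

records, truth = generate_library(SyntheticConfig(n_compounds=150, seed=8))
curated, _, _ = curate(records)
smiles = curated["canonical_smiles"]

fps = chemspace.fingerprints(smiles)
sim = chemspace.similarity_matrix(fps)
scaffolds = {chemspace.murcko_scaffold(s) for s in smiles} - {""}
labels, n_clusters = clustering.spontaneous_clustering(sim, max_dist=0.6)
coords = chemspace.embed_2d(chemspace.fingerprint_matrix(smiles), seed=8)

iu = np.triu_indices(len(sim), k=1)
print(f"compounds:                 {len(curated)}")
print(f"distinct Murcko scaffolds: {len(scaffolds)}")
print(f"median pairwise Tc:        {np.median(sim[iu]):.3f}")
print(f"spontaneous clusters:      {n_clusters}  (every intra-cluster 1-Tc <= 0.6)")
print(f"embedding shape:           {coords.shape}")
print()
print("Few clusters relative to library size means structurally cohesive")
print("series; the t-SNE coordinates are for plotting only and never feed")
print("downstream statistics.")
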