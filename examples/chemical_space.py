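"""Map the chemical space of a metabolite collection.

Computes the nine structural descriptors, class-level z-scores, a Tanimoto
distance matrix, hierarchical clusters with per-cluster FIX enrichment, and
a 2-D classical MDS embedding of the labeled metabolites.
"""

from diazopred import (
    FingerprintConfig,
    SimConfig,
    compute_descriptors,
    fingerprint_dataset,
    generate_dataset,
    hierarchical_clusters,
    mds_embedding,
    tanimoto_distance_matrix,
    zscore_matrix,
)

dataset = generate_dataset(SimConfig(n_pos=20, n_neg=20, seed=7))
config = FingerprintConfig(n_bits=4096)  # smaller folding is fine for distances

vectors = {r.compound_id: compute_descriptors(r.smiles) for r in dataset}
groups = {r.compound_id: f"FIX={r.fix_label}" for r in dataset}

z = zscore_matrix(vectors, groups)
print("class-level descriptor z-scores (global standardization):")
print(z.round(2).to_string())
print("\npositive z = above the global average; diazotroph-associated")
print("metabolites run nitrogen/amide-rich, non-diazotroph ones halogen-rich.")

fps, _ = fingerprint_dataset(dataset, config)
distances = tanimoto_distance_matrix(fps)
labels = {r.compound_id: r.fix_label for r in dataset}
assignments, enrichment = hierarchical_clusters(distances, labels, n_clusters=4)

print("\ncluster sizes and FIX=1 enrichment:")
for cluster in sorted(enrichment):
    size = sum(1 for c in assignments.values() if c == cluster)
    print(f"  cluster {cluster}: n={size:3d}  {enrichment[cluster]:5.1f}% diazotroph-associated")

coords = mds_embedding(distances, dims=2)
print("\nfirst rows of the 2-D MDS embedding of Tanimoto distances:")
print(coords.head().round(3).to_string())
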