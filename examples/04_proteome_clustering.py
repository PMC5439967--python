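"""Correlation-dissimilarity clustering of a (proteomic-style) matrix.

Pairwise Pearson correlations on pairwise-complete observations are turned
into the dissimilarity D = 1 - |r| — anti-correlated rows are as close as
correlated ones — and complete-linkage agglomeration recovers the planted
co-abundance blocks.
"""

from motifcoloc import correlation_matrix, dissimilarity, hierarchical_cluster
from motifcoloc.clustering import linkage_to_newick
from motifcoloc.simulate import SimConfig, make_expression

cfg = SimConfig(
    seed=21, expr_n_blocks=3, expr_rows_per_block=5, expr_n_samples=30, expr_within_r=0.9
)
matrix, truth_blocks = make_expression(cfg)
print(f"matrix: {matrix.shape[0]} proteins x {matrix.shape[1]} samples")

corr = correlation_matrix(matrix)
D = dissimilarity(corr.r)
print(f"example: r(P01_01, P01_02) = {corr.r.iloc[0, 1]:+.3f} "
      f"-> D = {D.D.iloc[0, 1]:.3f} (sign discarded by design)")

labels, Z = hierarchical_cluster(D, k=3, linkage="complete")
agree = (labels.to_numpy()[:, None] == labels.to_numpy()[None, :]) == (
    truth_blocks.to_numpy()[:, None] == truth_blocks.to_numpy()[None, :]
)
print("cluster sizes at k=3:", labels.value_counts().sort_index().to_dict())
print(f"pairwise agreement with planted blocks: {agree.mean():.3f}")
print("tree:", linkage_to_newick(Z, list(D.labels))[:80], "...")
print("Agreement 1.0 means the k=3 cut reproduces the planted co-abundance "
      "blocks exactly despite the noise and sign flips.")
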