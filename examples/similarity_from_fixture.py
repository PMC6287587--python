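"""Compute the bone-contact similarity matrix of the four study skulls.

Loads the packaged transcription of the contact observations for the
fossil protostegid Desmatochelys lowii and three living turtles, applies
the similarity statistic (same spatial relation; suture depth within one
ordinal category), and prints the percentage matrix with its audit
counts.  Each off-diagonal cell is the share of bone pairs, scored in
both taxa, whose contacts are similar.
"""

import itertools

import numpy as np

from sutura import SimilarityPolicy, rank_report, similarity_matrix, study_fixture

table = study_fixture()
matrix = similarity_matrix(table, SimilarityPolicy())

width = max(len(t) for t in matrix.taxa) + 2
print("Similarity (%), nasal contacts excluded:")
print(" " * width + "".join(t[:4].center(6) for t in matrix.taxa))
for i, taxon in enumerate(matrix.taxa):
    cells = "".join(
        ("-" if np.isnan(matrix.values[i, j]) else str(int(matrix.values[i, j]))).center(6)
        for j in range(len(matrix.taxa))
    )
    print(taxon.ljust(width) + cells)

print("\nComparable bone pairs per taxon pair (the denominators):")
for i, j in itertools.combinations(range(len(matrix.taxa)), 2):
    pair = frozenset((matrix.taxa[i], matrix.taxa[j]))
    nc, ns = matrix.counts[pair]
    print(f"  {matrix.taxa[i][:20]:22s} vs {matrix.taxa[j][:20]:22s} {ns:>3d}/{nc:<3d}")

focal = "Desmatochelys_lowii"
print(f"\nTaxa ranked by similarity to {focal}:")
for rank, (other, pct) in enumerate(rank_report(matrix, focal), start=1):
    print(f"  {rank}. {other} ({int(pct)}%)")
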