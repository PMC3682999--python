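"""Building semantic similarity matrices: measure averaging and LSA.

Combines two toy expert-style similarity measures by min-max rescaling
and averaging, derives an LSA similarity matrix from a six-document toy
corpus (log-entropy weighting, truncated SVD), and prints the
complete-linkage similarity tree of the LSA matrix in Newick form.
"""

import numpy as np

from ordsim import (
    Corpus,
    MeasureStack,
    SimilarityMatrix,
    WordSet,
    cluster_tree,
    combine_measures,
    lsa_term_similarity,
)

words = WordSet(["cat", "dog", "car", "road"])

measure_a = SimilarityMatrix(words, np.array([
    [1.0, 0.8, 0.1, 0.1],
    [0.8, 1.0, 0.1, 0.1],
    [0.1, 0.1, 1.0, 0.7],
    [0.1, 0.1, 0.7, 1.0],
]))
measure_b = SimilarityMatrix(words, 10 * measure_a.sims)  # different scale
combined = combine_measures(
    MeasureStack(words, (measure_a, measure_b), ("path", "gloss")),
    normalization="minmax",
)
print("combined measure (min-max rescaled then averaged):")
print(np.round(combined.sims, 3))

corpus = Corpus.from_text(
    "the cat sat with the dog on the mat\n"
    "a cat and a dog played in the yard\n"
    "the car drove down the road\n"
    "a car needs fuel and a road\n"
    "the cat chased the dog\n"
    "engines make a car fast on the road\n"
)
lsa = lsa_term_similarity(corpus, words, max_factors=300)
print("\nLSA cosine similarities in term space:")
print(np.round(lsa.sims, 3))
print("cat-dog vs cat-car:", round(lsa.sims[0, 1], 3), ">", round(lsa.sims[0, 2], 3),
      "-> co-occurrence recovers the animal/vehicle grouping")

print("\ncomplete-linkage tree:", cluster_tree(lsa, distance="one-minus").to_newick())
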