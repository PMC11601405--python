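"""Hypergeometric over-representation analysis of a gene set.

The worked case: universe of 10 genes, a term covering 4 of them, a query
of 5 genes with 3 in the term. The upper-tail probability of an overlap
of at least 3 is 66/252 ~= 0.2619.
"""

import traitblocks as tb

universe = [f"G{i}" for i in range(10)]
collection = tb.GeneSetCollection(
    {"PATHWAY_A": ("example pathway", frozenset(universe[:4]))}, axis="gene"
)
query = universe[:3] + universe[8:]  # 3 genes inside the term, 2 outside

results = tb.ora(query, collection, universe)
r = results[0]
print(f"term {r.term_id}: overlap k={r.overlap_k} of K={r.term_size_K}")
print(f"query n={r.query_size_n}, universe N={r.universe_size_N}")
print(f"P(X >= {r.overlap_k}) = {r.p_value:.6f}  (exactly 66/252 = {66/252:.6f})")
print(f"BH-adjusted p = {r.adjusted_p:.6f} (single term: equals the raw p)")
# In the pipeline this test runs for every annotation term against every
# meta-bicluster's gene union (GO-style sets) and trait set (DO-style
# sets), with BH adjustment across the terms of each collection.
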