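"""Over-representation analysis and cross-region overlap/cosine similarity.

Enriches a gene list against a synthetic GO Process database, then compares
per-region significant term sets: all-region overlap (|intersection|/|union|),
pairwise Jaccard, Venn counts, and the M1-vs-rest binary cosine.
"""

import numpy as np

from synaptomics import enrich_terms, generate_annotation_db, region_overlap

rng = np.random.default_rng(3)
background = {f"G{i}" for i in range(1000)}
db = generate_annotation_db(40, sorted(background), "GO Process", seed=4)

# a gene list built from one term's members is strongly enriched for it
target_term = sorted(db.terms)[5]
genes = set(db.terms[target_term]) | set(rng.choice(sorted(background), 20))
hits = enrich_terms(genes, background, db, alpha=0.05)
print(f"{len(hits)} significant terms; top hit:")
print(hits.head(1).to_string(index=False))
# observed >> expected for the planted term: strength = log10(obs/exp) > 0.

sets = {
    "M1": {"GO:1", "GO:2", "GO:3", "GO:4"},
    "S1": {"GO:3", "GO:4", "GO:5"},
    "DLS": {"GO:4", "GO:6"},
    "DMS": {"GO:4", "GO:7"},
}
report = region_overlap(sets, reference="M1")
print(f"\nall-region overlap: {report.all_region_overlap:.4f}")
print(f"M1 vs rest cosine:  {report.m1_vs_rest_cosine:.4f}")
print(f"unique to M1:       {report.unique_counts['M1']} "
      f"({report.unique_percentages['M1']:.1f}%)")
# GO:4 is the only term shared by all four regions -> overlap 1/7; the cosine
# compares M1's 4 terms to the union of the other regions' terms.
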