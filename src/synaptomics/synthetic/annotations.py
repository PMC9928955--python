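"""Random GMT annotation databases over a supplied gene universe."""

from __future__ import annotations

import numpy as np

from synaptomics.enrichment import CATEGORIES, AnnotationDB
from synaptomics.synthetic.design import ParameterError

_PREFIX = {"GO Process": "GO:00", "GO Function": "GO:01",
           "KEGG": "mmu", "Reactome": "R-MMU-"}


def generate_annotation_db(
    n_terms: int,
    genes: list[str],
    category: str,
    seed: int = 0,
    size_range: tuple[int, int] = (5, 50),
) -> AnnotationDB:
    """Random term -> gene-set database for one annotation category.

    Each term samples its member genes uniformly without replacement from
    ``genes``; term sizes are uniform over ``size_range`` (clipped to the
    universe size, minimum 1 member).
    """
    if category not in CATEGORIES:
        raise ParameterError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if not genes:
        raise ParameterError("gene universe is empty")
    if n_terms < 0:
        raise ParameterError("n_terms must be non-negative")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    lo = max(1, min(size_range[0], len(genes)))
    hi = max(lo, min(size_range[1], len(genes)))
    terms, descriptions = {}, {}
    prefix = _PREFIX[category]
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        term_id = f"{prefix}{i + 1:05d}"
        terms[term_id] = frozenset(str(g) for g in members)
        descriptions[term_id] = f"synthetic {category} term {i + 1}"
    return AnnotationDB(category=category, terms=terms, descriptions=descriptions)
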