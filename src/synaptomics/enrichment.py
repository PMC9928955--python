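"""Over-representation analysis, cross-region overlap and cosine similarity.

Enrichment of a differential gene list against a term database uses the
hypergeometric upper tail: drawing |genes| from the background universe, the
p-value of a term is the probability of observing at least the seen number of
term members. The universe is the set of genes quantified in the region's
table, the standard choice for proteomics ORA. Strength is log10(observed /
expected), the ranking used for "strongest term" throughout.

Cross-region agreement uses set overlap fractions (intersection over union by
default) and binary-vector cosine similarity |A∩B| / sqrt(|A|·|B|); an empty
set has cosine 0 by convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("GO Process", "GO Function", "KEGG", "Reactome")


class BackgroundError(ValueError):
    """Raised when the query gene list is not contained in the background."""


@dataclass
class AnnotationDB:
    """A term -> gene-set annotation database for one category.

    GMT serialization: one term per line, tab-separated as
    ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.
    """

    category: str
    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term} has no member genes")

    def __len__(self) -> int:
        return len(self.terms)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                desc = self.descriptions.get(term, self.category)
                genes = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{desc}\t{genes}\n")

    @classmethod
    def read_gmt(cls, path, category: str) -> "AnnotationDB":
        terms: dict[str, frozenset[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                terms[parts[0]] = frozenset(parts[2:])
                descriptions[parts[0]] = parts[1]
        return cls(category=category, terms=terms, descriptions=descriptions)


def enrich_terms(
    genes: set[str],
    background: set[str],
    db: AnnotationDB,
    alpha: float = 0.05,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` against ``db``.

    Returns a DataFrame (term_id, category, n_term, observed, expected,
    strength, p_value, fdr) sorted by p ascending; filtered to raw p < alpha
    unless ``significant_only`` is False. FDR (Benjamini-Hochberg) is computed
    across all terms of the category before filtering.
    """
    offenders = genes - background
    if offenders:
        raise BackgroundError(
            f"{len(offenders)} query gene(s) not in background, e.g. "
            f"{sorted(offenders)[:5]}")
    if not db.terms:
        raise ValueError("annotation database is empty")
    M, N = len(background), len(genes)
    rows = []
    for term_id in sorted(db.terms):
        members = db.terms[term_id] & background
        n = len(members)
        if n == 0:
            continue
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        expected = N * n / M
        strength = float(np.log10(k / expected)) if k > 0 else np.nan
        rows.append({"term_id": term_id, "category": db.category, "n_term": n,
                     "observed": k, "expected": expected, "strength": strength,
                     "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["term_id", "category", "n_term", "observed",
                                     "expected", "strength", "p_value", "fdr"])
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    if significant_only:
        out = out[out["p_value"] < alpha].reset_index(drop=True)
    return out


def cosine_similarity(a: set, b: set) -> float:
    """Binary-vector cosine over the union vocabulary: |a∩b|/sqrt(|a|·|b|).

    Either set empty -> 0.0 (the convention when one side has nothing to
    compare, interpreted as zero similarity).
    """
    if not a or not b:
        return 0.0
    return len(a & b) / float(np.sqrt(len(a) * len(b)))


def _overlap_fraction(sets: list[set], convention: str) -> float:
    union = set().union(*sets)
    if not union:
        return 0.0
    inter = set(sets[0]).intersection(*sets[1:])
    if convention == "union":
        return len(inter) / len(union)
    if convention == "min":
        denom = min(len(s) for s in sets)
        return len(inter) / denom if denom else 0.0
    if convention == "mean":
        return len(inter) / float(np.mean([len(s) for s in sets]))
    raise ValueError(f"unknown overlap convention {convention!r}")


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Exact membership-pattern counts over every non-empty region subset.

    Keys are '&'-joined sorted subset labels; the counts over all subsets sum
    to the size of the union.
    """
    labels = sorted(sets)
    counts: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set(sets[combo[0]]).intersection(*(sets[c] for c in combo[1:]))
            outside = set().union(*(sets[c] for c in labels if c not in combo)) \
                if len(combo) < len(labels) else set()
            counts["&".join(combo)] = len(inside - outside)
    return counts


@dataclass
class SimilarityReport:
    """Overlap/cosine statistics across per-region significant sets."""

    regions: list[str]
    set_sizes: dict[str, int]
    all_region_overlap: float
    pairwise_overlap: dict[str, float]
    m1_vs_rest_cosine: float
    venn: dict[str, int]
    intersection: list[str] = field(default_factory=list)
    unique_counts: dict[str, int] = field(default_factory=dict)
    unique_percentages: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "regions": self.regions,
            "set_sizes": self.set_sizes,
            "all_region_overlap": self.all_region_overlap,
            "pairwise_overlap": self.pairwise_overlap,
            "m1_vs_rest_cosine": self.m1_vs_rest_cosine,
            "venn": self.venn,
            "intersection": sorted(self.intersection),
            "unique_counts": self.unique_counts,
            "unique_percentages": self.unique_percentages,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def region_overlap(
    sets: dict[str, set],
    reference: str = "M1",
    pairwise_convention: str = "union",
    all_convention: str = "union",
) -> SimilarityReport:
    """Overlap fractions, Venn counts and reference-vs-rest cosine similarity.

    ``all_region_overlap`` is |∩ all regions| / |∪ all regions| by default;
    pairwise overlaps are Jaccard. The reference region's set is compared to
    the de-duplicated union of all other regions' sets by binary cosine.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 regions")
    if reference not in sets:
        raise KeyError(f"reference region {reference!r} missing from sets")
    regions = sorted(sets)
    all_frac = _overlap_fraction([sets[r] for r in regions], all_convention)
    pairwise = {}
    for r1, r2 in combinations(regions, 2):
        pairwise[f"{r1}|{r2}"] = _overlap_fraction([sets[r1], sets[r2]],
                                                   pairwise_convention)
    rest = set().union(*(sets[r] for r in regions if r != reference))
    cos = cosine_similarity(set(sets[reference]), rest)
    inter = set(sets[regions[0]]).intersection(*(sets[r] for r in regions[1:]))
    unique_counts, unique_pct = {}, {}
    for r in regions:
        others = set().union(*(sets[o] for o in regions if o != r))
        uniq = set(sets[r]) - others
        unique_counts[r] = len(uniq)
        unique_pct[r] = 100.0 * len(uniq) / len(sets[r]) if sets[r] else 0.0
    return SimilarityReport(
        regions=regions,
        set_sizes={r: len(sets[r]) for r in regions},
        all_region_overlap=all_frac,
        pairwise_overlap=pairwise,
        m1_vs_rest_cosine=cos,
        venn=venn_counts(sets),
        intersection=sorted(inter),
        unique_counts=unique_counts,
        unique_percentages=unique_pct,
    )


def geneid_overlap(tables: dict[str, "DifferentialTable"], reference: str = "M1",
                   **kwargs) -> SimilarityReport:
    """Cross-region overlap of significant GeneID sets from differential tables.

    Accepts per-region :class:`~synaptomics.differential.DifferentialTable`
    objects at one omics level; reports overlap fractions, Venn counts,
    reference-vs-rest cosine, and per-region counts/percentages of GeneIDs
    unique to that region.
    """
    sets = {region: table.significant_genes() for region, table in tables.items()}
    return region_overlap(sets, reference=reference, **kwargs)
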