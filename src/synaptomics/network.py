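"""Interaction-network construction, spectral k-means subclustering and labeling.

Edges come from a STRING-style export (node, node, combined confidence score);
the highest-confidence filter keeps edges with score >= 0.9 and hides
disconnected nodes. Subclusters are found by k-means on a spectral embedding
of the graph — the leading eigenvectors of the symmetrically normalized
adjacency — which is a principled stand-in for STRING's own (unpublished)
k-means feature space. Each subcluster is labeled post hoc by its strongest
significant annotation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from synaptomics.enrichment import AnnotationDB, enrich_terms


class EdgeParseError(ValueError):
    """Raised for malformed edge rows; carries the 1-based line number."""


@dataclass
class InteractionGraph:
    """Undirected interaction graph with combined scores in [0, 1]."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["score"]) for u, v, d in self.graph.edges(data=True)]


def _normalize_score(raw: float) -> float:
    # STRING exports integer scores 0-999; anything > 1 is that dialect
    return raw / 1000.0 if raw > 1 else float(raw)


def build_graph(edges, min_score: float = 0.9,
                node_log2_ar: dict[str, float] | None = None) -> InteractionGraph:
    """Filter an edge list at a confidence threshold and drop isolated nodes.

    Parameters
    ----------
    edges
        Iterable of (node1, node2, combined_score) or a DataFrame with columns
        protein1/protein2/combined_score. STRING-dialect integer scores
        (0-999) are divided by 1,000.
    min_score
        Minimum combined score on [0, 1]; 0.9 is the "highest confidence"
        setting.
    node_log2_ar
        Optional node -> log2 abundance-ratio attribute map.
    """
    if isinstance(edges, pd.DataFrame):
        edges = edges[["protein1", "protein2", "combined_score"]].itertuples(index=False)
    g = nx.Graph()
    for u, v, raw in edges:
        score = _normalize_score(float(raw))
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"combined score out of range: {raw}")
        if u == v:
            continue
        if score >= min_score:
            # keep the strongest score for duplicate pairs
            if g.has_edge(u, v):
                g[u][v]["score"] = max(g[u][v]["score"], score)
            else:
                g.add_edge(u, v, score=score)
    # edge-induced graph: nodes of degree 0 never enter; nodes that lost all
    # edges to the filter are absent, i.e. "disconnected nodes hidden"
    if node_log2_ar:
        for n in g.nodes:
            g.nodes[n]["log2_ar"] = node_log2_ar.get(n, np.nan)
    return InteractionGraph(graph=g)


def read_string_edges(path) -> pd.DataFrame:
    """Read a STRING-export TSV (protein1, protein2, combined_score).

    Malformed rows raise :class:`EdgeParseError` with the offending line
    number.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i1, i2, isc = (header.index(c) for c in ("protein1", "protein2",
                                                     "combined_score"))
        except ValueError as exc:
            raise EdgeParseError(f"line 1: missing required column ({exc})") from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                rows.append((parts[i1], parts[i2], float(parts[isc])))
            except (IndexError, ValueError) as exc:
                raise EdgeParseError(f"line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


@dataclass
class SubclusterAssignment:
    """Node -> cluster assignment with per-cluster labels and edge flags."""

    assignment: dict[str, int]
    k: int
    labels: dict[int, str] = field(default_factory=dict)
    label_strength: dict[int, float] = field(default_factory=dict)
    intra_edges: list[tuple[str, str]] = field(default_factory=list)
    inter_edges: list[tuple[str, str]] = field(default_factory=list)

    def members(self, cluster: int) -> set[str]:
        return {n for n, c in self.assignment.items() if c == cluster}

    def sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {c: 0 for c in range(self.k)}
        for c in self.assignment.values():
            sizes[c] += 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": sorted(self.assignment),
            "cluster": [self.assignment[n] for n in sorted(self.assignment)],
        })


def _spectral_embedding(graph: nx.Graph, nodes: list[str], dim: int) -> np.ndarray:
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="score")
    deg = a.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    n_sym = d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    # eigh returns ascending eigenvalues; take the top-dim eigenvectors
    vals, vecs = np.linalg.eigh(n_sym)
    emb = vecs[:, -dim:]
    # row-normalize (spectral clustering convention); zero rows left as-is
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return emb / norms


def kmeans_subcluster(graph: InteractionGraph, k: int, seed: int = 0) -> SubclusterAssignment:
    """k-means subclustering of the graph on its spectral embedding.

    Deterministic for fixed seed and invariant to node input order (nodes are
    processed in sorted order). Raises if the graph has fewer nodes than k.
    """
    nodes = graph.nodes
    if len(nodes) < k:
        raise ValueError(f"graph has {len(nodes)} nodes < k={k}")
    if k < 1:
        raise ValueError("k must be >= 1")
    emb = _spectral_embedding(graph.graph, nodes, dim=k)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(emb)
    # relabel clusters by first appearance in sorted node order for determinism
    relabel: dict[int, int] = {}
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel)
    assignment = {n: relabel[c] for n, c in zip(nodes, raw)}
    k_eff = len(relabel)
    intra, inter = [], []
    for u, v in graph.graph.edges:
        (intra if assignment[u] == assignment[v] else inter).append((u, v))
    return SubclusterAssignment(assignment=assignment, k=k_eff,
                                intra_edges=intra, inter_edges=inter)


def label_subclusters(
    assignment: SubclusterAssignment,
    db: AnnotationDB | None,
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> SubclusterAssignment:
    """Label each subcluster by its strongest significant annotation term.

    Enrichment of the cluster's members is computed against ``background``
    (default: all assigned nodes); the label is the significant term with
    maximal strength, ties broken by smaller p then lexicographic term_id.
    Clusters with no significant term — or an empty database — are labeled
    "unlabeled".
    """
    if background is None:
        background = set(assignment.assignment)
    for cluster in range(assignment.k):
        members = assignment.members(cluster) & background
        label, strength = "unlabeled", float("nan")
        if db is not None and db.terms and members:
            hits = enrich_terms(members, background, db, alpha=alpha)
            if not hits.empty:
                best = hits.sort_values(
                    ["strength", "p_value", "term_id"],
                    ascending=[False, True, True]).iloc[0]
                label, strength = str(best["term_id"]), float(best["strength"])
        assignment.labels[cluster] = label
        assignment.label_strength[cluster] = strength
    return assignment
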