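"""Log-normal reporter-abundance simulator plus kinase-map and edge-list generators.

The generative model for feature i in sample j of region r (group g):

    log2 abundance = base_i + effect_log2(i, r) * [g = PME]
                     + log2(channel_loading_j) + Normal(0, noise_sd)

with a per-feature baseline drawn once, planted log2 effects that are either
shared across all regions or exclusive to one region, and a per-channel
multiplicative loading factor emulating unequal peptide amounts. Everything is
driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synaptomics.abundance import AbundanceMatrix
from synaptomics.synthetic.design import ParameterError, StudyDesign


@dataclass
class OmicsGroundTruth:
    """Parameters and (after generation) realized ground truth for one level.

    The array fields (``effect_log2``, masks, ``channel_loading``) are filled
    in by :func:`simulate_level`; constructing the object only sets the
    generative parameters.
    """

    n_features: int = 5000
    frac_differential: float = 0.1
    effect_size_log2: float = 1.0
    frac_shared: float = 0.5
    noise_sd: float = 0.3
    channel_loading_range: tuple[float, float] = (0.5, 2.0)
    baseline_log2_mean: float = 13.0
    baseline_log2_sd: float = 1.5
    gene_universe: int | None = None
    seed: int = 0
    # realized by the generator
    effect_log2: pd.DataFrame | None = None  # features x regions
    shared_mask: np.ndarray | None = None
    unique_mask: np.ndarray | None = None
    channel_loading: dict[str, pd.Series] | None = None

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ParameterError("n_features must be positive")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ParameterError("frac_differential must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        lo, hi = self.channel_loading_range
        if lo <= 0 or hi < lo:
            raise ParameterError("channel_loading_range must be positive and ordered")

    def differential_features(self) -> np.ndarray:
        """Boolean mask of features with a planted effect in any region."""
        if self.effect_log2 is None:
            raise RuntimeError("ground truth not yet realized; run simulate_level")
        return (self.effect_log2.to_numpy() != 0).any(axis=1)


def _plant_effects(truth: OmicsGroundTruth, regions, feature_ids,
                   rng: np.random.Generator) -> None:
    n = truth.n_features
    n_diff = int(round(truth.frac_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    n_shared = int(round(truth.frac_shared * n_diff))
    shared_idx = diff_idx[:n_shared]
    unique_idx = diff_idx[n_shared:]
    effect = np.zeros((n, len(regions)))
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    for pos, i in enumerate(shared_idx):
        effect[i, :] = signs[pos] * truth.effect_size_log2
    for pos, i in enumerate(unique_idx):
        r = pos % len(regions)
        effect[i, r] = signs[n_shared + pos] * truth.effect_size_log2
    truth.effect_log2 = pd.DataFrame(effect, index=feature_ids, columns=list(regions))
    truth.shared_mask = np.isin(np.arange(n), shared_idx)
    truth.unique_mask = np.isin(np.arange(n), unique_idx)


def simulate_level(
    design: StudyDesign,
    truth: OmicsGroundTruth,
    level: str = "protein",
) -> tuple[dict[str, AbundanceMatrix], OmicsGroundTruth]:
    """Generate per-region abundance matrices for one omics level.

    Returns the region -> :class:`AbundanceMatrix` mapping and the ground
    truth with its realized effect matrix, masks and channel loadings.
    """
    if level not in ("protein", "phospho"):
        raise ParameterError(f"level must be protein or phospho, got {level!r}")
    rng = np.random.default_rng(truth.seed)
    n = truth.n_features
    prefix = "P" if level == "protein" else "pS"
    feature_ids = [f"{prefix}{i:05d}" for i in range(n)]
    universe = truth.gene_universe or n
    gene_ids = pd.Series([f"GENE{i % universe}" for i in range(n)], index=feature_ids)
    site_labels = None
    if level == "phospho":
        site_labels = pd.Series(
            [f"S{int(s)}" for s in rng.integers(1, 1000, size=n)], index=feature_ids)

    base = rng.normal(truth.baseline_log2_mean, truth.baseline_log2_sd, size=n)
    _plant_effects(truth, design.regions, feature_ids, rng)

    lo, hi = truth.channel_loading_range
    matrices: dict[str, AbundanceMatrix] = {}
    truth.channel_loading = {}
    for ri, region in enumerate(design.regions):
        meta = design.sample_table(region)
        loading = pd.Series(rng.uniform(lo, hi, size=len(meta)), index=meta.index)
        truth.channel_loading[region] = loading
        is_pme = (meta["group"] == "PME").to_numpy(float)
        log2_vals = (
            base[:, None]
            + truth.effect_log2.iloc[:, ri].to_numpy()[:, None] * is_pme[None, :]
            + np.log2(loading.to_numpy())[None, :]
            + rng.normal(0.0, truth.noise_sd, size=(n, len(meta)))
        )
        values = pd.DataFrame(np.exp2(log2_vals), index=pd.Index(feature_ids, name="feature_id"),
                              columns=meta.index)
        matrices[region] = AbundanceMatrix(
            values=values, sample_meta=meta[["group", "sex", "region"]],
            gene_ids=gene_ids, site_labels=site_labels, region=region, level=level)
    return matrices, truth


def generate_omics_dataset(
    design: StudyDesign,
    protein_truth: OmicsGroundTruth,
    phospho_truth: OmicsGroundTruth | None = None,
) -> tuple[dict[str, tuple[AbundanceMatrix, AbundanceMatrix]],
           tuple[OmicsGroundTruth, OmicsGroundTruth]]:
    """Generate the full per-region (protein, phospho) abundance-matrix pairs.

    When no phospho truth is given, a smaller phosphopeptide table is derived
    from the protein parameters (same noise and effect settings, ~60% as many
    features, gene universe shared with the protein level, child seed).
    """
    if phospho_truth is None:
        phospho_truth = OmicsGroundTruth(
            n_features=max(2, int(round(0.6 * protein_truth.n_features))),
            frac_differential=protein_truth.frac_differential,
            effect_size_log2=protein_truth.effect_size_log2,
            frac_shared=protein_truth.frac_shared,
            noise_sd=protein_truth.noise_sd,
            channel_loading_range=protein_truth.channel_loading_range,
            gene_universe=protein_truth.gene_universe or protein_truth.n_features,
            seed=protein_truth.seed + 1,
        )
    proteins, protein_truth = simulate_level(design, protein_truth, level="protein")
    phosphos, phospho_truth = simulate_level(design, phospho_truth, level="phospho")
    paired = {r: (proteins[r], phosphos[r]) for r in design.regions}
    return paired, (protein_truth, phospho_truth)


def generate_kinase_substrate_map(
    n_kinases: int,
    substrates_per_kinase: int,
    phospho_features: list[str],
    seed: int = 0,
    networkin_frac: float = 0.5,
) -> pd.DataFrame:
    """Random kinase-substrate map over quantified phosphosites.

    Every mapped substrate is drawn (without replacement per kinase) from the
    supplied feature list; each row carries a source flag (PSP or NetworKIN)
    and a non-negative NetworKIN-like score.
    """
    if n_kinases < 0 or substrates_per_kinase < 0:
        raise ParameterError("counts must be non-negative")
    if n_kinases > 0 and not phospho_features:
        raise ParameterError("phospho feature list is empty")
    if substrates_per_kinase > len(phospho_features) and n_kinases > 0:
        raise ParameterError(
            f"substrates_per_kinase={substrates_per_kinase} exceeds "
            f"{len(phospho_features)} available features")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_kinases):
        kinase = f"KIN{k:03d}"
        subs = rng.choice(phospho_features, size=substrates_per_kinase, replace=False)
        for s in subs:
            is_nk = rng.random() < networkin_frac
            rows.append({
                "kinase": kinase,
                "substrate": str(s),
                "source": "NetworKIN" if is_nk else "PSP",
                "networkin_score": float(rng.uniform(0.0, 5.0)),
            })
    return pd.DataFrame(rows, columns=["kinase", "substrate", "source",
                                       "networkin_score"])


def generate_interaction_edges(
    nodes: list[str],
    n_communities: int = 5,
    p_in: float = 0.9,
    p_out: float = 0.05,
    score_in: tuple[float, float] = (0.900, 0.999),
    score_out: tuple[float, float] = (0.400, 0.899),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Planted-partition interaction edge list with STRING-style scores.

    Nodes are assigned round-robin to communities; within-community pairs get
    an edge with probability ``p_in`` and a high combined score, cross pairs
    with probability ``p_out`` and a sub-threshold score. Returns the edge
    DataFrame (protein1, protein2, combined_score in [0, 1]) and the planted
    node -> community labels.
    """
    if n_communities < 1 or n_communities > max(len(nodes), 1):
        raise ParameterError("n_communities must be in [1, n_nodes]")
    rng = np.random.default_rng(seed)
    labels = {node: i % n_communities for i, node in enumerate(nodes)}
    rows = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            same = labels[u] == labels[v]
            p, band = (p_in, score_in) if same else (p_out, score_out)
            if rng.random() < p:
                rows.append({"protein1": u, "protein2": v,
                             "combined_score": float(rng.uniform(*band))})
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]), labels


def write_string_edges(edges: pd.DataFrame, path) -> None:
    """Write an edge list in the STRING export dialect (integer scores 0-999)."""
    out = edges.copy()
    out["combined_score"] = (out["combined_score"] * 1000).round().astype(int).clip(0, 999)
    out.to_csv(path, sep="\t", index=False)
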