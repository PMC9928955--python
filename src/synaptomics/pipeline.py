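"""End-to-end orchestration: simulate -> differential -> KSEA -> enrichment ->
overlap -> network -> puncta, from a single config with deterministic seeding.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``: stage i always receives the i-th
child regardless of which stages are enabled, so re-running one stage in
isolation reproduces its in-pipeline output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from synaptomics.differential import differential_table, filter_and_count
from synaptomics.enrichment import CATEGORIES, geneid_overlap, region_overlap, enrich_terms
from synaptomics.ksea import kinome_export, ksea_scores, sites_from_differential
from synaptomics.network import build_graph, kmeans_subcluster, label_subclusters
from synaptomics.puncta import (
    POST_DIAMETER_UM,
    PRE_DIAMETER_UM,
    compare_groups,
    detect_spots,
    estimate_neuropil,
    pair_synapses,
)
from synaptomics.synthetic import (
    OmicsGroundTruth,
    StudyDesign,
    generate_annotation_db,
    generate_image_stack,
    generate_interaction_edges,
    generate_kinase_substrate_map,
    generate_omics_dataset,
    simulate_image_truth,
)

STAGES = ("simulate", "differential", "ksea", "enrich", "overlap", "network", "puncta")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a distinct exit code."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All knobs for a synthetic end-to-end run (YAML-loadable)."""

    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "synaptomics_run"
    # synthetic omics
    regions: tuple[str, ...] = ("M1", "S1", "DLS", "DMS")
    n_per_group: int = 8
    n_features: int = 2000
    n_phospho: int | None = None
    frac_differential: float = 0.1
    effect_size_log2: float = 1.0
    noise_sd: float = 0.3
    test: str = "student"
    # ksea
    networkin_cutoff: float = 0.0
    substrate_cutoff: int = 0
    n_kinases: int = 50
    substrates_per_kinase: int = 10
    # enrichment / overlap
    n_terms_per_category: int = 100
    categories: tuple[str, ...] = CATEGORIES
    pairwise_convention: str = "union"
    all_convention: str = "union"
    reference_region: str = "M1"
    # network
    min_score: float = 0.9
    k_protein: int = 5
    k_phospho: int = 3
    network_nodes_max: int = 120
    # puncta
    puncta_enabled: bool = False
    puncta_n_pairs: int = 60
    puncta_images_per_group: int = 4
    puncta_stack_shape: tuple[int, int, int] = (14, 128, 128)
    puncta_voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    puncta_snr: float = 20.0
    puncta_pme_effect: float = 0.3  # fractional PME density increase
    puncta_max_dist: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.reference_region not in self.regions:
            raise ValueError("reference_region must be one of regions")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regions", "categories", "puncta_stack_shape", "puncta_voxel_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        params = dataclasses.asdict(self)
        params.pop("out_dir")
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def design(self) -> StudyDesign:
        half = self.n_per_group // 2
        return StudyDesign(regions=self.regions, n_per_group=self.n_per_group,
                           sex_split=(half, self.n_per_group - half))


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config_hash: str = ""
    version: str = ""
    differential: dict = field(default_factory=dict)
    ksea: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    puncta: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2 ** 31))
            for stage, child in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every enabled stage and write outputs under ``config.out_dir``.

    Identical config + seed produce an identical report. A stage failure
    raises :class:`StageError`; outputs of completed stages are retained.
    """
    from synaptomics import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report = RunReport(config_hash=config.config_hash(), version=__version__)

    # ---------------------------------------------------------- simulate
    try:
        design = config.design()
        protein_truth = OmicsGroundTruth(
            n_features=config.n_features,
            frac_differential=config.frac_differential,
            effect_size_log2=config.effect_size_log2,
            noise_sd=config.noise_sd,
            seed=seeds["simulate"],
        )
        phospho_truth = None
        if config.n_phospho:
            phospho_truth = OmicsGroundTruth(
                n_features=config.n_phospho,
                frac_differential=config.frac_differential,
                effect_size_log2=config.effect_size_log2,
                noise_sd=config.noise_sd,
                gene_universe=config.n_features,
                seed=seeds["simulate"] + 1,
            )
        matrices, truths = generate_omics_dataset(design, protein_truth, phospho_truth)
        for region, (prot, phos) in matrices.items():
            prot.write_tsv(out / f"abundance_{region}_protein.tsv")
            phos.write_tsv(out / f"abundance_{region}_phospho.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # ------------------------------------------------------ differential
    try:
        tables: dict[str, dict[str, object]] = {"protein": {}, "phospho": {}}
        for region, (prot, phos) in matrices.items():
            for level, matrix in (("protein", prot), ("phospho", phos)):
                table = differential_table(matrix, alpha=config.alpha, test=config.test)
                tables[level][region] = table
                path = out / f"differential_{region}_{level}.tsv"
                table.write_tsv(path)
                n_sig, n_up, n_down = table.counts
                report.differential[f"{region}_{level}"] = {
                    "n_features": len(table.records), "n_significant": n_sig,
                    "n_up": n_up, "n_down": n_down,
                }
                report.tables[f"differential_{region}_{level}"] = str(path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("differential", exc) from exc

    # -------------------------------------------------------------- ksea
    try:
        for region in config.regions:
            table = tables["phospho"][region]
            sites = sites_from_differential(table.records)
            ks_map = generate_kinase_substrate_map(
                config.n_kinases, config.substrates_per_kinase,
                list(sites["feature_id"]), seed=seeds["ksea"])
            scores = ksea_scores(sites, ks_map,
                                 networkin_cutoff=config.networkin_cutoff,
                                 substrate_cutoff=config.substrate_cutoff)
            path = out / f"ksea_{region}.tsv"
            scores.to_csv(path, sep="\t", index=False)
            if not scores.empty:
                kinome_export(scores).to_csv(out / f"kinome_{region}.tsv",
                                             sep="\t", index=False)
            report.ksea[region] = {
                "n_kinases": len(scores),
                "n_fdr_significant": int((scores["fdr"] < 0.05).sum()) if len(scores) else 0,
            }
            report.tables[f"ksea_{region}"] = str(path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("ksea", exc) from exc

    # ------------------------------------------------- enrichment + dbs
    try:
        universe = sorted(set(matrices[config.regions[0]][0].gene_ids))
        dbs = {cat: generate_annotation_db(config.n_terms_per_category, universe,
                                           cat, seed=seeds["enrich"] + i)
               for i, cat in enumerate(config.categories)}
        term_sets: dict[str, dict[str, dict[str, set]]] = {}
        for level in ("protein", "phospho"):
            term_sets[level] = {cat: {} for cat in config.categories}
            for region in config.regions:
                table = tables[level][region]
                background = set(table.records["gene_id"])
                genes = table.significant_genes() & background
                for cat in config.categories:
                    hits = enrich_terms(genes, background, dbs[cat], alpha=config.alpha)
                    term_sets[level][cat][region] = set(hits["term_id"])
                    hits.to_csv(out / f"enrichment_{region}_{level}_{cat.replace(' ', '')}.tsv",
                                sep="\t", index=False)
            report.enrichment[level] = {
                cat: {r: len(term_sets[level][cat][r]) for r in config.regions}
                for cat in config.categories}
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc

    # ----------------------------------------------------------- overlap
    try:
        for level in ("protein", "phospho"):
            gene_report = geneid_overlap(
                tables[level], reference=config.reference_region,
                pairwise_convention=config.pairwise_convention,
                all_convention=config.all_convention)
            gene_report.write_json(out / f"overlap_geneids_{level}.json")
            report.overlap[f"geneids_{level}"] = gene_report.to_dict()
            for cat in config.categories:
                sim = region_overlap(
                    term_sets[level][cat], reference=config.reference_region,
                    pairwise_convention=config.pairwise_convention,
                    all_convention=config.all_convention)
                sim.write_json(out / f"overlap_{level}_{cat.replace(' ', '')}.json")
                report.overlap[f"{level}_{cat}"] = {
                    "all_region_overlap": sim.all_region_overlap,
                    "m1_vs_rest_cosine": sim.m1_vs_rest_cosine,
                }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("overlap", exc) from exc

    # ----------------------------------------------------------- network
    try:
        for level, k, cat in (("protein", config.k_protein, "KEGG"),
                              ("phospho", config.k_phospho, "Reactome")):
            table = tables[level][config.reference_region]
            sig = table.records[table.records["significant"]]
            sig = sig.reindex(sig["log2_ar"].abs().sort_values(ascending=False).index)
            nodes = list(dict.fromkeys(sig["gene_id"]))[:config.network_nodes_max]
            if len(nodes) < k:
                report.network[level] = {"n_nodes": len(nodes), "skipped": True}
                continue
            edges, planted = generate_interaction_edges(
                nodes, n_communities=k, seed=seeds["network"])
            graph = build_graph(edges, min_score=config.min_score,
                                node_log2_ar=dict(zip(sig["gene_id"], sig["log2_ar"])))
            if graph.n_nodes < k:
                report.network[level] = {"n_nodes": graph.n_nodes, "skipped": True}
                continue
            assign = kmeans_subcluster(graph, k=k, seed=seeds["network"])
            assign = label_subclusters(assign, dbs.get(cat), alpha=config.alpha)
            assign.to_frame().to_csv(out / f"network_clusters_{level}.tsv",
                                     sep="\t", index=False)
            report.network[level] = {
                "n_nodes": graph.n_nodes, "n_edges": graph.n_edges, "k": assign.k,
                "cluster_sizes": {str(c): s for c, s in assign.sizes().items()},
                "labels": {str(c): l for c, l in assign.labels.items()},
                "n_intra_edges": len(assign.intra_edges),
                "n_inter_edges": len(assign.inter_edges),
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    # ------------------------------------------------------------ puncta
    if config.puncta_enabled:
        try:
            records = []
            rng = np.random.default_rng(seeds["puncta"])
            for group, factor in (("PME", 1.0 + config.puncta_pme_effect), ("PSE", 1.0)):
                for i in range(config.puncta_images_per_group):
                    n_pairs = int(round(config.puncta_n_pairs * factor))
                    img_seed = int(rng.integers(0, 2 ** 31))
                    truth = simulate_image_truth(
                        n_pairs=n_pairs, n_unpaired_pre=10, n_unpaired_post=10,
                        stack_shape=config.puncta_stack_shape,
                        voxel_size=config.puncta_voxel_size, seed=img_seed)
                    stack, _ = generate_image_stack(truth, snr=config.puncta_snr,
                                                    seed=img_seed + 1)
                    stack.group, stack.animal_id = group, f"{group}{i + 1}"
                    _, neuropil, volume = estimate_neuropil(stack)
                    pre = detect_spots(stack.channels["pre"], PRE_DIAMETER_UM,
                                       stack.voxel_size, neuropil_mask=neuropil)
                    post = detect_spots(stack.channels["post"], POST_DIAMETER_UM,
                                        stack.voxel_size, neuropil_mask=neuropil)
                    _, rec = pair_synapses(pre, post, max_dist=config.puncta_max_dist,
                                           neuropil_volume=volume, group=group,
                                           animal_id=stack.animal_id)
                    records.append(rec)
            comparison = compare_groups(records, metric="density")
            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
                out / "synapse_density.tsv", sep="\t", index=False)
            report.puncta = {
                "n_images": len(records),
                "mean_density_pme": float(np.mean([r.density for r in records
                                                   if r.group == "PME"])),
                "mean_density_pse": float(np.mean([r.density for r in records
                                                   if r.group == "PSE"])),
                "t": comparison.t, "df": comparison.df, "p_value": comparison.p_value,
                "welch": bool(comparison.welch),
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("puncta", exc) from exc

    write_report(report, out)
    return report


def write_report(report: RunReport, out_dir, format: str = "json") -> Path:
    """Serialize a report as JSON (default) or a TSV bundle; returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path = out / "run_report.json"
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        return path
    if format == "tsv":
        path = out / "run_report_tsv"
        path.mkdir(exist_ok=True)
        for section in ("differential", "ksea", "enrichment", "overlap", "network",
                        "puncta"):
            data = getattr(report, section)
            rows = [{"key": k, "value": json.dumps(v, sort_keys=True)}
                    for k, v in sorted(data.items())]
            pd.DataFrame(rows, columns=["key", "value"]).to_csv(
                path / f"{section}.tsv", sep="\t", index=False)
        return path
    raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> RunReport:
    """Load a JSON report back into a :class:`RunReport`."""
    with open(path) as fh:
        data = json.load(fh)
    return RunReport(**data)
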