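"""End-to-end pipeline orchestration.

One YAML configuration drives every stage in dependency order: ADMET
screen -> target assembly -> interaction networks (topology, key targets,
MCODE, TF subnetwork) -> diffusion, proximity and enrichment -> docking
summary.  Every artifact is recorded in a JSON manifest with the stage,
parameters and seed that produced it, so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import yaml

from . import diffusion, enrichment, io, mcode, netcore, proximity, screen, targets
from .docking import DockingRecord, summarize_docking
from .synth import SyntheticConfig, gen_compound_table, gen_correlation_matrix, \
    gen_disease_genes, gen_gene_sets, gen_ppi, gen_regulation_table, \
    gen_target_associations, herb_abbreviations

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline",
           "write_simulation"]

logger = logging.getLogger("netpharm")

ASSOCIATION_SCHEMA = io.TableSchema(
    name="associations",
    required_columns=(
        ("compound_id", "text"),
        ("gene", "text"),
        ("probability", "probability"),
        ("source", "text"),
    ),
)
DISEASE_SCHEMA = io.TableSchema(
    name="disease_genes",
    required_columns=(("gene", "text"), ("score", "number"), ("source", "text")),
)
REGULATION_SCHEMA = io.TableSchema(
    name="regulations",
    required_columns=(("regulator", "text"), ("target", "text"), ("mode", "text")),
)
DOCKING_SCHEMA = io.TableSchema(
    name="docking",
    required_columns=(("receptor", "text"), ("ligand", "text"), ("delta_g", "number")),
)


@dataclass
class PipelineConfig:
    """Paths to every input plus per-stage parameters and the global seed."""

    compounds: Path
    associations: Path
    disease_genes: Path
    ppi_edges: Path
    gene_sets: Path
    pathways: Path | None = None
    regulations: Path | None = None
    correlation: Path | None = None
    docking: Path | None = None
    output_dir: Path = Path("netpharm_out")
    global_seed: int = 0
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.params.get(stage, {}))


_REQUIRED_INPUTS = ("compounds", "associations", "disease_genes", "ppi_edges", "gene_sets")
_OPTIONAL_INPUTS = ("pathways", "regulations", "correlation", "docking")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    kwargs: dict[str, Any] = {}
    inputs = raw.get("inputs", {})
    for name in _REQUIRED_INPUTS:
        if name not in inputs:
            raise ValueError(f"config missing required input {name!r}")
        kwargs[name] = base / inputs[name]
    for name in _OPTIONAL_INPUTS:
        if inputs.get(name):
            kwargs[name] = base / inputs[name]
    kwargs["output_dir"] = base / raw.get("output_dir", "netpharm_out")
    kwargs["global_seed"] = int(raw.get("seed", 0))
    kwargs["params"] = raw.get("params", {}) or {}
    return PipelineConfig(**kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return an empty list iff the pipeline can run; each problem names the
    offending field and the reason."""
    problems: list[str] = []
    for name in _REQUIRED_INPUTS:
        path = getattr(config, name)
        if not Path(path).exists():
            problems.append(f"{name}: file {path} does not exist")
    for name in _OPTIONAL_INPUTS:
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name}: file {path} does not exist")

    def check_range(stage: str, key: str, low: float, high: float,
                    low_open: bool = False, high_open: bool = False) -> None:
        value = config.stage_params(stage).get(key)
        if value is None:
            return
        ok = (value > low if low_open else value >= low) and (
            value < high if high_open else value <= high
        )
        if not ok:
            interval = f"{'(' if low_open else '['}{low}, {high}{')' if high_open else ']'}"
            problems.append(f"params.{stage}.{key}: {value} outside {interval}")

    check_range("rwr", "restart_probability", 0.0, 1.0, low_open=True)
    check_range("targets", "genecards_top_fraction", 0.0, 1.0, low_open=True)
    check_range("targets", "min_probability", 0.0, 1.0)
    check_range("network", "min_confidence", 0.0, 1.0)
    check_range("enrichment", "p_cutoff", 0.0, 1.0, low_open=True)
    check_range("mcode", "node_score_cutoff", 0.0, 1.0)
    null_groups = config.stage_params("proximity").get("null_groups")
    if null_groups is not None and null_groups < 1:
        problems.append(f"params.proximity.null_groups: {null_groups} must be >= 1")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(header)
        writer.writerows(rows)


class _Manifest:
    def __init__(self, output_dir: Path, seed: int) -> None:
        self.output_dir = output_dir
        self.seed = seed
        self.artifacts: list[dict] = []

    def record(self, stage: str, path: Path, params: dict) -> None:
        self.artifacts.append(
            {
                "stage": stage,
                "path": str(path.relative_to(self.output_dir)),
                "sha256": _sha256(path),
                "params": params,
                "seed": self.seed,
            }
        )

    def write(self) -> Path:
        path = self.output_dir / "manifest.json"
        path.write_text(json.dumps({"seed": self.seed, "artifacts": self.artifacts},
                                   indent=2, sort_keys=True) + "\n")
        return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest as a dict.

    Any stage error aborts with the stage name attached.  Re-running with an
    identical config and seed produces identical artifact hashes.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.global_seed)
    run_summary: dict = {}
    stage = "setup"
    try:
        # --- screen ---------------------------------------------------
        stage = "screen"
        t0 = time.perf_counter()
        rows = io.read_table(config.compounds, screen.COMPOUND_SCHEMA)
        compounds = [screen.compound_from_row(r) for r in rows]
        thresholds = screen.ScreenThresholds(**config.stage_params("screen"))
        kept, report = screen.screen_compounds(compounds, thresholds)
        tox = screen.summarize_toxicity(kept)
        path = out / "compounds_kept.tsv"
        _write_tsv(path, ["compound_id", "name"], [[c.compound_id, c.name] for c in kept])
        manifest.record(stage, path, asdict(thresholds))
        path = out / "screen_report.json"
        path.write_text(json.dumps({"failures": report, "toxicity_active": tox,
                                    "n_input": len(compounds), "n_kept": len(kept)},
                                   indent=2, sort_keys=True) + "\n")
        manifest.record(stage, path, asdict(thresholds))
        run_summary["screen"] = {"n_input": len(compounds), "n_kept": len(kept)}
        logger.info("screen: kept %d/%d compounds (%.2fs)", len(kept), len(compounds),
                    time.perf_counter() - t0)

        # --- targets --------------------------------------------------
        stage = "targets"
        t0 = time.perf_counter()
        tp = config.stage_params("targets")
        assoc_rows = io.read_table(config.associations, ASSOCIATION_SCHEMA)
        kept_ids = {c.compound_id for c in kept}
        assocs = [
            targets.TargetAssociation(r["compound_id"], r["gene"], r["probability"], r["source"])
            for r in assoc_rows
            if r["compound_id"] in kept_ids
        ]
        drug = targets.drug_targets(assocs, tp.get("min_probability", 0.8))
        disease_rows = io.read_table(config.disease_genes, DISEASE_SCHEMA)
        disease = targets.disease_targets(
            [targets.DiseaseGeneRecord(r["gene"], r["score"], r["source"]) for r in disease_rows],
            tp.get("genecards_top_fraction", 0.5),
        )
        common = targets.common_targets(drug, disease)
        if not common:
            raise ValueError("no common targets between drug and disease sets")
        path = out / "common_targets.tsv"
        _write_tsv(path, ["gene"], [[g] for g in common])
        manifest.record(stage, path, tp)

        herb_codes = herb_abbreviations(200)  # covers any herb id HERBxx
        herb_codes.update({h: h for c in kept for h in c.herb_ids if h not in herb_codes})
        aliases = targets.assign_aliases(kept, herb_codes, allow_double_letters=True)
        path = out / "compound_aliases.tsv"
        _write_tsv(path, ["compound_id", "label"],
                   [[a.compound_id, a.label] for a in aliases])
        manifest.record(stage, path, {})

        if config.pathways is not None:
            pathway_sets = io.read_gmt(config.pathways)
            labels, counts = targets.label_pathway_members(common, pathway_sets)
            path = out / "pathway_labels.tsv"
            _write_tsv(path, ["gene", "pathways"],
                       [[g, ",".join(p)] for g, p in sorted(labels.items())])
            manifest.record(stage, path, {"per_pathway_counts": counts})
        run_summary["targets"] = {"n_drug_targets": len(drug),
                                  "n_disease_targets": len(disease),
                                  "n_common_targets": len(common)}
        logger.info("targets: %d drug, %d disease, %d common (%.2fs)",
                    len(drug), len(disease), len(common), time.perf_counter() - t0)

        # --- network --------------------------------------------------
        stage = "network"
        t0 = time.perf_counter()
        np_params = config.stage_params("network")
        min_conf = np_params.get("min_confidence", 0.4)
        edges = io.read_edge_list(config.ppi_edges)
        full_network = netcore.build_network(edges, min_conf)
        common_network = netcore.build_network(edges, min_conf, restrict_to=common)
        path = out / "ppi_common.graphml"
        io.write_graph(common_network, "graphml", path)
        manifest.record(stage, path, {"min_confidence": min_conf})

        stats = netcore.network_stats(common_network)
        table = netcore.centralities(common_network)
        keys = sorted(netcore.key_targets(table))
        path = out / "network_stats.json"
        path.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        manifest.record(stage, path, {"min_confidence": min_conf})
        path = out / "centralities.tsv"
        _write_tsv(path, ["gene", "degree", "betweenness"],
                   [[g, d, f"{b:.6f}"] for g, (d, b) in sorted(table.items())])
        manifest.record(stage, path, {})
        path = out / "key_targets.tsv"
        _write_tsv(path, ["gene"], [[g] for g in keys])
        manifest.record(stage, path, {"rule": "degree and betweenness > 2x median"})

        ranking = netcore.compound_degree_ranking(assocs, common, aliases)
        path = out / "compound_degree_ranking.tsv"
        _write_tsv(path, ["compound_id", "label", "degree"],
                   [[c, l, d] for c, l, d in ranking])
        manifest.record(stage, path, {})

        if config.regulations is not None:
            reg_rows = io.read_table(config.regulations, REGULATION_SCHEMA)
            kept_edges, out_degree = netcore.tf_subnetwork(
                [(r["regulator"], r["target"], r["mode"]) for r in reg_rows], set(common)
            )
            path = out / "tf_subnetwork.tsv"
            _write_tsv(path, ["regulator", "target", "mode"], [list(e) for e in kept_edges])
            manifest.record(stage, path, {"out_degree": out_degree})
        run_summary["network"] = {**stats, "n_key_targets": len(keys)}
        logger.info("network: %d nodes, %d edges, %d key targets (%.2fs)",
                    stats["n_nodes"], stats["n_edges"], len(keys),
                    time.perf_counter() - t0)

        # --- mcode ----------------------------------------------------
        stage = "mcode"
        t0 = time.perf_counter()
        mcode_params = mcode.MCODEParams(**config.stage_params("mcode"))
        complexes = mcode.mcode_find_complexes(common_network, mcode_params)
        path = out / "mcode_complexes.tsv"
        _write_tsv(path, ["rank", "score", "seed", "members"],
                   [[i + 1, f"{c.score:.4f}", c.seed, ",".join(sorted(c.members))]
                    for i, c in enumerate(complexes)])
        manifest.record(stage, path, asdict(mcode_params))
        logger.info("mcode: %d complexes (%.2fs)", len(complexes), time.perf_counter() - t0)

        # --- rwr ------------------------------------------------------
        stage = "rwr"
        t0 = time.perf_counter()
        rwr_params = config.stage_params("rwr")
        top_k = int(rwr_params.pop("top_k", 10))
        rwr_config = diffusion.RWRConfig(**rwr_params)
        lcc_nodes = max(nx.connected_components(full_network), key=len)
        lcc = full_network.subgraph(lcc_nodes).copy()
        seeds = set(common) & set(lcc.nodes)
        if not seeds:
            raise ValueError("no common target lies in the network's main component")
        result = diffusion.rwr(lcc, seeds, rwr_config)
        candidates = diffusion.top_candidates(result, top_k, seeds, rwr_config)
        path = out / "rwr_scores.tsv"
        _write_tsv(path, ["gene", "score"],
                   [[g, f"{s:.8f}"] for g, s in sorted(result.scores.items())])
        manifest.record(stage, path, asdict(rwr_config))
        path = out / "rwr_top_candidates.tsv"
        _write_tsv(path, ["rank", "gene", "score"],
                   [[i + 1, g, f"{s:.8f}"] for i, (g, s) in enumerate(candidates)])
        manifest.record(stage, path, {"top_k": top_k, **asdict(rwr_config)})
        logger.info("rwr: %d nodes scored (%.2fs)", len(result.scores),
                    time.perf_counter() - t0)

        # --- proximity ------------------------------------------------
        stage = "proximity"
        t0 = time.perf_counter()
        prox_params = config.stage_params("proximity")
        n_groups = int(prox_params.get("null_groups", 50))
        set_a = set(drug) & set(lcc.nodes)
        set_b = set(disease) & set(lcc.nodes)
        if len(set_a) >= 2 and len(set_b) >= 2:
            cache: dict = {}
            prox = proximity.proximity_index(lcc, set_a, set_b, cache)
            # random groups are matched in size to the drug target set and
            # scored against it, mirroring the study's control design
            null_mean, null_sd, _ = proximity.null_control(
                lcc, set_a, group_size=len(set_a), n_groups=n_groups,
                seed=config.global_seed,
            )
            path = out / "proximity.json"
            path.write_text(json.dumps(
                {"s_ab": prox.s_ab, "d_ab": prox.d_ab, "d_aa": prox.d_aa,
                 "d_bb": prox.d_bb, "null_mean": null_mean, "null_sd": null_sd,
                 "n_null": n_groups, "seed": config.global_seed},
                indent=2, sort_keys=True) + "\n")
            manifest.record(stage, path, {"null_groups": n_groups})
            run_summary["proximity"] = {"s_ab": prox.s_ab, "null_mean": null_mean,
                                        "null_sd": null_sd}
            logger.info("proximity: s_AB=%.3f vs null %.3f (%.2fs)", prox.s_ab,
                        null_mean, time.perf_counter() - t0)

        # --- enrichment ----------------------------------------------
        stage = "enrichment"
        t0 = time.perf_counter()
        enrich_params = config.stage_params("enrichment")
        terms = io.read_gmt(config.gene_sets)
        results = enrichment.enrich(
            set(common), terms, p_cutoff=enrich_params.get("p_cutoff", 0.005)
        )
        path = out / "enrichment.tsv"
        _write_tsv(path, ["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj",
                          "significant", "overlap"],
                   [[r.term_id, r.term_name, r.k, r.K, r.n, r.N, f"{r.p:.6g}",
                     f"{r.p_adj:.6g}", int(r.significant),
                     ",".join(sorted(r.overlap_genes))] for r in results])
        manifest.record(stage, path, enrich_params)
        logger.info("enrichment: %d terms tested (%.2fs)", len(results),
                    time.perf_counter() - t0)

        # --- correlation clustering ----------------------------------
        if config.correlation is not None:
            stage = "cluster"
            t0 = time.perf_counter()
            genes, matrix = read_correlation_matrix(config.correlation)
            n_clusters = int(config.stage_params("cluster").get("n_clusters", 4))
            assignment = enrichment.correlation_clusters(matrix, genes, n_clusters)
            path = out / "correlation_clusters.tsv"
            _write_tsv(path, ["gene", "cluster"],
                       [[g, c] for g, c in sorted(assignment.items())])
            manifest.record(stage, path, {"n_clusters": n_clusters})
            logger.info("cluster: %d genes into %d clusters (%.2fs)", len(genes),
                        n_clusters, time.perf_counter() - t0)

        # --- docking --------------------------------------------------
        if config.docking is not None:
            stage = "docking"
            t0 = time.perf_counter()
            dock_rows = io.read_table(config.docking, DOCKING_SCHEMA)
            records = [DockingRecord(r["receptor"], r["ligand"], r["delta_g"])
                       for r in dock_rows]
            summary = summarize_docking(records)
            path = out / "docking_ki.tsv"
            _write_tsv(path, ["receptor", "ligand", "delta_g_kcal_mol", "ki_umol_ml"],
                       [[r.receptor, r.ligand, r.delta_g, f"{r.ki:.6g}"]
                        for r in records])
            manifest.record(stage, path, {})
            path = out / "docking_summary.json"
            path.write_text(json.dumps(asdict(summary), indent=2, sort_keys=True) + "\n")
            manifest.record(stage, path, {})
            logger.info("docking: %d records (%.2fs)", len(records),
                        time.perf_counter() - t0)
    except Exception as error:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {error}") from error

    manifest.write()
    return {"seed": config.global_seed, "artifacts": manifest.artifacts,
            "summary": run_summary}


def write_correlation_matrix(path: Path, genes: list[str], matrix: np.ndarray) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["gene", *genes])
        for gene, row in zip(genes, matrix):
            writer.writerow([gene, *(f"{v:.6f}" for v in row)])


def read_correlation_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    with Path(path).open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        genes = header[1:]
        rows = [list(map(float, row[1:])) for row in reader]
    return genes, np.asarray(rows)


def write_simulation(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate every pipeline input into *out_dir* plus a ready-to-run
    pipeline config (config.yaml) and the planted ground truth
    (ground_truth.json).  Returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    compounds = gen_compound_table(config)
    _write_tsv(out / "compounds.tsv",
               [c for c, _ in screen.COMPOUND_SCHEMA.required_columns],
               [[screen.compound_to_row(c)[col]
                 for col, _ in screen.COMPOUND_SCHEMA.required_columns]
                for c in compounds])

    assocs = gen_target_associations(config)
    _write_tsv(out / "associations.tsv",
               ["compound_id", "gene", "probability", "source"],
               [[a.compound_id, a.gene, f"{a.probability:.6f}", a.source] for a in assocs])

    disease = gen_disease_genes(config)
    _write_tsv(out / "disease_genes.tsv", ["gene", "score", "source"],
               [[d.gene, f"{d.score:.6f}", d.source] for d in disease])

    planted = gen_ppi(config)
    # edge list files are headerless 3-column TSV
    edge_lines = [
        f"{a}\t{b}\t{d['confidence']:.6f}"
        for a, b, d in sorted(planted.network.edges(data=True))
    ]
    (out / "ppi_edges.tsv").write_text("\n".join(edge_lines) + "\n")

    sets, planted_term = gen_gene_sets(config, set(planted.set_a) | set(planted.set_b_near))
    io.write_gmt(sets, out / "gene_sets.gmt")
    io.write_gmt(sets[:5], out / "pathways.gmt")

    genes = sorted(planted.network.nodes)[: max(40, 4 * config.correlation_blocks)]
    matrix, labels = gen_correlation_matrix(config, genes)
    write_correlation_matrix(out / "correlation.tsv", genes, matrix)

    regulations = gen_regulation_table(config)
    _write_tsv(out / "regulations.tsv", ["regulator", "target", "mode"],
               [list(r) for r in regulations])

    (out / "ground_truth.json").write_text(json.dumps(
        {
            "clique": sorted(planted.clique),
            "set_a": sorted(planted.set_a),
            "set_b_near": sorted(planted.set_b_near),
            "set_b_far": sorted(planted.set_b_far),
            "planted_term": planted_term,
            "correlation_blocks": dict(zip(genes, labels)),
        },
        indent=2, sort_keys=True) + "\n")

    config_yaml = {
        "seed": config.seed,
        "output_dir": "results",
        "inputs": {
            "compounds": "compounds.tsv",
            "associations": "associations.tsv",
            "disease_genes": "disease_genes.tsv",
            "ppi_edges": "ppi_edges.tsv",
            "gene_sets": "gene_sets.gmt",
            "pathways": "pathways.gmt",
            "regulations": "regulations.tsv",
            "correlation": "correlation.tsv",
        },
        "params": {"cluster": {"n_clusters": config.correlation_blocks}},
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config_yaml, sort_keys=True))
    return config_path
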