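"""End-to-end pipeline orchestration with a flat config file.

Stage order: network prep -> concordant gene selection -> module mining
-> filter cascade -> neighbour scoring / pathway ranking -> permutation
significance -> differential co-expression.  Each stage writes its
output before the next begins and logs one structured line; the run
manifest records per-stage counts, parameters and seeds, so a rerun
with the same config reproduces identical outputs.

A single global seed is expanded into per-stage seeds by a fixed
counter scheme (``stage_seed = seed + stage index``), keeping every
stage independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .expression import read_differential_table, read_expression_matrix, select_concordant_genes
from .filters import (
    GO_NAMESPACES,
    conserved_neighbors,
    deg_containment_filter,
    neighbor_threshold,
    pathway_overlap_count,
    read_annotation,
    read_gmt,
    significant_terms,
    size_filter,
    term_overlap_filter,
    disease_term_filter,
    top_k_modules,
    write_gmt,
)
from .netprep import build_tensor, normalize_weights, read_edge_list, select_top_edges
from .rhs_miner import MinerConfig, mine_rhs
from .significance import coexpression_network, differential_edges, permutation_pvalue

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]

# stage name -> seed offset (the documented counter scheme)
STAGE_OFFSETS = {
    "prep": 0,
    "select_genes": 1,
    "mine": 2,
    "filter": 3,
    "neighbors": 4,
    "permtest": 5,
    "coexpr": 6,
}


class ConfigError(ValueError):
    """Invalid or unknown configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


@dataclass
class PipelineConfig:
    """Flat, YAML-compatible pipeline configuration."""

    # inputs
    layer_edges: list[str] = field(default_factory=list)
    layer_names: list[str] = field(default_factory=list)
    disease_logfc: dict[str, str] = field(default_factory=dict)
    drug_logfc: str | None = None
    drug_targets_gmt: str | None = None
    disease_genes_gmt: str | None = None
    annotation_tsv: str | None = None
    expression_tsv: str | None = None
    expression_labels_tsv: str | None = None
    # tunables
    normalize: bool = True
    top_fractions: list[float] = field(default_factory=list)
    density_threshold: float = 0.41
    min_size: int = 3
    max_modules: int = 100
    min_abs_logfc: float = 0.0
    deg_mode: str = "any"
    alpha: float = 0.05
    min_proportion: float = 0.2
    n_samples: int = 100_000
    rank: int = 50
    top_k: int = 2
    n_perm: int = 10_000
    r_threshold: float = 0.8
    seed: int = 0
    out_dir: str = "sdtp_out"

    def __post_init__(self) -> None:
        if len(self.layer_edges) != len(self.layer_names):
            raise ConfigError("layer_edges and layer_names must have equal length")
        if self.top_fractions and len(self.top_fractions) != len(self.layer_edges):
            raise ConfigError("top_fractions must match the number of layers")
        for f in self.top_fractions:
            if not 0 < f <= 1:
                raise ConfigError(f"top fraction {f} outside (0, 1]")
        if not 0 < self.density_threshold <= 1:
            raise ConfigError("density_threshold must be in (0, 1]")
        if self.min_size < 2:
            raise ConfigError("min_size must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 <= self.min_proportion <= 1:
            raise ConfigError("min_proportion must be in [0, 1]")
        if self.deg_mode not in ("any", "all"):
            raise ConfigError("deg_mode must be 'any' or 'all'")
        if self.rank < 1 or self.rank > self.n_samples:
            raise ConfigError("rank must be in [1, n_samples]")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 <= self.r_threshold <= 1:
            raise ConfigError("r_threshold must be in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a flat mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_OFFSETS[stage]) % 2**31


def _log_stage(stage: str, **info: Any) -> None:
    logger.info("stage=%s %s", stage, json.dumps(info, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def record(stage: str, **info: Any) -> None:
        manifest["stages"][stage] = {"seed": config.stage_seed(stage), **info}
        _log_stage(stage, **info)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    # -- prep ----------------------------------------------------------
    stage = "prep"
    try:
        if not config.layer_edges:
            raise ValueError("no layer edge lists configured")
        nets = []
        for idx, (path, name) in enumerate(zip(config.layer_edges, config.layer_names)):
            net = read_edge_list(path, name=name)
            if config.normalize:
                net = normalize_weights(net)
            if config.top_fractions:
                net = select_top_edges(net, config.top_fractions[idx])
            nets.append(net)
        tensor = build_tensor(nets, config.layer_names)
        tensor.to_directory(out / "tensor")
        layer_nets = {name: tensor.layer_network(name) for name in tensor.layer_index}
        record(
            stage,
            n_common_genes=tensor.n_genes,
            n_layers=tensor.n_layers,
            edges_per_layer={n: net.n_edges for n, net in layer_nets.items()},
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, str(exc)) from exc

    # -- select-genes --------------------------------------------------
    stage = "select_genes"
    concordant: dict[str, set[str]] = {}
    try:
        if config.disease_logfc and config.drug_logfc:
            drug_table = read_differential_table(config.drug_logfc, "drug")
            for disease, path in sorted(config.disease_logfc.items()):
                table = read_differential_table(path, disease)
                concordant[disease] = select_concordant_genes(
                    table, drug_table, min_abs_logfc=config.min_abs_logfc
                )
            write_gmt(concordant, out / "concordant.gmt")
        record(stage, n_sets=len(concordant), sizes={d: len(s) for d, s in concordant.items()})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- mine ----------------------------------------------------------
    stage = "mine"
    try:
        miner_cfg = MinerConfig(
            density_threshold=config.density_threshold,
            min_size=config.min_size,
            max_modules=config.max_modules,
            seed=config.stage_seed(stage),
        )
        modules = mine_rhs(tensor, miner_cfg)
        with (out / "modules.jsonl").open("w") as fh:
            for mod in modules:
                fh.write(json.dumps(mod.to_dict()) + "\n")
        record(stage, n_modules=len(modules))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- filter --------------------------------------------------------
    stage = "filter"
    try:
        kept = size_filter(modules, config.min_size)
        counts = {"size": len(kept)}
        if concordant:
            kept = deg_containment_filter(kept, concordant, mode=config.deg_mode)
        counts["deg_containment"] = len(kept)

        annotation = None
        if config.annotation_tsv:
            annotation = read_annotation(config.annotation_tsv)
        if annotation and config.drug_targets_gmt:
            drug_sets = read_gmt(config.drug_targets_gmt)
            drug_genes = set().union(*drug_sets.values()) & annotation.background
            reference_terms = {
                (ns, t)
                for ns in GO_NAMESPACES
                for t in (
                    significant_terms(drug_genes, annotation, ns, alpha=config.alpha)
                    if drug_genes
                    else set()
                )
            }
            if reference_terms:
                kept, _ = term_overlap_filter(
                    kept, reference_terms, annotation,
                    min_proportion=config.min_proportion, alpha=config.alpha,
                )
        counts["term_overlap"] = len(kept)
        if annotation and config.disease_genes_gmt:
            disease_sets = read_gmt(config.disease_genes_gmt)
            disease_terms = {}
            for disease, genes in sorted(disease_sets.items()):
                genes = set(genes) & annotation.background
                disease_terms[disease] = {
                    (ns, t)
                    for ns in GO_NAMESPACES
                    for t in (
                        significant_terms(genes, annotation, ns, alpha=config.alpha)
                        if genes
                        else set()
                    )
                }
            kept = disease_term_filter(kept, disease_terms, annotation, alpha=config.alpha)
        counts["disease_terms"] = len(kept)
        with (out / "filtered_modules.jsonl").open("w") as fh:
            for mod in kept:
                fh.write(json.dumps(mod.to_dict()) + "\n")
        record(stage, **counts)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- neighbour scoring & pathway ranking ---------------------------
    stage = "neighbors"
    final = kept
    try:
        if annotation and config.drug_targets_gmt and kept:
            drug_sets = read_gmt(config.drug_targets_gmt)
            drug_genes = set().union(*drug_sets.values()) & annotation.background
            drug_pathways = (
                significant_terms(drug_genes, annotation, "PATHWAY", alpha=config.alpha)
                if drug_genes
                else set()
            )
            scored = []
            rows = []
            for mod in kept:
                total = 0
                for name, net in layer_nets.items():
                    try:
                        thr = neighbor_threshold(
                            net, mod.genes & net.nodes,
                            n_samples=config.n_samples, rank=config.rank,
                            seed=config.stage_seed(stage),
                        )
                        neigh = conserved_neighbors(net, mod.genes & net.nodes, thr)
                    except ValueError:
                        neigh = set()
                    neigh &= annotation.background
                    mod_pathways = (
                        significant_terms(neigh, annotation, "PATHWAY", alpha=config.alpha)
                        if neigh
                        else set()
                    )
                    overlap = pathway_overlap_count(mod_pathways, drug_pathways)
                    rows.append(
                        {"module_rank": mod.rank, "layer": name,
                         "n_conserved_neighbors": len(neigh),
                         "pathway_overlap": overlap}
                    )
                    total += overlap
                scored.append((mod, float(total)))
            final = top_k_modules(scored, k=config.top_k)
            (out / "neighbor_report.json").write_text(json.dumps(rows, indent=2))
        with (out / "final_modules.jsonl").open("w") as fh:
            for mod in final:
                fh.write(json.dumps(mod.to_dict()) + "\n")
        record(stage, n_final=len(final))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- permutation significance --------------------------------------
    stage = "permtest"
    try:
        reports = []
        for mod in final:
            for name, net in layer_nets.items():
                genes = mod.genes & net.nodes
                if len(genes) < 2:
                    continue
                rep = permutation_pvalue(
                    net, genes, n_perm=config.n_perm, seed=config.stage_seed(stage)
                )
                reports.append({"module_rank": mod.rank, "layer": name, **rep.to_dict()})
        (out / "permutation.json").write_text(json.dumps(reports, indent=2))
        record(stage, n_tests=len(reports))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    # -- differential co-expression ------------------------------------
    stage = "coexpr"
    try:
        coexpr_rows = []
        if config.expression_tsv and config.expression_labels_tsv and final:
            expr = read_expression_matrix(
                config.expression_tsv, config.expression_labels_tsv
            )
            known = set(expr.genes)
            for mod in final:
                genes = sorted(set(mod.genes) & known)
                if len(genes) < 2:
                    continue
                case_net = coexpression_network(expr, genes, "case", config.r_threshold)
                ctrl_net = coexpression_network(expr, genes, "control", config.r_threshold)
                part = differential_edges(case_net, ctrl_net)
                coexpr_rows.append(
                    {
                        "module_rank": mod.rank,
                        "case_only": sorted(map(list, part.only_in_a)),
                        "control_only": sorted(map(list, part.only_in_b)),
                        "shared": sorted(map(list, part.shared)),
                    }
                )
            (out / "coexpression.json").write_text(json.dumps(coexpr_rows, indent=2))
        record(stage, n_modules_compared=len(coexpr_rows))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc

    return manifest
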