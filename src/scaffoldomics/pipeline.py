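"""End-to-end orchestration of the three analysis arms.

A single YAML config drives the imaging arm (stack cropping, segmentation,
clustering quantification), the expression arm (QC, normalization,
differential expression, dot-plot and population statistics), and the
network arm (DEG-seeded networks, per-level ORA, consensus, trimming,
merging, MCODE, dense-region enrichment).  Each arm can read real input
files or generate its synthetic fixture in place.  Every run writes its
artifacts plus a report with a parameter echo, per-file checksums, and
warnings; identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import io as sio
from .preprocessing import crop_stack, read_stack
from .segmentation import segment_channel
from .clustering import clustering_metrics, compare_conditions, volume_density_histogram
from .expression import (cluster_composition, dotplot_stats, percent_mtrna,
                         population_fraction, qc_trim, size_factor_normalize,
                         wilcoxon_de)
from .networks import (LEVEL_TRIM_DEFAULTS, build_network, mcode_dense_regions,
                       merge_networks, select_degs, trim_network)
from .enrichment import consensus_terms, hypergeom_ora, region_enrichment
from .synthetic import (CountsSpec, GlassLayerSpec, NetworkSpec, StackSpec,
                        simulate_counts, simulate_networks, simulate_stack)

log = logging.getLogger("scaffoldomics")

__all__ = ["RunConfig", "run_imaging_arm", "run_expression_arm",
           "run_network_arm", "run_all"]

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "scaffoldomics_run",
    "imaging": {
        "min_voxels": 10,
        "connectivity": 26,
        "exclude_edges": True,
        "peak_region": True,
        "inputs": None,          # {condition: {DiO: path, DAPI: path}}
        "voxel_size_zyx": [2.0, 1.0, 1.0],
        "synthetic": {           # {condition: StackSpec overrides}
            "control": {"n_singletons": 10, "n_clusters": 5,
                        "cells_per_cluster": [4, 4],
                        "shape_zyx": [30, 128, 128],
                        "glass_layer": {"z_range": [25, 29]}},
            "treated": {"n_singletons": 16, "n_clusters": 1,
                        "cells_per_cluster": [4, 4],
                        "shape_zyx": [30, 128, 128],
                        "glass_layer": {"z_range": [25, 29]}},
        },
    },
    "expression": {
        "max_molecules": 40000,
        "lfc": 0.25,
        "alpha": 0.01,
        "use_adjusted": True,
        "mito_threshold": 10.0,
        "group_key": "cluster",
        "group_a": "stem",
        "group_b": "bulk_control",
        "dotplot_genes": ["SOX2", "FOXM1", "CD44", "ID2", "ID3", "GPC3", "SOX4"],
        "counts_dir": None,
        "synthetic": {},         # CountsSpec overrides
    },
    "network": {
        "alpha": 0.05,
        "q_threshold": 0.1,
        "min_networks": 3,
        "trim": {lvl: {"degree_min": d, "betweenness_min": b}
                 for lvl, (d, b) in LEVEL_TRIM_DEFAULTS.items()},
        "mcode": {"degree_cutoff": 2, "node_score_cutoff": 0.2, "k_core": 2,
                  "max_depth": 100, "haircut": True, "fluff": False},
        "deg_table": None,
        "edges": None,           # {level: path}
        "gmt": None,
        "synthetic": {},         # NetworkSpec overrides
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


class RunConfig:
    """Run configuration with every threshold pre-filled to its default.

    Round-trips losslessly to YAML (the full, merged parameter set is what
    gets written).
    """

    def __init__(self, data: dict | None = None):
        self.data = _merge(DEFAULTS, data or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.data, sort_keys=True))
        return path

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.data["out_dir"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _finish(out_dir: Path, arm: str, params: dict, files: list[Path],
            caught: list[str]) -> dict:
    report = {
        "arm": arm,
        "parameters": params,
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)},
        "warnings": caught,
    }
    report_path = out_dir / f"{arm}_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_imaging_arm(config: RunConfig) -> dict:
    """Crop, segment, and quantify clustering for each condition's stack."""
    cfg = config["imaging"]
    out_dir = config.out_dir / "imaging"
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    caught: list[str] = []
    metrics = []
    results: dict = {"metrics": {}, "profiles": {}, "tables": {}, "truths": {}}

    stacks = {}
    if cfg.get("inputs"):
        for cond, paths in sorted(cfg["inputs"].items()):
            stacks[cond] = read_stack(paths, tuple(cfg["voxel_size_zyx"]))
    elif cfg.get("synthetic"):
        for i, (cond, overrides) in enumerate(sorted(cfg["synthetic"].items())):
            overrides = dict(overrides or {})
            if "glass_layer" in overrides and overrides["glass_layer"] is not None:
                overrides["glass_layer"] = GlassLayerSpec(**overrides["glass_layer"])
            overrides.setdefault("seed", (config.seed * 31 + i) % (2**31 - 1))
            for key in ("shape_zyx", "voxel_size_zyx", "cells_per_cluster",
                        "channel_gains"):
                if key in overrides:
                    overrides[key] = tuple(overrides[key])
            stack, truth = simulate_stack(StackSpec(**overrides))
            stacks[cond] = stack
            results["truths"][cond] = truth
    else:
        raise ValueError("imaging arm needs 'inputs' or 'synthetic'")

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for cond, stack in stacks.items():
            log.info("imaging: condition=%s slices=%d", cond, stack.n_slices)
            cropped, profile = crop_stack(stack)
            prof_df = profile.to_frame()
            p = out_dir / f"{cond}_slice_profile.tsv"
            prof_df.to_csv(p, sep="\t"); files.append(p)
            p = out_dir / f"{cond}_slice_profile.json"
            p.write_text(json.dumps(profile.to_json_dict(), indent=2)); files.append(p)

            _, table, thr = segment_channel(
                cropped, "DiO", min_voxels=cfg["min_voxels"],
                exclude_edges=cfg["exclude_edges"],
                connectivity=cfg["connectivity"])
            p = out_dir / f"{cond}_objects.csv"
            table.to_csv(p, index=False); files.append(p)
            results["tables"][cond] = table
            results["profiles"][cond] = profile

            hist = volume_density_histogram(
                table["volume_um3"].to_numpy(), peak_region=cfg["peak_region"],
                condition=cond, day="d3")
            p = out_dir / f"{cond}_histogram.tsv"
            hist.to_frame().to_csv(p, sep="\t", index=False); files.append(p)

            m = clustering_metrics(table, condition=cond, day="d3")
            metrics.append(m)
            results["metrics"][cond] = m
        comparison = compare_conditions(metrics) if len(stacks) > 1 else None
        caught.extend(str(w.message) for w in wlist)

    if comparison is not None:
        p = out_dir / "condition_comparison.tsv"
        comparison.to_csv(p, sep="\t", index=False); files.append(p)
        results["comparison"] = comparison
    results["report"] = _finish(out_dir, "imaging", cfg, files, caught)
    return results


def run_expression_arm(config: RunConfig) -> dict:
    """QC, normalize, and compute the expression statistics."""
    cfg = config["expression"]
    out_dir = config.out_dir / "expression"
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    caught: list[str] = []
    results: dict = {}

    if cfg.get("counts_dir"):
        adata = sio.read_counts_mtx(cfg["counts_dir"])
    elif cfg.get("synthetic") is not None:
        overrides = dict(cfg["synthetic"] or {})
        overrides.setdefault("seed", (config.seed * 31 + 11) % (2**31 - 1))
        if "stem_subpop" in overrides:
            f, m, x = overrides["stem_subpop"]
            overrides["stem_subpop"] = (f, tuple(m), x)
        adata, truth = simulate_counts(CountsSpec(**overrides))
        results["truth"] = truth
    else:
        raise ValueError("expression arm needs 'counts_dir' or 'synthetic'")

    log.info("expression: %d cells x %d genes", adata.n_obs, adata.n_vars)
    adata = qc_trim(adata, max_molecules=cfg["max_molecules"])
    percent_mtrna(adata)
    adata = size_factor_normalize(adata)
    results["adata"] = adata

    key = cfg["group_key"]
    mask_a = (adata.obs[key] == cfg["group_a"]).to_numpy()
    mask_b = (adata.obs[key] == cfg["group_b"]).to_numpy()
    de = wilcoxon_de(adata, mask_a, mask_b, lfc_threshold=cfg["lfc"],
                     alpha=cfg["alpha"], use_adjusted=cfg["use_adjusted"])
    p = out_dir / "de_table.tsv"; de.to_csv(p, sep="\t", index=False); files.append(p)
    results["de"] = de

    dots, skipped = dotplot_stats(adata, key, list(cfg["dotplot_genes"]))
    p = out_dir / "dotplot.tsv"; dots.to_csv(p, sep="\t", index=False); files.append(p)
    if skipped:
        p = out_dir / "dotplot_skipped_genes.txt"
        p.write_text("\n".join(skipped) + "\n"); files.append(p)
        caught.append(f"dot plot skipped unknown genes: {skipped}")
    results["dotplot"] = dots

    frac = population_fraction(adata.obs, "pct_mt", cfg["mito_threshold"], "condition")
    p = out_dir / "population_fraction.tsv"
    frac.to_frame().to_csv(p, sep="\t"); files.append(p)
    results["fractions"] = frac

    comp = cluster_composition(adata.obs, "condition", key)
    p = out_dir / "cluster_composition.tsv"; comp.to_csv(p, sep="\t"); files.append(p)
    results["composition"] = comp

    results["report"] = _finish(out_dir, "expression", cfg, files, caught)
    return results


def run_network_arm(config: RunConfig) -> dict:
    """Build, enrich, trim, merge, and mine the multi-level networks."""
    cfg = config["network"]
    out_dir = config.out_dir / "network"
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    caught: list[str] = []
    results: dict = {}

    if cfg.get("deg_table") and cfg.get("edges") and cfg.get("gmt"):
        deg_table = sio.read_deg_table(cfg["deg_table"])
        edge_tables = {lvl: sio.read_edge_table(p) for lvl, p in cfg["edges"].items()}
        gene_sets = sio.read_gmt(cfg["gmt"])
    elif cfg.get("synthetic") is not None:
        overrides = dict(cfg["synthetic"] or {})
        overrides.setdefault("seed", (config.seed * 31 + 23) % (2**31 - 1))
        for key in ("planted_term", "term_size_range"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        edge_tables, gene_sets, deg_table, truth = simulate_networks(NetworkSpec(**overrides))
        results["truth"] = truth
    else:
        raise ValueError("network arm needs deg_table+edges+gmt or 'synthetic'")

    degs = select_degs(deg_table, alpha=cfg["alpha"])
    if degs.empty:
        raise ValueError(f"no DEGs at alpha={cfg['alpha']}")
    annotated = set().union(*gene_sets.values())

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        nets, trimmed, ora_by_level = {}, {}, {}
        for level, edges in sorted(edge_tables.items()):
            net = build_network(degs, edges, level)
            nets[level] = net
            log.info("network: level=%s nodes=%d edges=%d", level,
                     net.number_of_nodes(), net.number_of_edges())
            study = {n for n in net.nodes if net.nodes[n].get("seed")}
            universe = set(net.nodes) & annotated
            ora = hypergeom_ora(study, gene_sets, universe, level=level)
            ora_by_level[level] = ora
            p = out_dir / f"ora_{level}.tsv"; ora.to_csv(p, sep="\t", index=False); files.append(p)
            tcfg = cfg["trim"].get(level, {"degree_min": 0, "betweenness_min": None})
            trimmed[level] = trim_network(net, **tcfg)
            p = out_dir / f"network_{level}.tsv"
            nx.to_pandas_edgelist(trimmed[level]).to_csv(p, sep="\t", index=False); files.append(p)
            p = out_dir / f"network_{level}.graphml"
            g = trimmed[level].copy()
            for n in g.nodes:  # GraphML cannot carry None attribute values
                g.nodes[n].setdefault("logfc", 0.0)
            nx.write_graphml(g, p); files.append(p)

        consensus = consensus_terms(ora_by_level, q_threshold=cfg["q_threshold"],
                                    min_networks=cfg["min_networks"])
        if cfg["min_networks"] > len(ora_by_level) and not consensus["kept"].any():
            caught.append("min_networks exceeds the number of levels: empty consensus")
        p = out_dir / "consensus.tsv"; consensus.to_csv(p, sep="\t", index=False); files.append(p)

        merged, rep = merge_networks(list(trimmed.values()))
        p = out_dir / "merge_report.json"
        p.write_text(json.dumps(rep, indent=2)); files.append(p)

        regions = mcode_dense_regions(merged, **cfg["mcode"])
        rdf = pd.DataFrame([{"region": r.rank, "rank": r.rank, "score": r.score,
                             "n_nodes": len(r), "members": ";".join(sorted(r.nodes))}
                            for r in regions])
        p = out_dir / "dense_regions.tsv"; rdf.to_csv(p, sep="\t", index=False); files.append(p)

        reg_univ = set(merged.nodes) & annotated
        reg_enr = region_enrichment(regions, gene_sets, reg_univ,
                                    deg_genes=set(degs["gene"]))
        p = out_dir / "region_enrichment.tsv"
        reg_enr.to_csv(p, sep="\t", index=False); files.append(p)
        caught.extend(str(w.message) for w in wlist)

    results.update({
        "degs": degs, "networks": nets, "trimmed": trimmed,
        "ora_by_level": ora_by_level, "consensus": consensus,
        "merged": merged, "merge_report": rep, "regions": regions,
        "region_enrichment": reg_enr,
    })
    results["report"] = _finish(out_dir, "network", cfg, files, caught)
    return results


def run_all(config: RunConfig) -> dict:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(config.out_dir / "config_echo.yaml")
    out = {
        "imaging": run_imaging_arm(config),
        "expression": run_expression_arm(config),
        "network": run_network_arm(config),
    }
    manifest = {}
    for arm in out.values():
        manifest.update(arm["report"]["checksums"])
    (config.out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return out
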