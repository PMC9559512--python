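"""Stage orchestration: each stage is a pure function of its input files,
parameters and seed, writing TSV/JSON artifacts plus a run manifest."""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import pandas as pd

from . import features, io, netstats, preprocess
from .enrichment import ora
from .pcit import pcit as pcit_filter
from .pcit import pearson_matrix, significant_edges
from .simulate import GroundTruth, ModuleSpec, SimulationConfig, simulate

__all__ = ["DEFAULT_CONFIG", "DependencyError", "merge_config", "run_stage", "STAGES"]


class DependencyError(RuntimeError):
    """A required artifact from an earlier stage is missing."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results",
    "paths": {"counts": None, "samples": None, "gmt": None, "degrees": None},
    "simulate": {},  # SimulationConfig field overrides
    "preprocess": {
        "min_cpm": 0.5,
        "min_fraction": 0.5,
        "method": "log_cpm",
        "batch_adjust": True,
    },
    "select": {
        "ig_threshold": 0.01,
        "train_fraction": 2 / 3,
        "top_n": 5,
        "sd_max": 0.1,
        "k_max": 25,
        "classifiers": list(features.CLASSIFIER_NAMES),
        "metrics": list(features.OPTIMIZATION_METRICS),
        "stepwise": True,
    },
    "network": {
        "p_max": 0.05,
        "mode": "pcit_and_p",
        "max_genes": 5000,
        "force": False,
        "seeds": "from-ml",  # biomarker list file, explicit list, or null
    },
    "diffk": {"degree_source": "full", "ddof": 1},
    "ora": {"fdr_max": 0.05},
}

STAGES = ("simulate", "preprocess", "select", "network", "diffk", "ora")


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def _outdir(cfg: dict) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _manifest(cfg: dict, stage: str, params: dict, counts: dict) -> None:
    from . import __version__

    payload = {
        "stage": stage,
        "seed": cfg["seed"],
        "params": params,
        "counts": counts,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (_outdir(cfg) / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=1))


def _need(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path.name}: run the {produced_by!r} stage first"
        )
    return path


def _load_counts_samples(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = _outdir(cfg)
    counts_path = cfg["paths"]["counts"] or _need(out / "counts.tsv", "simulate")
    samples_path = cfg["paths"]["samples"] or _need(out / "samples.tsv", "simulate")
    return io.read_matrix(counts_path), io.read_samples(samples_path)


def _load_normalized(cfg: dict) -> pd.DataFrame:
    return io.read_matrix(_need(_outdir(cfg) / "normalized.tsv", "preprocess"))


def stage_simulate(cfg: dict) -> None:
    out = _outdir(cfg)
    params = dict(cfg["simulate"])
    params.setdefault("seed", cfg["seed"])
    if "module_specs" in params:
        params["module_specs"] = tuple(ModuleSpec(*m) for m in params["module_specs"])
    sim_cfg = SimulationConfig(**params)
    counts, samples, truth = simulate(sim_cfg)
    io.write_matrix(counts, out / "counts.tsv")
    io.write_samples(samples, out / "samples.tsv")
    truth.to_json(out / "ground_truth.json")
    _manifest(cfg, "simulate", {k: str(v) for k, v in params.items()},
              {"genes": counts.shape[0], "samples": counts.shape[1]})


def stage_preprocess(cfg: dict) -> None:
    out = _outdir(cfg)
    counts, samples = _load_counts_samples(cfg)
    p = cfg["preprocess"]
    norm = preprocess.run_preprocess(
        counts, samples, p["min_cpm"], p["min_fraction"], p["method"], p["batch_adjust"]
    )
    io.write_matrix(norm, out / "normalized.tsv")
    _manifest(cfg, "preprocess", p,
              {"genes_in": counts.shape[0], "genes_out": norm.shape[0]})


def stage_select(cfg: dict) -> None:
    out = _outdir(cfg)
    norm = _load_normalized(cfg)
    _, samples = _load_counts_samples(cfg)
    s = cfg["select"]
    res = features.discover_biomarkers(
        norm,
        samples,
        ig_threshold=s["ig_threshold"],
        train_fraction=s["train_fraction"],
        top_n=s["top_n"],
        sd_max=s["sd_max"],
        seed=cfg["seed"],
        classifiers=tuple(s["classifiers"]),
        metrics=tuple(s["metrics"]),
        k_grid=range(1, s["k_max"] + 1),
        stepwise=s["stepwise"],
    )
    ranked_df = pd.DataFrame(
        [(rf.gene_id, rf.information_gain, rf.rank) for rf in res["ranked"]],
        columns=["gene", "information_gain", "rank"],
    )
    ranked_df.to_csv(out / "ranked_features.tsv", sep="\t", index=False,
                     float_format=io.FLOAT_FMT)
    (out / "model_reports.json").write_text(
        json.dumps(
            {
                "all_models": [r.to_dict() for r in res["reports"]],
                "selected": [r.to_dict() for r in res["selected"]],
                "biomarkers_union": res["biomarkers"],
                "biomarkers_intersection": res["biomarkers_intersection"],
                "train_ids": res["train_ids"],
                "test_ids": res["test_ids"],
            },
            indent=1,
        )
    )
    (out / "biomarkers.txt").write_text("\n".join(res["biomarkers"]) + "\n")
    _manifest(cfg, "select", {k: v for k, v in s.items()},
              {"ranked": len(res["ranked"]), "models": len(res["reports"]),
               "biomarkers": len(res["biomarkers"])})


def _resolve_seeds(cfg: dict) -> list[str] | None:
    seeds = cfg["network"]["seeds"]
    if seeds is None:
        return None
    if seeds == "from-ml":
        path = _need(_outdir(cfg) / "biomarkers.txt", "select")
        return [g for g in path.read_text().splitlines() if g]
    if isinstance(seeds, str):
        return [g for g in Path(seeds).read_text().splitlines() if g]
    return list(seeds)


def stage_network(cfg: dict) -> None:
    out = _outdir(cfg)
    norm = _load_normalized(cfg)
    _, samples = _load_counts_samples(cfg)
    p = cfg["network"]
    if norm.shape[0] > p["max_genes"] and not p["force"]:
        raise ValueError(
            f"{norm.shape[0]} genes exceeds the O(n^3) PCIT guard of "
            f"{p['max_genes']}; set network.force to override"
        )
    seeds = _resolve_seeds(cfg)
    meta = samples.set_index("sample")
    counts: dict[str, int] = {}
    seed_nets: dict[str, pd.DataFrame] = {}
    for grp in ("P", "NP"):
        cols = [s for s in norm.columns if meta.loc[s, "class"] == grp]
        corr = pearson_matrix(norm[cols])
        edges = significant_edges(pcit_filter(corr, p_max=p["p_max"], mode=p["mode"]))
        io.write_edges(edges, out / f"edges_{grp}.tsv")
        counts[f"edges_{grp}"] = len(edges)
        if seeds is not None:
            sub = netstats.seed_subnetwork(edges, seeds)
            io.write_edges(sub, out / f"seed_edges_{grp}.tsv")
            io.write_sif(sub, out / f"seed_edges_{grp}.sif")
            counts[f"seed_edges_{grp}"] = len(sub)
            seed_nets[grp] = sub
    if seeds is not None and len(seed_nets) == 2:
        union, rewiring = netstats.union_rewiring(seed_nets["P"], seed_nets["NP"])
        io.write_edges(union, out / "union_edges.tsv")
        rewiring.to_csv(out / "rewiring.tsv", sep="\t", index=False,
                        float_format=io.FLOAT_FMT)
        counts["union_edges"] = len(union)
        counts["union_nodes"] = len(rewiring)
    _manifest(cfg, "network", {k: v for k, v in p.items()}, counts)


def stage_diffk(cfg: dict) -> None:
    out = _outdir(cfg)
    d = cfg["diffk"]
    if cfg["paths"]["degrees"]:
        table = io.read_degree_table(cfg["paths"]["degrees"])
        k_np = table.set_index("gene")["K_NP"]
        k_p = table.set_index("gene")["K_P"]
        source = "degree_table"
    else:
        prefix = "seed_edges" if d["degree_source"] == "seed" else "edges"
        e_np = io.read_edges(_need(out / f"{prefix}_NP.tsv", "network"))
        e_p = io.read_edges(_need(out / f"{prefix}_P.tsv", "network"))
        nodes = sorted(
            set(e_np["gene_a"]) | set(e_np["gene_b"]) | set(e_p["gene_a"]) | set(e_p["gene_b"])
        )
        k_np = netstats.degree(e_np, nodes)
        k_p = netstats.degree(e_p, nodes)
        source = d["degree_source"]
        hub_report = {
            "NP": netstats.hubs(k_np) if len(k_np) > 1 else [],
            "P": netstats.hubs(k_p) if len(k_p) > 1 else [],
        }
        (out / "hubs.json").write_text(json.dumps(hub_report, indent=1))
    records = netstats.diffk_zscores(netstats.diffk(k_np, k_p), ddof=d["ddof"])
    records.to_csv(out / "connectivity.tsv", sep="\t", index=False,
                   float_format="%.10g")
    _manifest(cfg, "diffk", {"degree_source": source, "ddof": d["ddof"]},
              {"genes": len(records), "significant": int(records["significant"].sum())})


def stage_ora(cfg: dict) -> None:
    out = _outdir(cfg)
    gmt_path = cfg["paths"]["gmt"]
    if not gmt_path:
        raise DependencyError("ora stage needs paths.gmt (a GMT gene-set file)")
    collection = io.read_gmt(gmt_path)
    norm = _load_normalized(cfg)
    background = list(norm.index)
    seeds = _resolve_seeds(cfg) or []
    counts: dict[str, int] = {}
    queries: dict[str, set[str]] = {}
    for grp in ("P", "NP"):
        path = out / f"seed_edges_{grp}.tsv"
        if not path.exists():
            raise DependencyError(
                "ora stage needs seed subnetworks: run 'network' with seeds configured"
            )
        sub = io.read_edges(path)
        queries[grp] = (set(sub["gene_a"]) | set(sub["gene_b"])) - set(seeds)
    queries["shared"] = queries["P"] & queries["NP"]
    for name, query in queries.items():
        if not query:
            counts[f"enrichment_{name}"] = 0
            continue
        table = ora(query, collection, background, fdr_max=cfg["ora"]["fdr_max"])
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False,
                     float_format=io.FLOAT_FMT)
        counts[f"enrichment_{name}"] = int(table["significant"].sum())
    _manifest(cfg, "ora", dict(cfg["ora"]), counts)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "select": stage_select,
    "network": stage_network,
    "diffk": stage_diffk,
    "ora": stage_ora,
}


def run_stage(stage: str, config: dict | None = None) -> None:
    """Run one stage (or 'all') with config overrides on DEFAULT_CONFIG."""
    cfg = merge_config(config)
    if stage == "all":
        for s in STAGES:
            if s == "ora" and not cfg["paths"]["gmt"]:
                continue  # enrichment is optional without a gene-set file
            _STAGE_FUNCS[s](cfg)
        return
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}")
    _STAGE_FUNCS[stage](cfg)
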