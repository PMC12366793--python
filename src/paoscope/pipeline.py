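"""End-to-end pipeline orchestration behind one YAML config.

Stages run in dependency order (synth -> filter -> diversity -> opu ->
network -> linkage), every output is written under the run directory, and a
manifest records inputs, parameters, seeds and SHA-256 hashes of all outputs
so a run can be verified and any stage re-run in isolation. One root seed
drives all stages through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, diversity, linkage, network, raman, synth

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("paoscope")

STAGES = ("synth", "filter", "diversity", "opu", "network", "linkage")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    out_dir: str = "paoscope_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    synth_params: dict = field(default_factory=dict)
    filter_params: dict = field(
        default_factory=lambda: {"min_rel_abund": 1e-4, "min_escore": 99.0}
    )
    opu_params: dict = field(default_factory=lambda: {"cutoff": 0.6, "bin_width": 6.0})
    network_params: dict = field(
        default_factory=lambda: {"group_by": "warming", "n_null": 50, "p_max": 0.05}
    )
    linkage_params: dict = field(
        default_factory=lambda: {"r_min": 0.6, "alpha": 0.05, "method": "pearson"}
    )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    Any stage failure raises :class:`StageError` naming the stage; a stage
    whose dependency is disabled raises a dependency error before running.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    deps = {
        "filter": ["synth"],
        "diversity": ["filter"],
        "opu": ["synth", "filter"],
        "network": ["filter"],
        "linkage": ["synth", "network", "diversity"],
    }
    for s in enabled:
        missing = [d for d in deps.get(s, []) if d not in enabled]
        if missing:
            raise StageError(f"stage '{s}': missing dependency stage(s) {missing}")

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in enabled:
        log.info("running stage %s", stage)
        try:
            outputs = _RUNNERS[stage](config, out, state)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
            "files": {name: str(p) for name, p in outputs.items()},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------


def _stage_synth(config: RunConfig, out: Path, state: dict) -> dict:
    params = synth.SynthParams(seed=config.seed, **config.synth_params)
    data = synth.gen_all(params)
    state.update(data)
    state["params"] = params
    files = {
        "design": out / "design.tsv",
        "otu": out / "otu_table.tsv",
        "functions": out / "function_table.tsv",
        "env": out / "env_table.tsv",
        "spectra": out / "spectra.tsv",
        "spectra_meta": out / "spectra_meta.tsv",
        "truth": out / "truth.json",
    }
    data["design"].to_csv(files["design"], sep="\t", index=False)
    data["otu"].to_tsv(files["otu"])
    data["functions"].to_tsv(files["functions"])
    data["env"].to_csv(files["env"], sep="\t")
    data["spectra"].to_tsv(files["spectra"], meta_path=files["spectra_meta"])
    files["truth"].write_text(
        json.dumps(data["truth"], indent=2, sort_keys=True, default=str)
    )
    return files


def _stage_filter(config: RunConfig, out: Path, state: dict) -> dict:
    table = state["otu"]
    filtered, ledger = community.filter_otus(table, **config.filter_params)
    pao = community.require_pao_genes(filtered, state["functions"])
    state["filtered"] = filtered
    state["pao"] = pao
    files = {
        "filtered": out / "otu_filtered.tsv",
        "pao": out / "otu_pao.tsv",
        "removal_ledger": out / "removal_ledger.json",
    }
    filtered.to_tsv(files["filtered"])
    pao.to_tsv(files["pao"])
    files["removal_ledger"].write_text(json.dumps(ledger, indent=2, sort_keys=True))
    return files


def _stage_diversity(config: RunConfig, out: Path, state: dict) -> dict:
    design = state["design"].set_index("sample_id", drop=False)
    pao = state["pao"]
    rel = pao.relative_abundance()
    h = rel.apply(lambda col: diversity.shannon(col.to_numpy()), axis=0)
    state["h_tax"] = h
    effects = diversity.fit_lmm(h.loc[design.index].to_numpy(), design)
    fr = diversity.functional_redundancy(
        state["functions"].contributions.loc[pao.taxa]
    )
    state["fr"] = fr
    files = {
        "shannon": out / "pao_shannon.tsv",
        "effects": out / "effect_sizes.tsv",
        "fr": out / "functional_redundancy.json",
    }
    h.rename("shannon").to_csv(files["shannon"], sep="\t", index_label="sample_id")
    pd.DataFrame([e.as_dict() for e in effects]).to_csv(
        files["effects"], sep="\t", index=False
    )
    files["fr"].write_text(json.dumps({"FR": fr}, indent=2))
    return files


def _stage_opu(config: RunConfig, out: Path, state: dict) -> dict:
    spectra = state["spectra"]
    pre = raman.preprocess_set(
        spectra, bin_width=config.opu_params.get("bin_width", 6.0)
    )
    opus = raman.cluster_opus(pre, cutoff=config.opu_params.get("cutoff", 0.6))
    comp = raman.opu_abundance(opus, pre.meta)
    h_fun = comp.apply(lambda row: diversity.shannon(row.to_numpy()), axis=1)
    state["opus"] = opus
    state["opu_composition"] = comp
    state["h_fun"] = h_fun
    # functionality-biodiversity fit on pooled samples
    truth = state["truth"]
    h_tax = pd.Series(truth["h_tax_pooled"])
    shared = h_tax.index.intersection(h_fun.index)
    fit = diversity.compare_fits(h_tax[shared].to_numpy(), h_fun[shared].to_numpy())
    state["fit_comparison"] = fit
    files = {
        "assignments": out / "opu_assignments.tsv",
        "mean_spectra": out / "opu_mean_spectra.tsv",
        "composition": out / "opu_composition.tsv",
        "fit_comparison": out / "fit_comparison.json",
    }
    opus.assignments.to_csv(files["assignments"], sep="\t", index_label="cell_id")
    opus.mean_spectra.to_csv(files["mean_spectra"], sep="\t", index_label="opu")
    comp.to_csv(files["composition"], sep="\t", index_label="sample_id")
    files["fit_comparison"].write_text(json.dumps(fit.as_dict(), indent=2))
    return files


def _stage_network(config: RunConfig, out: Path, state: dict) -> dict:
    design = state["design"].set_index("sample_id", drop=False)
    pao = state["pao"]
    # PAO taxa on the whole-community scale: counts over total sample depth,
    # so block-level normalization does not manufacture anti-correlations
    rel = state["otu"].relative_abundance().loc[pao.taxa]
    group_by = config.network_params.get("group_by", "warming")
    n_null = int(config.network_params.get("n_null", 50))
    p_max = float(config.network_params.get("p_max", 0.05))
    metric_rows = {}
    edge_frames = []
    files: dict = {}
    state["networks"] = {}
    for key, grp in design.groupby(group_by):
        label = f"{group_by}{key}" if not isinstance(key, str) else str(key)
        cols = [c for c in grp.index if c in rel.columns]
        corr = network.correlation_matrix(rel[cols])
        s_star, diag = network.rmt_threshold(corr)
        g = network.build_network(corr, s_star, p_max=p_max, treatment=label)
        part = network.louvain_partition(g, seed=config.seed)
        metrics = network.complexity_metrics(g, partition=part, seed=config.seed)
        metrics.update(network.modularity_nestedness(g, n_null=n_null, seed=config.seed))
        metrics["R"] = network.robustness(g, seed=config.seed)
        metrics["V"] = network.vulnerability(g)
        coh = network.cohesion(rel[cols].T, n_null=n_null, seed=config.seed)
        metrics["Cohesion_pos"] = float(coh["cohesion_pos"].mean())
        metrics["Cohesion_neg"] = float(coh["cohesion_neg"].mean())
        metrics["s_star"] = s_star
        metric_rows[label] = metrics
        state["networks"][label] = g
        edges = pd.DataFrame(
            [
                {"group": label, "u": u, "v": v, "r": d["r"], "sign": d["sign"]}
                for u, v, d in g.edges(data=True)
            ]
        )
        edge_frames.append(edges)
        import networkx as nx

        gml = out / f"network_{label}.graphml"
        nx.write_graphml(g, gml)
        files[f"graphml_{label}"] = gml
    metric_table = pd.DataFrame(metric_rows).T
    state["network_metrics"] = metric_table
    files["metrics"] = out / "network_metrics.tsv"
    files["edges"] = out / "network_edges.tsv"
    metric_table.to_csv(files["metrics"], sep="\t", index_label="group")
    pd.concat(edge_frames).to_csv(files["edges"], sep="\t", index=False)
    return files


def _stage_linkage(config: RunConfig, out: Path, state: dict) -> dict:
    env = state["env"].copy()
    env["OM"] = linkage.percent_om(env["LOI"].to_numpy())
    design = state["design"].set_index("sample_id", drop=False)
    h = state["h_tax"]
    funcs = env[["NEE", "GPP", "ER", "Rs", "Rh"]]
    pao_metrics = pd.DataFrame({"pao_shannon": h}).loc[funcs.index.intersection(h.index)]
    pairs, n_sig = linkage.correlation_screen(
        pao_metrics,
        funcs.loc[pao_metrics.index],
        r_min=config.linkage_params.get("r_min", 0.6),
        alpha=config.linkage_params.get("alpha", 0.05),
        method=config.linkage_params.get("method", "pearson"),
    )
    files = {
        "env_derived": out / "env_derived.tsv",
        "linkage_pairs": out / "linkage_pairs.tsv",
        "linkage_summary": out / "linkage_summary.json",
    }
    env.to_csv(files["env_derived"], sep="\t")
    pairs.to_csv(files["linkage_pairs"], sep="\t", index=False)
    files["linkage_summary"].write_text(
        json.dumps({"n_significant": n_sig}, indent=2)
    )
    return files


_RUNNERS = {
    "synth": _stage_synth,
    "filter": _stage_filter,
    "diversity": _stage_diversity,
    "opu": _stage_opu,
    "network": _stage_network,
    "linkage": _stage_linkage,
}
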