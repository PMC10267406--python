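"""Pipeline orchestration: load/translate → topology → attractors →
perturbation → simulation → report bundle.

A run is described by a :class:`RunConfig` (loadable from YAML), executes
its stages in DAG order, and writes a manifest recording the seed, the
config hash, and a SHA-256 per output file so a re-run can be verified
byte-for-byte.  The single global seed fans out to per-stage seeds by a
fixed counter scheme (stage k uses ``seed * 1000 + k``), so re-running one
stage reproduces its slice of a full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import model_io, topology
from .attractors import (Attractor, async_random_walk, exhaustive_sync,
                         heuristic_search, sat_steady_states,
                         decomposition_search, dedupe)
from .dynamics import CtmcConfig, TrajectoryEstimate, simulate_ctmc
from .network import BooleanNetwork
from .pd_translation import read_pd_text, translate
from .perturb import prioritize_targets, sensitivity_report
from .synthetic import motif

__all__ = ["RunConfig", "Scenario", "run", "scenario_table",
           "load_network", "verify_bundle", "attractors_by_method"]

log = logging.getLogger("boolpath")

STAGES = ("topology", "attractors", "perturbation", "simulate")

STAGE_SEED_BASE = 1000


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * STAGE_SEED_BASE + STAGES.index(stage)) % (2**31 - 1)


@dataclass
class Scenario:
    """One simulation scenario: clamped node values, read-out nodes, and
    optional per-node initial ON-probabilities."""
    name: str
    clamps: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    initial: dict[str, float] = field(default_factory=dict)


@dataclass
class RunConfig:
    input_path: str = ""
    input_format: str = "rules"            # rules | sbml-qual | pd | motif
    stages: Sequence[str] = STAGES
    attractor_method: str = "sat+async"    # exhaustive | sat+async | heuristic
    perturbations: str | Sequence[str] = "all-single"
    scenarios: list[Scenario] = field(default_factory=list)
    output_dir: str = "boolpath_out"
    seed: int = 0
    max_time: float = 10.0
    n_trajectories: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenarios = [Scenario(**s) for s in raw.pop("scenarios", [])]
        cfg = cls(**raw)
        cfg.scenarios = scenarios
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s) {sorted(bad)}")


def load_network(path_or_name: str, fmt: str = "rules") -> BooleanNetwork:
    """Load a network from rule text, SBML-qual, a PD document (translated
    on the fly), or a built-in motif name."""
    if fmt == "motif":
        return motif(path_or_name)
    text = Path(path_or_name).read_text()
    if fmt == "rules":
        return model_io.read_rules(text)
    if fmt == "sbml-qual":
        return model_io.read_sbml_qual(text)
    if fmt == "pd":
        net, _ = translate(read_pd_text(text))
        return net
    raise ValueError(f"unknown input format {fmt!r}")


def attractors_by_method(network: BooleanNetwork, method: str,
                         seed: int = 0) -> list[Attractor]:
    """Run one (or the combined default) attractor-search strategy."""
    if method == "exhaustive":
        return exhaustive_sync(network)
    if method == "sat":
        return [Attractor("steady", (s,), method="sat")
                for s in sat_steady_states(network)]
    if method == "heuristic":
        return heuristic_search(network, n_starts=200, seed=seed)
    if method == "decomposition":
        return decomposition_search(network)
    if method == "async":
        return async_random_walk(network, n_runs=100, seed=seed)
    if method == "sat+async":
        steady = [Attractor("steady", (s,), method="sat")
                  for s in sat_steady_states(network)]
        complexes = [a for a in
                     async_random_walk(network, n_runs=100, seed=seed)
                     if a.kind == "complex"]
        return dedupe(steady + complexes)
    raise ValueError(f"unknown attractor method {method!r}")


def _attractors_json(network: BooleanNetwork,
                     attractors: list[Attractor]) -> str:
    payload = {
        "nodes": network.nodes,
        "attractors": [{
            "kind": a.kind,
            "states": ["".join(map(str, s)) for s in a.states],
            "basin": a.basin,
            "method": a.method,
            "verified": a.verified,
            "certified": a.certified,
        } for a in attractors],
    }
    return json.dumps(payload, indent=1) + "\n"


def run(config: RunConfig,
        network: BooleanNetwork | None = None) -> dict[str, Any]:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dict; raises on the first failing stage (partial
    outputs are flagged ``"incomplete": true`` in the manifest on disk).
    """
    config.validate()
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    if network is None:
        network = load_network(config.input_path, config.input_format)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "nodes": len(network),
        "files": {},
        "incomplete": True,
    }
    manifest_path = outdir / "manifest.json"

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        manifest["files"][name] = hashlib.sha256(text.encode()).hexdigest()
        manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")

    emit("model.rules", model_io.write_rules(network))
    centrality = None
    try:
        if "topology" in config.stages:
            log.info("stage topology: %d nodes", len(network))
            graph = topology.build_graph(network.interaction_edges())
            centrality = topology.centrality_table(graph)
            emit("centrality.tsv", centrality.to_csv(sep="\t", index=False))
        attractors = None
        if "attractors" in config.stages:
            log.info("stage attractors: method=%s", config.attractor_method)
            attractors = attractors_by_method(
                network, config.attractor_method,
                seed=stage_seed(config.seed, "attractors"))
            emit("attractors.json", _attractors_json(network, attractors))
        if "perturbation" in config.stages:
            nodes = (None if config.perturbations == "all-single"
                     else list(config.perturbations))
            log.info("stage perturbation: %s",
                     "all single nodes" if nodes is None else nodes)
            sens = sensitivity_report(
                network, nodes=nodes,
                seed=stage_seed(config.seed, "perturbation"))
            emit("sensitivity.tsv", sens.to_csv(sep="\t", index=False))
            if centrality is not None:
                prio = prioritize_targets(centrality, sens)
                emit("priority.tsv", prio.to_csv(sep="\t", index=False))
        if "simulate" in config.stages:
            log.info("stage simulate: %d scenario(s)",
                     max(1, len(config.scenarios)))
            table = scenario_table(
                config, network,
                seed=stage_seed(config.seed, "simulate"))
            emit("scenarios.tsv", table.to_csv(sep="\t", index=False))
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise RuntimeError(f"stage failure: {exc}") from exc
    manifest["incomplete"] = False
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dict(config.__dict__)
    d["scenarios"] = [s.__dict__ for s in config.scenarios]
    d["stages"] = list(config.stages)
    if not isinstance(d["perturbations"], str):
        d["perturbations"] = list(d["perturbations"])
    return d


def scenario_table(config: RunConfig, network: BooleanNetwork,
                   seed: int | None = None) -> pd.DataFrame:
    """One row per scenario: clamp pattern plus final-time ON-probability
    (± Monte-Carlo standard error) of each named output node.

    Clamping is implemented as a function clamp (knockout/overexpression
    semantics), so clamped inputs hold their level for the whole horizon.
    A node clamped twice with different values is a configuration error.
    """
    if seed is None:
        seed = stage_seed(config.seed, "simulate")
    scenarios = config.scenarios or [
        Scenario(name="baseline", clamps={},
                 outputs=[n for n in network.nodes
                          if not list(_out_neighbors(network, n))])]
    rows = []
    for k, sc in enumerate(scenarios):
        seen: dict[str, int] = {}
        for node, value in sc.clamps.items():
            if node not in network.functions:
                raise KeyError(f"scenario {sc.name!r}: unknown node {node!r}")
            if seen.setdefault(node, value) != value:
                raise ValueError(f"scenario {sc.name!r}: contradictory "
                                 f"clamps on {node!r}")
            if value not in (0, 1):
                raise ValueError(f"scenario {sc.name!r}: clamp value "
                                 f"{value!r} must be 0 or 1")
        for node in sc.outputs:
            if node not in network.functions:
                raise KeyError(f"scenario {sc.name!r}: unknown output "
                               f"{node!r}")
        from .expr import Const
        net = network.copy({node: Const(v) for node, v in sc.clamps.items()})
        initial = {node: float(v) for node, v in sc.clamps.items()}
        initial.update(sc.initial)
        est = simulate_ctmc(net, CtmcConfig(
            n_trajectories=config.n_trajectories,
            max_time=config.max_time,
            seed=seed + k,
            initial_state=initial,
        ))
        row: dict[str, Any] = {"scenario": sc.name}
        row.update({f"clamp:{n}": v for n, v in sc.clamps.items()})
        for out in sc.outputs:
            row[out] = est.final_probability(out)
            row[f"{out}_se"] = est.final_stderr(out)
        rows.append(row)
    return pd.DataFrame(rows)


def _out_neighbors(network: BooleanNetwork, node: str):
    for src, _, tgt in network.interaction_edges():
        if src == node:
            yield tgt


def verify_bundle(output_dir: str | Path) -> dict[str, bool]:
    """Re-hash every file listed in a bundle's manifest; True = intact."""
    outdir = Path(output_dir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    out = {}
    for name, digest in manifest["files"].items():
        path = outdir / name
        out[name] = (path.exists() and
                     hashlib.sha256(path.read_text().encode()).hexdigest()
                     == digest)
    return out
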