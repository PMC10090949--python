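"""Configuration-driven orchestration of the analysis stages.

A run config (YAML or dict) names a model file, a list of stages and
per-stage parameters; ``run_pipeline`` executes the stages in order,
writes one TSV/JSON output per stage into the output directory and
finishes with a manifest recording seeds, input checksums and versions so
identical configs reproduce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .essentiality import (SubstratePanel, essentiality_screen,
                           run_substrate_panel, score_panel)
from .growth import GrowthConstraintSet, normalize_to_substrate, simulate_minimal_growth
from .lp import active_reactions, run_fva, sample_fluxes, solve_fba
from .sbml import read_sbml
from .sodium import (build_halophile_core, reaction_knockout_effect,
                     sodium_influx_sweep)

KNOWN_STAGES = ("growth", "fva", "sampling", "essentiality", "substrates",
                "sodium")


class ConfigError(ValueError):
    """The run configuration is invalid; nothing was executed."""


@dataclass
class RunConfig:
    model_path: str | None
    stages: list[str]
    output_dir: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        stages = raw.get("stages") or []
        if not stages:
            raise ConfigError("empty stage list")
        unknown = [s for s in stages if s not in KNOWN_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}; known: {KNOWN_STAGES}")
        model_path = raw.get("model")
        if model_path is not None and not Path(model_path).exists():
            raise ConfigError(f"model file {model_path!r} does not exist")
        if model_path is None and any(s != "sodium" for s in stages):
            raise ConfigError("a model file is required for these stages")
        return cls(model_path=model_path, stages=list(stages),
                   output_dir=raw.get("output_dir", "natrigem_out"),
                   params=raw.get("params", {}), seed=int(raw.get("seed", 0)))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = read_sbml(config.model_path) if config.model_path else None
    t0 = time.time()
    stage_outputs: dict[str, str] = {}

    for stage in config.stages:
        p = config.params.get(stage, {})
        if stage == "growth":
            constraints = GrowthConstraintSet(
                substrate_exchange=p.get("substrate_exchange", "EX_A"),
                uptake=p.get("uptake", 10.0),
                mass_units=p.get("mass_units", False),
                secretion_floors=p.get("secretion_floors", {}),
            )
            res = simulate_minimal_growth(model, constraints)
            payload = {"mu": res.mu, "yield_g_per_g": res.yield_g_per_g,
                       "uptake_molar": res.uptake_molar}
            path = out / "growth.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        elif stage == "fva":
            res = run_fva(model, fraction=p.get("fraction", 0.98),
                          reaction_ids=p.get("reactions"))
            path = out / "fva.tsv"
            with open(path, "w") as fh:
                fh.write("reaction\tmin\tmax\n")
                uptake = p.get("normalize_to_uptake")
                ranges = (normalize_to_substrate(res, uptake) if uptake
                          else res.ranges)
                for rid in sorted(ranges):
                    lo, hi = ranges[rid]
                    fh.write(f"{rid}\t{lo:.9g}\t{hi:.9g}\n")
        elif stage == "sampling":
            sample = sample_fluxes(model, n=p.get("n", 100),
                                   fraction=p.get("fraction", 0.98),
                                   seed=p.get("seed", config.seed))
            active = active_reactions(sample, p.get("threshold", 1e-6))
            path = out / "sampling.tsv"
            with open(path, "w") as fh:
                fh.write("\t".join(sample.reaction_ids) + "\n")
                for row in sample.matrix:
                    fh.write("\t".join(f"{v:.9g}" for v in row) + "\n")
            (out / "active_reactions.json").write_text(
                json.dumps(sorted(active), indent=2))
        elif stage == "essentiality":
            res = essentiality_screen(model, tau_ess=p.get("threshold", 0.9))
            path = out / "essentiality.tsv"
            with open(path, "w") as fh:
                fh.write("gene\tmu_ko\tessential\n")
                for gene in sorted(res.mu_ko):
                    mu = res.mu_ko[gene]
                    fh.write(f"{gene}\t{'NA' if mu is None else f'{mu:.9g}'}\t"
                             f"{gene in res.essential_genes}\n")
        elif stage == "substrates":
            panel = SubstratePanel(labels={k: bool(v)
                                           for k, v in p["panel"].items()})
            preds = run_substrate_panel(model, panel,
                                        mode=p.get("mode", "extracellular"),
                                        uptake=p.get("uptake", 10.0))
            cm = score_panel(preds, panel)
            path = out / "substrates.json"
            path.write_text(json.dumps({
                "predictions": {k: v for k, v in preds.items()},
                "confusion": {"TP": cm.tp, "FP": cm.fp, "TN": cm.tn,
                              "FN": cm.fn, "accuracy": cm.accuracy},
            }, indent=2, sort_keys=True))
        elif stage == "sodium":
            core = model if model is not None else build_halophile_core()
            grid = p.get("influxes", [20.0 * i for i in range(10)])
            sweep = sodium_influx_sweep(core, grid)
            path = out / "sodium_sweep.tsv"
            with open(path, "w") as fh:
                fh.write("phi_na\tmu\tf_oad\n")
                for phi, mu, f in zip(sweep.influxes, sweep.mu, sweep.f_oad):
                    fh.write(f"{phi:.9g}\t{mu:.9g}\t"
                             f"{'NA' if f is None else f'{f:.9g}'}\n")
            (out / "sodium_knockout.json").write_text(json.dumps({
                "oad_knockout_growth_decrease":
                    reaction_knockout_effect(core, "OAD")}))
        stage_outputs[stage] = str(path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "outputs": stage_outputs,
        "model": config.model_path,
        "model_sha256": _sha256(config.model_path) if config.model_path else None,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
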