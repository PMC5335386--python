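"""Experiment orchestration: scene build → multi-seed simulation → summary.

Ties the stages into the two headline in-silico comparisons (control vs
PAR1-activated scenes, full vs reduced transporter density): a single YAML
configuration describes the conditions, the engine settings and the seed
range; :func:`run_experiment` executes every condition, aggregates across
seeds and writes summary tables; :func:`write_report` renders the
human-readable report.  Every output is traceable to the configuration
hash and seed range recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import (SceneSpec, build_simplified_scene, CONTROL_SPEC,
                       TFLLR_SPEC, CONTROL_SPEC_TABLE2, TFLLR_SPEC_TABLE2)
from .kinetics import TransporterParams
from .mcsim import (SimConfig, run_simulation, aggregate_seeds, count_centroid)

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "run_experiment",
    "write_report",
    "SCENE_PRESETS",
]


class ConfigError(ValueError):
    pass


SCENE_PRESETS = {
    "control": CONTROL_SPEC,
    "tfllr": TFLLR_SPEC,
    "control_table2": CONTROL_SPEC_TABLE2,
    "tfllr_table2": TFLLR_SPEC_TABLE2,
}

_TOP_KEYS = {"experiment", "conditions", "simulation", "kinetics", "output"}
_COND_KEYS = {"name", "scene", "transporter_density"}


@dataclass
class RunManifest:
    """Provenance record of one experiment run."""

    experiment: str
    config: dict
    config_hash: str
    seeds: list[int]
    outputs: list[str]
    summaries: dict[str, dict]
    version: str = __version__
    wall_clock_s: float = 0.0

    def manifest_hash(self) -> str:
        payload = json.dumps(
            {"config": self.config, "summaries": self.summaries},
            sort_keys=True, default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["manifest_hash"] = self.manifest_hash()
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            doc = json.load(fh)
        doc.pop("manifest_hash", None)
        return cls(**doc)


def _parse_seeds(spec) -> list[int]:
    if isinstance(spec, int):
        return list(range(spec))
    if isinstance(spec, str) and ":" in spec:
        lo, hi = spec.split(":")
        return list(range(int(lo), int(hi)))
    if isinstance(spec, list):
        return [int(s) for s in spec]
    raise ConfigError(f"cannot parse seed specification {spec!r}")


def _scene_spec_from(doc) -> SceneSpec:
    if isinstance(doc, str):
        if doc not in SCENE_PRESETS:
            raise ConfigError(f"unknown scene preset {doc!r}; "
                              f"choose from {sorted(SCENE_PRESETS)}")
        return SCENE_PRESETS[doc]
    if not isinstance(doc, dict):
        raise ConfigError("scene must be a preset name or a mapping")
    doc = dict(doc)
    preset = doc.pop("preset", None)
    base = SCENE_PRESETS[preset] if preset else SceneSpec()
    valid = set(SceneSpec.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ConfigError(f"unknown scene keys: {sorted(unknown)}")
    return replace(base, **doc)


def load_config(path_or_dict) -> dict:
    """Load and validate an experiment configuration (strict keys)."""
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if not doc.get("conditions"):
        raise ConfigError("configuration lists no conditions")
    for i, cond in enumerate(doc["conditions"]):
        bad = set(cond) - _COND_KEYS
        if bad:
            raise ConfigError(f"condition {i}: unknown keys {sorted(bad)}")
        if "name" not in cond:
            raise ConfigError(f"condition {i} has no name")
    sim = doc.get("simulation", {})
    valid_sim = set(SimConfig.__dataclass_fields__) | {"seeds"}
    bad = set(sim) - valid_sim - {"tortuosity"}
    if bad:
        raise ConfigError(f"unknown simulation keys: {sorted(bad)}")
    kin = doc.get("kinetics", {})
    bad = set(kin) - set(TransporterParams.__dataclass_fields__)
    if bad:
        raise ConfigError(f"unknown kinetics keys: {sorted(bad)}")
    return doc


def run_experiment(config, out_dir, mesh_resolution: float = 0.02,
                   progress=None) -> RunManifest:
    """Execute every condition of an experiment configuration.

    For each condition: build the scene, run the configured seed range,
    aggregate, and summarize (cleft/neuropil count centroids, cumulative
    reaction totals).  Aggregated time series and the manifest are
    written under ``out_dir``.  Any stage failure aborts with the stage,
    condition and seed in the message.
    """
    import os

    doc = load_config(config)
    os.makedirs(out_dir, exist_ok=True)
    t_start = time.time()

    sim_doc = dict(doc.get("simulation", {}))
    seeds = _parse_seeds(sim_doc.pop("seeds", 30))
    sim = SimConfig(**sim_doc)
    params = TransporterParams(**doc.get("kinetics", {}))
    chash = hashlib.sha1(
        json.dumps(doc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    outputs: list[str] = []
    summaries: dict[str, dict] = {}
    for cond in doc["conditions"]:
        name = cond["name"]
        try:
            spec = _scene_spec_from(cond.get("scene", "control"))
            scene = build_simplified_scene(spec, mesh_resolution)
        except Exception as exc:
            raise ConfigError(
                f"stage=scene condition={name}: {exc}") from exc
        density = cond.get("transporter_density")
        results = []
        for seed in seeds:
            try:
                results.append(
                    run_simulation(scene, sim, seed=seed, transporter=params,
                                   transporter_density=density)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage=simulate condition={name} seed={seed}: {exc}"
                ) from exc
            if progress:
                progress(name, seed)
        agg = aggregate_seeds(results)
        cleft_centroids = [count_centroid(r.time_ms, r.cleft_free)
                           for r in results]
        extra_centroids = [count_centroid(r.time_ms, r.extra_free)
                           for r in results]
        summaries[name] = {
            "n_seeds": len(seeds),
            "transporter_density": density or spec.transporter_density,
            "cleft_centroid_ms_mean": float(np.mean(cleft_centroids)),
            "cleft_centroid_ms_sem": float(np.std(cleft_centroids, ddof=1)
                                           / np.sqrt(len(seeds)))
            if len(seeds) > 1 else 0.0,
            "neuropil_centroid_ms_mean": float(np.mean(extra_centroids)),
            "neuropil_centroid_ms_sem": float(np.std(extra_centroids, ddof=1)
                                              / np.sqrt(len(seeds)))
            if len(seeds) > 1 else 0.0,
            "cum_binding_final": float(agg.mean["cum_bind"][-1]),
            "cum_unbinding_final": float(agg.mean["cum_unbind"][-1]),
            "cum_translocation_final": float(agg.mean["cum_transloc"][-1]),
        }
        df = pd.DataFrame({"time_ms": agg.time_ms})
        for key in ("cleft_free", "extra_free", "bound", "translocated",
                    "cum_bind", "cum_unbind", "cum_transloc"):
            df[f"{key}_mean"] = agg.mean[key]
            df[f"{key}_sem"] = agg.sem[key]
        out_csv = os.path.join(out_dir, f"{name}_{chash[:8]}_timeseries.csv")
        df.to_csv(out_csv, index=False)
        outputs.append(out_csv)

    manifest = RunManifest(
        experiment=doc.get("experiment", "unnamed"),
        config=doc, config_hash=chash, seeds=seeds, outputs=outputs,
        summaries=summaries, wall_clock_s=time.time() - t_start,
    )
    manifest.to_json(f"{out_dir}/manifest.json")
    return manifest


def write_report(manifest: RunManifest) -> str:
    """Render a human-readable summary of an experiment run.

    One table of glutamate-lifetime centroids and one of cumulative
    reaction totals per condition; regeneration from the same manifest is
    idempotent.  A manifest without outputs yields an empty report with a
    warning line.
    """
    import os

    lines = [
        f"Experiment: {manifest.experiment}",
        f"Config hash: {manifest.config_hash}   seeds: "
        f"{manifest.seeds[0]}..{manifest.seeds[-1]}"
        if manifest.seeds else f"Config hash: {manifest.config_hash}",
        "",
    ]
    if not manifest.summaries:
        lines.append("WARNING: empty manifest; nothing to report")
        return "\n".join(lines)
    for path in manifest.outputs:
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest output missing: {path}")
    rows = []
    for name, s in manifest.summaries.items():
        rows.append({
            "condition": name,
            "density (um^-2)": s["transporter_density"],
            "cleft <t> (ms)": round(s["cleft_centroid_ms_mean"], 3),
            "cleft SEM": round(s["cleft_centroid_ms_sem"], 3),
            "neuropil <t> (ms)": round(s["neuropil_centroid_ms_mean"], 3),
            "neuropil SEM": round(s["neuropil_centroid_ms_sem"], 3),
        })
    lines.append("Glutamate lifetime centroids (cleft / neuropil counts):")
    lines.append(pd.DataFrame(rows).to_string(index=False))
    lines.append("")
    rows = [
        {
            "condition": name,
            "binding": round(s["cum_binding_final"], 1),
            "unbinding": round(s["cum_unbinding_final"], 1),
            "translocation": round(s["cum_translocation_final"], 1),
        }
        for name, s in manifest.summaries.items()
    ]
    lines.append("Cumulative transporter reactions (mean per seed, final):")
    lines.append(pd.DataFrame(rows).to_string(index=False))
    return "\n".join(lines)
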