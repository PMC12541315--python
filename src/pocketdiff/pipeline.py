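"""Configuration-driven end-to-end runs and report generation.

`run_pipeline` ties the stages together — synthetic data, mesh/assignment
precomputation, training, sampling, post-correction, collision evaluation —
from a single nested config (dict or YAML path) with a global seed, and
writes a JSON run report whose config hash makes reruns comparable:
identical configs give identical reports up to timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .collisions import CollisionConfig, CollisionReport, collision_trajectory, plcr
from .geometry import correct_complex
from .mesh import MeshParams
from .model import (DenoiserHyperparams, ReferenceDenoiser, SampleConfig, TrainConfig,
                    generate_set, prepare_training_complex, reverse_sample, train)
from .diffusion import build_schedule
from .synth import SynthConfig, make_training_set, write_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "emit_trajectory_csv"]

_SECTIONS = {
    "seed": int,
    "out_dir": str,
    "stages": list,
    "synth_data": dict,
    "mesh": dict,
    "diffusion": dict,
    "model": dict,
    "sampling": dict,
    "correction": dict,
    "evaluation": dict,
}
_DEFAULT_STAGES = ["synth_data", "collide_eval"]


@dataclasses.dataclass
class RunConfig:
    """Schema-validated nested run configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "run_output"
    stages: list = dataclasses.field(default_factory=lambda: list(_DEFAULT_STAGES))
    synth_data: dict = dataclasses.field(default_factory=dict)
    mesh: dict = dataclasses.field(default_factory=dict)
    diffusion: dict = dataclasses.field(default_factory=dict)
    model: dict = dataclasses.field(default_factory=dict)
    sampling: dict = dataclasses.field(default_factory=dict)
    correction: dict = dataclasses.field(default_factory=dict)
    evaluation: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, typ in _SECTIONS.items():
            if key in mapping and not isinstance(mapping[key], typ):
                raise ValueError(f"config key {key!r} must be of type {typ.__name__}")
        known_stages = ["synth_data", "mesh", "train", "sample", "correct", "collide_eval"]
        for st in mapping.get("stages", []):
            if st not in known_stages:
                raise ValueError(f"unknown stage: {st!r}")
        # validate nested section keys against their dataclasses
        _check_keys(mapping.get("synth_data", {}), SynthConfig)
        _check_keys(mapping.get("mesh", {}), MeshParams)
        _check_keys(mapping.get("model", {}), TrainConfig)
        _check_keys(mapping.get("sampling", {}), SampleConfig)
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # execution detail, not part of the scientific config
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _check_keys(section: dict, dc) -> None:
    allowed = {f.name for f in dataclasses.fields(dc)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} for section {dc.__name__}")


@dataclasses.dataclass
class RunReport:
    config_hash: str
    stage_timings: dict
    collision_reports: dict
    loss_curve: list
    file_inventory: list

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, CollisionReport):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), indent=2, default=default)

    def content_hash(self) -> str:
        """Hash over everything except timings (rerun-comparable)."""
        d = dataclasses.asdict(self)
        d.pop("stage_timings")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: RunConfig | dict | str | Path) -> RunReport:
    """Execute the requested stages in order and write report.json to out_dir."""
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = RunConfig.from_mapping(config)
    else:
        cfg = config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    collision_reports: dict[str, dict | list] = {}
    loss_curve: list = []
    inventory: list[str] = []

    complexes = None
    size_dist = None
    dataset = None
    denoiser = None
    samples = None

    def timed(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
            def __exit__(self_inner, *exc):
                timings[name] = time.perf_counter() - self_inner.t0
        return _Timer()

    for stage in cfg.stages:
        if stage == "synth_data":
            with timed(stage):
                synth_cfg = SynthConfig(**{"seed": cfg.seed, **cfg.synth_data})
                complexes, size_dist = make_training_set(synth_cfg)
                manifest = write_dataset(complexes, out_dir / "dataset")
                inventory += [f"dataset/{e['pocket']}" for e in manifest["entries"]]
                inventory += [f"dataset/{e['ligand']}" for e in manifest["entries"]]
                inventory.append("dataset/manifest.json")
        elif stage == "mesh":
            with timed(stage):
                if complexes is None:
                    raise RuntimeError("mesh stage requires synth_data first")
                c = cfg.model.get("mesh_points_per_nucleus", 4)
                params = MeshParams(**cfg.mesh) if cfg.mesh else MeshParams(subdivision_level=1)
                dataset = [prepare_training_complex(cx, c=c, mesh_params=params) for cx in complexes]
        elif stage == "train":
            with timed(stage):
                if dataset is None:
                    raise RuntimeError("train stage requires mesh stage first")
                train_cfg = TrainConfig(**{"seed": cfg.seed, **cfg.model})
                schedule = build_schedule(train_cfg.T, train_cfg.schedule_kind,
                                          **cfg.diffusion)
                denoiser = ReferenceDenoiser(DenoiserHyperparams(init_seed=cfg.seed), schedule)
                loss_curve = train(dataset, denoiser, train_cfg)
        elif stage == "sample":
            with timed(stage):
                if denoiser is None or complexes is None:
                    raise RuntimeError("sample stage requires train stage first")
                sample_cfg = SampleConfig(**{"seed": cfg.seed, **cfg.sampling})
                pockets = [cx.pocket for cx in complexes]
                samples = generate_set(pockets, denoiser, size_dist, sample_cfg)
        elif stage == "correct":
            with timed(stage):
                target = samples if samples is not None else complexes
                if target is None:
                    raise RuntimeError("correct stage requires complexes")
                method = cfg.correction.get("method", "circle")
                seed = cfg.correction.get("seed", 42)
                max_rounds = cfg.correction.get("max_rounds", 10)
                ccfg = CollisionConfig(K=cfg.evaluation.get("K", 10))
                corrected = []
                for cx in target:
                    fixed, _, _ = correct_complex(cx, ccfg, method, seed, max_rounds)
                    corrected.append(fixed)
                if samples is not None:
                    samples = corrected
                else:
                    complexes = corrected
        elif stage == "collide_eval":
            with timed(stage):
                target = samples if samples is not None else complexes
                if target is None:
                    raise RuntimeError("collide_eval stage requires complexes")
                ccfg = CollisionConfig(K=cfg.evaluation.get("K", 10),
                                       strict=cfg.evaluation.get("strict", True))
                collision_reports["pairwise"] = plcr(target, ccfg)
        else:  # unreachable after validation
            raise ValueError(stage)

    report = RunReport(cfg.config_hash(), timings, collision_reports, loss_curve, inventory)
    (out_dir / "report.json").write_text(report.to_json())
    return report


def emit_trajectory_csv(reports: list[tuple[int, CollisionReport]], path=None):
    """One row per evaluated timestep: step, colliding_pairs, denominator, plcr."""
    import pandas as pd

    df = pd.DataFrame(
        [{"step": t, "colliding_pairs": r.colliding_pairs, "denominator": r.denominator,
          "plcr": r.plcr} for t, r in reports],
        columns=["step", "colliding_pairs", "denominator", "plcr"],
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
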