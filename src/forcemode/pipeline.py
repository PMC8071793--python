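"""End-to-end orchestration from inputs to the validation report.

Two input modes share the downstream analysis:

* ``ensemble`` — per-frame feature matrices and observables already
  exist (synthetic or precomputed), read from an ensemble directory or
  generated on the fly from a :class:`SyntheticEnsembleSpec`.
* ``trajectory`` — toy coordinate trajectories plus a nonbonded
  parameter table and up/down references: punctual stress and the
  difference vector are computed here first.

Outputs are written into a run directory named by a hash of the
configuration, so a rerun with identical settings is bit-identical and
never mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .constants import R_CUT, R_SWITCH, STATE_THRESHOLD, STRIDE_PS
from .forces import stress_trajectory
from .observable import ReferencePair, difference_series
from .synthetic import SyntheticEnsembleSpec, generate_force_ensemble
from .validation import Replica, ValidationReport, chain_symmetry, cross_validate


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (exit code 3)."""


class NumericalError(RuntimeError):
    """A numerical stage failed (exit code 4)."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    ``mode`` is ``"ensemble"`` or ``"trajectory"``. For ensemble mode
    either ``ensemble_dir`` (with a manifest) or ``synthetic`` (spec
    fields for on-the-fly generation) must be given. Trajectory mode
    needs ``trajectories`` (multi-model PDBs), ``parameter_table``,
    ``reference_down`` and ``reference_up``.
    """

    mode: str = "ensemble"
    out_dir: str = "forcemode_out"
    seed: int = 0
    # nonbonded model
    r_cut: float = R_CUT
    r_switch: float = R_SWITCH
    stride_ps: float = STRIDE_PS
    # state labelling / PLS
    state_threshold: float = STATE_THRESHOLD
    n_components: int | str = "auto"
    max_components: int = 20
    # ensemble mode
    ensemble_dir: str | None = None
    synthetic: dict | None = None
    # trajectory mode
    trajectories: list[str] = field(default_factory=list)
    parameter_table: str | None = None
    reference_down: str | None = None
    reference_up: str | None = None
    # optional chain-symmetry analysis
    chain_pairing: str | None = None

    def validate(self) -> None:
        if self.r_switch >= self.r_cut:
            raise ConfigError(f"r_switch ({self.r_switch}) must be smaller "
                              f"than r_cut ({self.r_cut})")
        if self.mode not in ("ensemble", "trajectory"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "ensemble":
            if self.ensemble_dir is None and self.synthetic is None:
                raise ConfigError("ensemble mode needs ensemble_dir or a "
                                  "synthetic spec")
        else:
            for name in ("parameter_table", "reference_down", "reference_up"):
                if getattr(self, name) is None:
                    raise ConfigError(f"trajectory mode needs {name}")
            if not self.trajectories:
                raise ConfigError("trajectory mode needs at least one "
                                  "trajectory file")
        for path in self._referenced_paths():
            if not Path(path).exists():
                raise ConfigError(f"referenced file does not exist: {path}")
        if self.n_components != "auto" and int(self.n_components) < 1:
            raise ConfigError("n_components must be 'auto' or >= 1")

    def _referenced_paths(self):
        paths = list(self.trajectories)
        for name in ("parameter_table", "reference_down", "reference_up",
                     "chain_pairing"):
            if getattr(self, name) is not None:
                paths.append(getattr(self, name))
        if self.ensemble_dir is not None:
            paths.append(str(Path(self.ensemble_dir) / "manifest.json"))
        return paths

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


class _JsonLog:
    def __init__(self, path: Path):
        self._path = path
        self._path.write_text("")

    def event(self, stage: str, **payload) -> None:
        record = {"stage": stage, "time": time.time(), **payload}
        with self._path.open("a") as handle:
            handle.write(json.dumps(record, default=str) + "\n")


def _load_replicas(config: PipelineConfig, run_dir: Path, log: _JsonLog):
    if config.mode == "ensemble":
        if config.ensemble_dir is not None:
            try:
                ensemble = fio.read_ensemble(config.ensemble_dir)
            except Exception as exc:
                raise DataError(f"stage load-ensemble: {exc}") from exc
        else:
            spec_dict = dict(config.synthetic)
            spec_dict.setdefault("seed", config.seed)
            if "transition_window" in spec_dict:
                spec_dict["transition_window"] = tuple(
                    spec_dict["transition_window"])
            ensemble = generate_force_ensemble(
                SyntheticEnsembleSpec(**spec_dict))
            fio.write_ensemble(ensemble, run_dir / "ensemble")
        log.event("load-ensemble", n_replicas=ensemble.n_replicas)
        return ensemble.replicas(), ensemble.residue_ids()

    try:
        system = fio.read_system(config.reference_down, config.parameter_table)
        r_down, _ = fio.read_coordinates(config.reference_down)
        r_up, _ = fio.read_coordinates(config.reference_up)
    except Exception as exc:
        raise DataError(f"stage load-references: {exc}") from exc
    selection = np.flatnonzero(system.protein_mask)
    refs = ReferencePair(r_up, r_down, selection)
    replicas = []
    for t, path in enumerate(config.trajectories):
        try:
            frames = fio.read_trajectory(path)
        except Exception as exc:
            raise DataError(f"stage load-trajectory ({path}): {exc}") from exc
        try:
            stress = stress_trajectory(system, frames, config.stride_ps,
                                       config.r_cut, config.r_switch)
            series = difference_series(frames, refs, config.state_threshold,
                                       config.stride_ps)
        except Exception as exc:
            raise NumericalError(f"stage stress/diffvec ({path}): {exc}"
                                 ) from exc
        fio.write_stress_series(stress, run_dir / f"stress_{t:02d}.tsv")
        fio.write_difference_series(series, run_dir / f"diffvec_{t:02d}.tsv")
        replicas.append(Replica(stress.values, series.x, series.labels,
                                replica_id=Path(path).stem))
    log.event("trajectories", n=len(replicas))
    return replicas, system.residue_labels()


def run_pipeline(config: PipelineConfig) -> tuple[ValidationReport, Path]:
    """Run the full inference chain and write all artifacts.

    Returns the validation report and the run directory (named by the
    configuration hash, so identical configs map to identical outputs).
    """
    config.validate()
    run_dir = Path(config.out_dir) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _JsonLog(run_dir / "log.jsonl")
    log.event("start", config=asdict(config), seed=config.seed)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    replicas, residue_ids = _load_replicas(config, run_dir, log)
    try:
        report = cross_validate(replicas, config.n_components,
                                config.state_threshold,
                                config.max_components)
    except Exception as exc:
        raise NumericalError(f"stage cross-validate: {exc}") from exc
    log.event("cross-validate", n_components=report.n_components)

    fio.write_validation_report(report, run_dir / "report.json",
                                run_dir / "summary.tsv")
    fio.write_coefficient_table(residue_ids, report.ensemble_vector,
                                run_dir / "ensemble_vector.tsv")
    if config.chain_pairing is not None:
        pairing = fio.read_chain_pairing(config.chain_pairing)
        sym = chain_symmetry(report.ensemble_vector, residue_ids, pairing)
        sym.pairs.to_csv(run_dir / "chain_pairs.tsv", sep="\t", index=False)
        log.event("chain-symmetry", pearson_r=sym.pearson_r)
    log.event("done")
    return report, run_dir
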