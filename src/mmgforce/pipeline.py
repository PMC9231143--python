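"""End-to-end pipeline: simulate -> preprocess -> features -> GRA -> ICS-SVR.

A :class:`PipelineConfig` round-trips losslessly through YAML; every run
writes the resolved config (with its hash) next to its artifacts so the run
is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import features as feat
from . import gra as gra_mod
from .cuckoo import ICSParams
from .exceptions import ConfigError, MMGForceError
from .model import SVR_BOUNDS, EvaluationReport, evaluate_protocol
from .signal_prep import WindowSpec
from .synthetic import DEFAULT_LEVELS, SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(MMGForceError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full run."""

    # synthetic stage
    mvc_newtons: float = 300.0
    levels: tuple = DEFAULT_LEVELS
    trials_per_level: int = 9
    noise_sd: float = 0.05
    fluctuation_frac: float = 0.04
    amp_gain_intercept: float = 0.2
    amp_gain_slope: float = 0.8
    # windowing
    window_length: int = 1000
    window_overlap: int = 100
    windows_per_level: int = 50
    # features
    feature_groups: tuple = feat.ALL_GROUPS
    # GRA
    rho: float = 0.5
    combination: str = "D"
    # tuning
    tuning_n_nests: int = 10
    tuning_iterations: int = 15
    # evaluation
    n_repetitions: int = 10
    train_frac: float = 0.9
    epsilon: float = 0.01
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["feature_groups"] = list(self.feature_groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        d = dict(d)
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        if "feature_groups" in d:
            d["feature_groups"] = tuple(d["feature_groups"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            mvc_newtons=self.mvc_newtons,
            levels=self.levels,
            noise_sd=self.noise_sd,
            fluctuation_frac=self.fluctuation_frac,
            amp_gain_intercept=self.amp_gain_intercept,
            amp_gain_slope=self.amp_gain_slope,
        )

    def window_spec(self) -> WindowSpec:
        return WindowSpec(length=self.window_length,
                          overlap=self.window_overlap)

    def tuning_params(self) -> ICSParams:
        return ICSParams(
            bounds=SVR_BOUNDS,
            n_nests=self.tuning_n_nests,
            T=self.tuning_iterations,
            seed=self.seed,
        )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MMGForceError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig, out_dir) -> EvaluationReport:
    """Execute all stages and write the five artifacts: features.csv,
    gra_ranking.csv, combinations.csv, report.json and config.yaml.

    Partial outputs are retained when a later stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    config.to_yaml(out / "config.yaml")

    # resolve every sub-config first so bad settings fail before any stage
    syn_cfg = _stage("config")(config.synthetic_config)()
    window_spec = _stage("config")(config.window_spec)()
    tuning = _stage("config")(config.tuning_params)()

    recordings = _stage("synthetic")(generate_dataset)(
        syn_cfg,
        trials_per_level=config.trials_per_level,
        seed=config.seed,
    )
    fm = _stage("features")(feat.extract_dataset)(
        recordings,
        spec=window_spec,
        groups=config.feature_groups,
        windows_per_level=config.windows_per_level,
    )
    fm.meta["config_hash"] = digest
    fm.to_csv(out / "features.csv")

    result = _stage("gra")(gra_mod.feature_force_gra)(fm, rho=config.rho)
    ranking = result.ranking()
    ranking["config_hash"] = digest
    ranking.to_csv(out / "gra_ranking.csv", index=False)
    members = result.membership_table()
    members["config_hash"] = digest
    members.to_csv(out / "combinations.csv", index=False)

    combination = _stage("gra")(gra_mod.select_combination)(
        result, config.combination
    )
    report = _stage("model")(evaluate_protocol)(
        fm,
        combination=combination,
        tune_params=tuning,
        n_reps=config.n_repetitions,
        train_frac=config.train_frac,
        seed=config.seed,
        epsilon=config.epsilon,
    )
    payload = report.to_dict()
    payload["config_hash"] = digest
    payload["selected_features"] = list(combination.names)
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    return report
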