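"""Pipeline configuration and the paper-scale / desk-scale profiles."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .movement import MCMCConfig
from .preprocess import FilterConfig
from .ssf import SSFPriors

# Table-2-magnitude selection coefficients in the fixed covariate order
# (depth, conc, conc2, sdconc, d2land, d2land2, d2ice, d2ice2)
DEFAULT_BETA_TRUE = (0.0, 1.5, -0.7, 0.25, 0.5, -0.3, -1.4, 1.7)


@dataclass(frozen=True)
class SimulateConfig:
    n_per_class: int = 4
    n_steps: dict = field(
        default_factory=lambda: {"AF": 18, "AM": 13, "SA": 13}
    )
    duty_cycle_days: dict = field(
        default_factory=lambda: {"AF": 3.0, "AM": 3.0, "SA": 2.0}
    )
    failure_time_days: dict = field(
        default_factory=lambda: {"AF": None, "AM": 52.0, "SA": 52.0}
    )
    grid_nrows: int = 56
    grid_ncols: int = 56
    cell_size: float = 25_000.0
    n_days: int = 90
    beta_true: tuple = DEFAULT_BETA_TRUE
    error_scale: float = 1.0
    n_candidates: int = 100  # generation candidate pool; large approximates the continuous-choice kernel
    start_date: str = "2015-03-08"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full run from one master seed."""

    seed: int = 0
    profile: str = "desk"
    m_imputations: int = 5
    step_interval_days: float = 4.0
    a_available: int = 25
    angle_mode: str = "bearing"
    simulate: SimulateConfig = SimulateConfig()
    filter: FilterConfig = FilterConfig()
    movement_mcmc: MCMCConfig = MCMCConfig.desk_movement()
    ssf_mcmc: MCMCConfig = MCMCConfig(adapt=500, burnin=1000, iters=1500, thin=3)
    cv_mcmc: MCMCConfig = MCMCConfig(adapt=300, burnin=600, iters=900, thin=3)
    cv_n_datasets: int = 3
    cv_test_frac: float = 0.2
    ssf_priors: SSFPriors = SSFPriors()
    on_ice_filter: bool = True

    @staticmethod
    def paper_profile(seed: int = 0) -> "PipelineConfig":
        """The study-scale schedules (hours of compute)."""
        return PipelineConfig(
            seed=seed,
            profile="paper",
            m_imputations=25,
            movement_mcmc=MCMCConfig(adapt=5000, burnin=100_000, iters=100_000, thin=100),
            ssf_mcmc=MCMCConfig(adapt=5000, burnin=10_000, iters=5_000, thin=5),
            cv_mcmc=MCMCConfig(adapt=5000, burnin=10_000, iters=5_000, thin=5),
            cv_n_datasets=25,
        )

    @staticmethod
    def desk_profile(seed: int = 0) -> "PipelineConfig":
        """Scaled-down schedules; the full pipeline runs in minutes."""
        return PipelineConfig(seed=seed, profile="desk")

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        order = ["simulate", "preprocess", "fit-movement", "fit-ssf", "validate"]
        return np.random.SeedSequence([self.seed, order.index(stage)])

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", "desk")
    base = (
        PipelineConfig.paper_profile() if profile == "paper" else PipelineConfig.desk_profile()
    )
    d = base.to_dict()
    d["profile"] = profile

    def merge(dst: dict, src: dict):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(d, raw)
    return PipelineConfig(
        seed=d["seed"],
        profile=d["profile"],
        m_imputations=d["m_imputations"],
        step_interval_days=d["step_interval_days"],
        a_available=d["a_available"],
        angle_mode=d["angle_mode"],
        simulate=SimulateConfig(**d["simulate"]),
        filter=FilterConfig(**{
            **d["filter"],
            "season_start": tuple(d["filter"]["season_start"]),
            "season_end": tuple(d["filter"]["season_end"]),
        }),
        movement_mcmc=MCMCConfig(**d["movement_mcmc"]),
        ssf_mcmc=MCMCConfig(**d["ssf_mcmc"]),
        cv_mcmc=MCMCConfig(**d["cv_mcmc"]),
        cv_n_datasets=d["cv_n_datasets"],
        cv_test_frac=d["cv_test_frac"],
        ssf_priors=SSFPriors(**d["ssf_priors"]),
        on_ice_filter=d["on_ice_filter"],
    )


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
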