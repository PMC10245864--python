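"""Flat key-value configuration for schedules, training and sampling.

A config file is a flat YAML mapping; recognised keys (all optional):

    sigma_min, sigma_max, rho, n_steps     - noise schedule (A / counts)
    sigma_data                             - preconditioning data scale (A)
    log_mean, log_std                      - training-sigma log-normal
    trans_scale                            - augmentation translation (A)
    churn, step_scale                      - sampling stochasticity / score scale
    resample_p_start, resample_p_end       - sequence-resampling annealing
    stage2_steps, stage2_sigma             - rotamer-repacking stage
    guidance_mode, guidance_weight         - conditioning
    seed                                   - base random seed

Unknown keys are rejected, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .diffusion import NoiseSchedule, Preconditioner, TrainingSigmaDistribution
from .sampler import SamplerConfig

__all__ = ["RunConfig", "load_config"]

_SCHEDULE_KEYS = {"sigma_min", "sigma_max", "rho", "n_steps"}
_SAMPLER_KEYS = {
    "churn", "step_scale", "resample_p_start", "resample_p_end",
    "stage2_steps", "stage2_sigma", "guidance_mode", "guidance_weight", "seed",
}
_OTHER_KEYS = {"sigma_data", "log_mean", "log_std", "trans_scale"}
_ALL_KEYS = _SCHEDULE_KEYS | _SAMPLER_KEYS | _OTHER_KEYS


@dataclass
class RunConfig:
    """Bundle of all configurable objects, echoing the flat key set."""

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    precond: Preconditioner = field(default_factory=Preconditioner)
    sigma_dist: TrainingSigmaDistribution = field(
        default_factory=TrainingSigmaDistribution
    )
    trans_scale: float = 1.0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def describe(self) -> dict:
        s, sp = self.schedule, self.sampler
        return {
            "sigma_min": s.sigma_min, "sigma_max": s.sigma_max,
            "rho": s.rho, "n_steps": s.n_steps,
            "sigma_data": self.precond.sigma_data,
            "log_mean": self.sigma_dist.log_mean,
            "log_std": self.sigma_dist.log_std,
            "trans_scale": self.trans_scale,
            "churn": sp.churn, "step_scale": sp.step_scale,
            "resample_p_start": sp.resample_p_start,
            "resample_p_end": sp.resample_p_end,
            "stage2_steps": sp.stage2_steps, "stage2_sigma": sp.stage2_sigma,
            "guidance_mode": sp.guidance_mode,
            "guidance_weight": sp.guidance_weight,
            "seed": sp.seed,
        }


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _ALL_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sched = NoiseSchedule(**{k: data[k] for k in _SCHEDULE_KEYS if k in data})
    sampler = SamplerConfig(
        schedule=sched, **{k: data[k] for k in _SAMPLER_KEYS if k in data}
    )
    return RunConfig(
        schedule=sched,
        precond=Preconditioner(sigma_data=data.get("sigma_data", 10.0)),
        sigma_dist=TrainingSigmaDistribution(
            log_mean=data.get("log_mean", 0.0), log_std=data.get("log_std", 1.5)
        ),
        trans_scale=data.get("trans_scale", 1.0),
        sampler=sampler,
    )
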