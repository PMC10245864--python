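"""Reverse-process engine: superposition-aware Euler integration.

The sampler maintains two superpositions — the noisy state ``X_t`` and the
running estimate of the clean state ``X_0`` — plus a per-slot record of the
noise level at which each slot was last updated.  Each iteration:

1. collapse ``X_t`` with the current sequence to get the network input
   ``x_t^net`` and run the denoiser at the schedule noise level;
2. with an annealed probability, re-predict the sequence from the denoised
   estimate;
3. update ``X_0`` with the (possibly new) sequence from the denoiser
   output, then collapse ``X_t`` and ``X_0`` with that sequence to get the
   step inputs ``x_t^step`` and ``x_0``;
4. optionally inflate the noise level stochastically ("churn") and take a
   per-atom Euler step of the probability-flow ODE:

       x_{t-1}[a] = x_t[a] + s * (sigma_next - sigma_last[a])
                            * (x_t[a] - x0_hat[a]) / sigma_last[a]

   where ``sigma_last[a]`` is the level at which atom ``a``'s slot was last
   stepped and ``s`` is the step scale;
5. write the result back into ``X_t`` and record ``sigma_next`` for the
   stepped slots.

Backbone slots are addressed by every sequence and therefore stepped at
every iteration; a sidechain slot is stepped only while its residue type is
selected, so its effective step sizes telescope over the iterations at
which it was chosen.  An optional second stage re-initialises and re-packs
the sidechains of the final sequence with the backbone held fixed (rotamer
repacking as a special case of conditional sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .diffusion import NoiseSchedule, sigma_steps
from .residues import (
    AA1_ORDER,
    BACKBONE_SLOTS73,
    CollapsedStructure,
    Superposition,
    collapse,
    sequence_mask,
    update,
)

__all__ = [
    "SamplerConfig",
    "Trajectory",
    "StepRecord",
    "per_atom_euler_step",
    "churn_inflate",
    "anneal_resample_probability",
    "sample",
    "repack_sidechains",
    "replacement_condition",
    "reconstruction_guide",
]

MAX_CHURN_GAMMA = float(np.sqrt(2.0) - 1.0)


# --------------------------------------------------------------------------
# Configuration and trajectory records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling hyper-parameters.

    churn
        Stochastic noise re-injection amount; per-step inflation factor is
        gamma = min(churn / n_steps, sqrt(2) - 1).  0 disables churn and
        makes the solve deterministic given the denoiser.
    step_scale
        Multiplier applied to the score direction before the step-size
        multiplication; values > 1 behave like low-temperature sampling.
    resample_p_start / resample_p_end
        Sequence-resampling probability at sigma_max and at sigma 0; the
        probability is annealed linearly in sigma between them, so the
        sequence stabilises late in the trajectory.
    stage2_steps
        Euler steps of the second (repacking) stage; 0 disables stage 2.
    stage2_sigma
        Noise level at which stage-2 sidechains are re-initialised.
    guidance_mode
        'none', 'replacement' or 'reconstruction' (requires ``known``
        passed to :func:`sample`).
    """

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    churn: float = 0.0
    step_scale: float = 1.0
    resample_p_start: float = 1.0
    resample_p_end: float = 0.2
    stage2_steps: int = 0
    stage2_sigma: float = 10.0
    guidance_mode: str = "none"
    guidance_weight: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.churn < 0:
            raise ValueError("churn must be >= 0")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")
        for p in (self.resample_p_start, self.resample_p_end):
            if not 0.0 <= p <= 1.0:
                raise ValueError("resample probabilities must lie in [0, 1]")
        if self.guidance_mode not in ("none", "replacement", "reconstruction"):
            raise ValueError(f"unknown guidance mode {self.guidance_mode!r}")
        if self.stage2_steps < 0:
            raise ValueError("stage2_steps must be >= 0")


@dataclass
class StepRecord:
    """One sampler iteration: noise levels, sequence, states, bookkeeping."""

    step: int
    sigma: float
    sigma_next: float
    sequence: str
    resampled: bool
    x_t_net: CollapsedStructure
    x0_hat: CollapsedStructure
    slot_sigma_before: np.ndarray      # (L, 73) at entry; (L, 37) in stage 2
    slot_sigma_after: np.ndarray       # (L, 73) after the write-back; (L, 37) in stage 2
    churn_gamma: float
    stage: int = 1


@dataclass
class Trajectory:
    """Per-step records of a sampling run."""

    records: List[StepRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> List[str]:
        return [r.sequence for r in self.records]

    def slot_sigma_history(self) -> np.ndarray:
        """(n_records + 1, L, 73): entry sigma of step 0, then after each step."""
        first = self.records[0].slot_sigma_before
        return np.stack([first] + [r.slot_sigma_after for r in self.records])

    def to_frame(self):
        """Compact per-step log as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [r.step for r in self.records],
                "stage": [r.stage for r in self.records],
                "sigma": [r.sigma for r in self.records],
                "sigma_next": [r.sigma_next for r in self.records],
                "churn_gamma": [r.churn_gamma for r in self.records],
                "resampled": [r.resampled for r in self.records],
                "sequence": [r.sequence for r in self.records],
            }
        )


# --------------------------------------------------------------------------
# Core step operations
# --------------------------------------------------------------------------


def per_atom_euler_step(
    x_t_step: np.ndarray,
    x0_hat: np.ndarray,
    sigma_last: np.ndarray,
    sigma_next: float,
    step_scale: float = 1.0,
) -> np.ndarray:
    """Euler update of the probability-flow ODE with per-atom step sizes.

    ``x_t_step`` and ``x0_hat`` are (..., 3); ``sigma_last`` broadcasts over
    the leading axes and is the noise level at which each atom was last
    stepped.  Atoms with sigma_last == sigma_next are returned unchanged.
    """
    x_t_step = np.asarray(x_t_step, dtype=float)
    x0_hat = np.asarray(x0_hat, dtype=float)
    sigma_last = np.asarray(sigma_last, dtype=float)
    if sigma_next < 0:
        raise ValueError("sigma_next must be >= 0")
    if np.any(sigma_last < sigma_next - 1e-12):
        raise ValueError("sigma_last must be >= sigma_next for every atom")
    moving = sigma_last > sigma_next
    if np.any(moving & (sigma_last == 0)):
        raise ValueError("cannot step an atom with sigma_last == 0 (no score)")
    safe = np.where(sigma_last > 0, sigma_last, 1.0)
    direction = (x_t_step - x0_hat) / safe[..., None]
    delta = (sigma_next - sigma_last)[..., None]       # negative or zero
    step = np.where(moving[..., None], step_scale * delta * direction, 0.0)
    return x_t_step + step


def churn_inflate(
    x_t: np.ndarray,
    sigma: np.ndarray | float,
    churn_amount: float,
    n_steps: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stochastic noise re-injection before an Euler step.

    Inflates the noise level to sigma_hat = sigma * (1 + gamma) with
    gamma = min(churn_amount / n_steps, sqrt(2) - 1) and adds fresh noise
    of scale sqrt(sigma_hat^2 - sigma^2) so the marginal variance matches
    the inflated level.  churn_amount = 0 is the identity.
    """
    if churn_amount < 0:
        raise ValueError("churn_amount must be >= 0")
    x_t = np.asarray(x_t, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), x_t.shape[:-1]).copy()
    if churn_amount == 0:
        return x_t.copy(), sigma
    gamma = min(churn_amount / n_steps, MAX_CHURN_GAMMA)
    sigma_hat = sigma * (1.0 + gamma)
    extra = np.sqrt(np.maximum(sigma_hat**2 - sigma**2, 0.0))
    x_hat = x_t + rng.standard_normal(x_t.shape) * extra[..., None]
    return x_hat, sigma_hat


def anneal_resample_probability(sigma: float, config: SamplerConfig) -> float:
    """Sequence-resampling probability at noise level ``sigma``.

    Linear in sigma from p_start at sigma_max down to p_end at sigma 0:
    early in the trajectory the sequence is resampled almost every step,
    late it is mostly frozen so likely sidechains accumulate steps.
    """
    smax = config.schedule.sigma_max
    frac = np.clip(sigma / smax, 0.0, 1.0)
    return float(
        config.resample_p_end
        + (config.resample_p_start - config.resample_p_end) * frac
    )


# --------------------------------------------------------------------------
# Conditioning
# --------------------------------------------------------------------------


def replacement_condition(
    x_t: CollapsedStructure,
    known: CollapsedStructure,
    known_mask: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> CollapsedStructure:
    """Overwrite conditioned atoms with the known coordinates noised to sigma.

    Atoms outside ``known_mask`` are untouched.  At sigma = 0 the
    conditioned atoms equal the known coordinates exactly.
    """
    known_mask = np.asarray(known_mask, dtype=bool)
    out = x_t.copy()
    z = rng.normal(scale=sigma, size=(int(known_mask.sum()), 3)) if sigma > 0 else 0.0
    out.coords37[known_mask] = known.coords37[known_mask] + z
    return out


def reconstruction_guide(
    x0_hat: CollapsedStructure,
    known: CollapsedStructure,
    known_mask: np.ndarray,
    weight: float,
) -> CollapsedStructure:
    """Pull the denoised estimate toward known atoms by a gradient step.

    One explicit gradient-descent step on the squared conditioning error
    ||x0_hat - known||^2 over the conditioned atoms: they move by
    2 * weight * (known - x0_hat); unconditioned atoms are unchanged.
    """
    if weight < 0:
        raise ValueError("guidance weight must be >= 0")
    known_mask = np.asarray(known_mask, dtype=bool)
    out = x0_hat.copy()
    residual = out.coords37[known_mask] - known.coords37[known_mask]
    out.coords37[known_mask] -= 2.0 * weight * residual
    return out


# --------------------------------------------------------------------------
# The sampling loop
# --------------------------------------------------------------------------


def _validate_sequence(seq: str, L: int, step: int) -> str:
    if len(seq) != L:
        raise ValueError(
            f"sequence predictor returned length {len(seq)} != {L} at step {step}"
        )
    bad = set(seq.upper()) - set(AA1_ORDER)
    if bad:
        raise ValueError(
            f"sequence predictor returned non-canonical codes {bad} at step {step}"
        )
    return seq.upper()


def _validate_denoised(
    pred: CollapsedStructure, L: int, step: int
) -> CollapsedStructure:
    if pred.length != L:
        raise ValueError(f"denoiser returned length {pred.length} != {L} at step {step}")
    return pred


def sample(
    denoiser: Callable,
    seq_predictor: Callable,
    L: int,
    config: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
    known: Optional[CollapsedStructure] = None,
    known_mask: Optional[np.ndarray] = None,
    final_seq_predictor: Optional[Callable] = None,
) -> Tuple[CollapsedStructure, Trajectory]:
    """Generate an all-atom structure + sequence by reverse diffusion.

    Parameters
    ----------
    denoiser, seq_predictor
        Callables satisfying the denoiser / sequence-predictor contracts.
    L
        Number of residues (>= 2).
    known, known_mask
        Conditioning information for replacement/reconstruction guidance.
    final_seq_predictor
        Optional stronger predictor swapped in for the last step's
        sequence; defaults to the running predictor.

    The run is reproducible bit-for-bit from (config, seed).
    """
    if L < 2:
        raise ValueError("need at least 2 residues")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if known is not None and known_mask is None:
        known_mask = known.atom_mask
    sched = config.schedule
    sigmas = sigma_steps(sched)
    n_steps = sched.n_steps

    # All 73 slots i.i.d. Gaussian at sigma_max, centred; X_0 starts at the
    # data mean (the origin) for slots that have never been estimated.
    coords0 = rng.normal(scale=sched.sigma_max, size=(L, 73, 3))
    coords0 -= coords0.reshape(-1, 3).mean(axis=0)
    X_t = Superposition(coords0, np.full((L, 73), sigmas[0]))
    X_0 = Superposition(np.zeros((L, 73, 3)), np.full((L, 73), sigmas[0]))

    seq = "".join(rng.choice(list(AA1_ORDER), size=L))
    traj = Trajectory()
    x0_hat: Optional[CollapsedStructure] = None

    for i in range(n_steps):
        sigma, sigma_next = float(sigmas[i]), float(sigmas[i + 1])
        slot_sigma_before = X_t.slot_sigma.copy()

        x_t_net = collapse(X_t, seq)
        x0_hat = _validate_denoised(
            denoiser(x_t_net, sigma, x0_hat), L, i
        )

        resample = rng.random() < anneal_resample_probability(sigma, config)
        last_step = i == n_steps - 1
        if resample or last_step:
            predictor = (
                final_seq_predictor
                if (last_step and final_seq_predictor is not None)
                else seq_predictor
            )
            seq = _validate_sequence(predictor(x0_hat, sigma, seq), L, i)

        # Write the denoiser's estimate into X_0 under the (possibly new)
        # sequence, restricted to atoms the denoiser output actually carries.
        seq_mask = sequence_mask(seq)
        avail = seq_mask & x0_hat.atom_mask
        X_0 = update(X_0, seq, x0_hat, slot_sigma=sigma, where=avail)

        x_t_step = collapse(X_t, seq)
        x_0_step = collapse(X_0, seq)

        if config.guidance_mode == "replacement" and known is not None:
            x_t_step = replacement_condition(
                x_t_step, known, known_mask & seq_mask, sigma, rng
            )
        elif config.guidance_mode == "reconstruction" and known is not None:
            x_0_step = reconstruction_guide(
                x_0_step, known, known_mask & seq_mask, config.guidance_weight
            )

        # masked channels carry no atom: freeze them at sigma_next
        sigma_last = np.where(seq_mask, x_t_step.atom_sigma, sigma_next)
        coords, sigma_eff = churn_inflate(
            x_t_step.coords37, sigma_last, config.churn, n_steps, rng
        )
        stepped = per_atom_euler_step(
            coords, x_0_step.coords37, sigma_eff, sigma_next, config.step_scale
        )
        x_next = CollapsedStructure(seq, stepped, seq_mask.copy())
        X_t = update(X_t, seq, x_next, slot_sigma=sigma_next)

        gamma = (
            min(config.churn / n_steps, MAX_CHURN_GAMMA) if config.churn > 0 else 0.0
        )
        traj.records.append(
            StepRecord(
                step=i,
                sigma=sigma,
                sigma_next=sigma_next,
                sequence=seq,
                resampled=resample,
                x_t_net=x_t_net,
                x0_hat=x0_hat,
                slot_sigma_before=slot_sigma_before,
                slot_sigma_after=X_t.slot_sigma.copy(),
                churn_gamma=gamma,
            )
        )

    result = collapse(X_t, seq)
    result.atom_sigma = None

    if config.stage2_steps > 0:
        result, stage2_traj = repack_sidechains(
            result, denoiser, config, rng, _stage_offset=n_steps
        )
        traj.records.extend(stage2_traj.records)
    return result, traj


# --------------------------------------------------------------------------
# Stage 2: rotamer repacking
# --------------------------------------------------------------------------

_BACKBONE37 = np.array([0, 1, 2, 4])  # N, CA, C, O atom37 channels


def repack_sidechains(
    structure: CollapsedStructure,
    denoiser: Callable,
    config: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
    _stage_offset: int = 0,
) -> Tuple[CollapsedStructure, Trajectory]:
    """Re-sample the sidechains with the backbone and sequence held fixed.

    Sidechain atoms (everything beyond N, CA, C, O) of the fixed sequence
    are re-initialised with Gaussian noise at ``config.stage2_sigma`` and
    denoised to zero with uniform step sizes; no sequence re-prediction
    takes place.  The backbone coordinates and the sequence are returned
    bit-identical.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = structure.length
    seq_mask = sequence_mask(structure.sequence)
    bb_mask = np.zeros((L, 37), dtype=bool)
    bb_mask[:, _BACKBONE37] = True
    if not np.array_equal(structure.atom_mask & bb_mask, bb_mask):
        raise ValueError("repacking requires all backbone atoms present")
    sc_mask = seq_mask & ~bb_mask

    n2 = max(config.stage2_steps, 1)
    sigma0 = config.stage2_sigma
    sigmas = np.linspace(sigma0, 0.0, n2 + 1)

    x = structure.copy()
    x.atom_mask = seq_mask.copy()
    x.coords37 = np.where(
        sc_mask[..., None],
        x.coords37 + rng.normal(scale=sigma0, size=(L, 37, 3)),
        x.coords37,
    )
    traj = Trajectory()
    for j in range(n2):
        sigma, sigma_next = float(sigmas[j]), float(sigmas[j + 1])
        x0_hat = _validate_denoised(denoiser(x, sigma, None), L, j)
        sigma_last = np.where(sc_mask, sigma, sigma_next)   # backbone frozen
        avail = sc_mask & x0_hat.atom_mask
        x0_coords = np.where(avail[..., None], x0_hat.coords37, x.coords37)
        x.coords37 = per_atom_euler_step(
            x.coords37, x0_coords, sigma_last, sigma_next, step_scale=1.0
        )
        traj.records.append(
            StepRecord(
                step=_stage_offset + j,
                sigma=sigma,
                sigma_next=sigma_next,
                sequence=structure.sequence,
                resampled=False,
                x_t_net=x.copy(),
                x0_hat=x0_hat,
                slot_sigma_before=np.where(sc_mask, sigma, 0.0),
                slot_sigma_after=np.where(sc_mask, sigma_next, 0.0),
                churn_gamma=0.0,
                stage=2,
            )
        )
    out = CollapsedStructure(structure.sequence, x.coords37, seq_mask)
    # conditioning contract: backbone comes back bit-identical
    out.coords37[bb_mask] = structure.coords37[bb_mask]
    return out, traj
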