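"""Analytic denoisers and sequence predictors for exercising the sampler.

These stand in for the trained score network and the structure-conditioned
sequence model so that every sampling pathway can be tested exactly:

* ``perfect_denoiser`` always returns the target coordinates, making the
  probability-flow ODE solvable in a single exact Euler step;
* ``shrinkage_denoiser`` interpolates between the identity map and the
  perfect oracle, giving a controllable imperfection dial;
* the sequence predictors return the target sequence, a fixed sequence, or
  a uniform-random sequence (the latter reproduces the sequence-leakage
  failure mode: sidechains selected at random are denoised too rarely).

A tiny trainable denoiser (a scalar regressor under the EDM
preconditioning, fitted by gradient descent) is included purely as a smoke
test that the DSM objective decreases during optimisation.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .diffusion import Preconditioner, noise, sample_training_sigma, TrainingSigmaDistribution
from .residues import AA1_ORDER, CollapsedStructure, sequence_mask

__all__ = [
    "perfect_denoiser",
    "shrinkage_denoiser",
    "identity_denoiser",
    "oracle_seqpred",
    "fixed_seqpred",
    "random_seqpred",
    "TrainableShrinkageDenoiser",
    "load_plugin",
]


def _check_length(target: CollapsedStructure, x_t: CollapsedStructure) -> None:
    if x_t.length != target.length:
        raise ValueError(
            f"denoiser target has {target.length} residues but input has "
            f"{x_t.length}"
        )


def perfect_denoiser(target: CollapsedStructure) -> Callable:
    """Denoiser oracle: returns the target's coordinates for any input.

    The output carries the target's sequence mask (the atoms the oracle
    actually knows), irrespective of the input mask.
    """
    if not target.has_canonical_mask():
        raise ValueError("oracle target must have a canonical sequence mask")

    def denoise(x_t: CollapsedStructure, sigma: float, self_cond=None) -> CollapsedStructure:
        _check_length(target, x_t)
        return CollapsedStructure(
            sequence=target.sequence,
            coords37=target.coords37.copy(),
            atom_mask=target.atom_mask.copy(),
        )

    return denoise


def shrinkage_denoiser(target: CollapsedStructure, alpha: float) -> Callable:
    """Imperfect oracle: alpha * target + (1 - alpha) * x_t on shared atoms.

    alpha = 1 reduces to the perfect oracle; alpha = 0 is the identity map
    (no denoising at all).  Atoms of the target not present in the input
    mask take the target value scaled by alpha (the identity part has no
    coordinate to contribute).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not target.has_canonical_mask():
        raise ValueError("oracle target must have a canonical sequence mask")

    def denoise(x_t: CollapsedStructure, sigma: float, self_cond=None) -> CollapsedStructure:
        _check_length(target, x_t)
        shared = target.atom_mask & x_t.atom_mask
        coords = alpha * target.coords37.copy()
        coords[shared] += (1.0 - alpha) * x_t.coords37[shared]
        return CollapsedStructure(
            sequence=target.sequence,
            coords37=coords,
            atom_mask=target.atom_mask.copy(),
        )

    return denoise


def identity_denoiser() -> Callable:
    """D(x_t) = x_t; useful for closed-form loss checks."""

    def denoise(x_t: CollapsedStructure, sigma: float, self_cond=None) -> CollapsedStructure:
        return x_t.copy()

    return denoise


# --------------------------------------------------------------------------
# Sequence predictors
# --------------------------------------------------------------------------


def oracle_seqpred(target: CollapsedStructure) -> Callable:
    """Sequence predictor returning the target sequence for any input."""

    def predict(x0_hat: CollapsedStructure, sigma: float, prev_sequence: Optional[str] = None) -> str:
        _check_length(target, x0_hat)
        return target.sequence

    return predict


def fixed_seqpred(sequence: str) -> Callable:
    """Sequence predictor returning a fixed sequence, ignoring the structure."""
    CollapsedStructure(
        sequence, np.zeros((len(sequence), 37, 3)), sequence_mask(sequence)
    )  # validates the alphabet

    def predict(x0_hat: CollapsedStructure, sigma: float, prev_sequence: Optional[str] = None) -> str:
        if x0_hat.length != len(sequence):
            raise ValueError("fixed sequence length does not match structure")
        return sequence

    return predict


def random_seqpred(rng: np.random.Generator) -> Callable:
    """Uniform-random sequence predictor (per position, over the 20 codes)."""
    letters = list(AA1_ORDER)

    def predict(x0_hat: CollapsedStructure, sigma: float, prev_sequence: Optional[str] = None) -> str:
        return "".join(rng.choice(letters, size=x0_hat.length))

    return predict


# --------------------------------------------------------------------------
# Tiny trainable denoiser (smoke test only)
# --------------------------------------------------------------------------


class TrainableShrinkageDenoiser:
    """A one-parameter coordinate regressor under EDM preconditioning.

    D(x, sigma) = c_skip(sigma) * x + c_out(sigma) * w * (c_in(sigma) * x),
    with the scalar ``w`` fitted by stochastic gradient descent on the
    weighted DSM objective.  This is deliberately minimal: it exists to
    demonstrate that the preconditioned training loop reduces the loss, not
    to model proteins.
    """

    def __init__(self, precond: Optional[Preconditioner] = None, w: float = 0.0):
        self.precond = precond or Preconditioner()
        self.w = float(w)

    def __call__(self, x_t: CollapsedStructure, sigma: float, self_cond=None) -> CollapsedStructure:
        p = self.precond
        coords = p.c_skip(sigma) * x_t.coords37 + p.c_out(sigma) * (
            self.w * p.c_in(sigma) * x_t.coords37
        )
        out = x_t.copy()
        out.coords37 = coords
        return out

    def train_step(
        self,
        x0: CollapsedStructure,
        rng: np.random.Generator,
        dist: Optional[TrainingSigmaDistribution] = None,
        lr: float = 0.05,
    ) -> float:
        """One SGD step on one noised example; returns the weighted loss."""
        p = self.precond
        dist = dist or TrainingSigmaDistribution()
        sigma = float(sample_training_sigma(dist, rng))
        x_t = noise(x0.coords37, sigma, rng, mask=x0.atom_mask)
        m = x0.atom_mask
        f = p.c_in(sigma) * x_t[m]                     # network input
        pred = p.c_skip(sigma) * x_t[m] + p.c_out(sigma) * self.w * f
        resid = pred - x0.coords37[m]
        lam = p.loss_weight(sigma)
        loss = lam * float(np.mean(np.sum(resid**2, axis=-1)))
        # d loss / d w, with the same mean-over-atoms reduction
        grad = lam * float(
            np.mean(np.sum(2.0 * resid * p.c_out(sigma) * f, axis=-1))
        )
        self.w -= lr * grad
        return loss


# --------------------------------------------------------------------------
# Plugin discovery
# --------------------------------------------------------------------------


def load_plugin(spec: str) -> Callable:
    """Load an external denoiser/sequence-predictor callable.

    ``spec`` is ``"module.path:attribute"``; the attribute must be a
    callable conforming to the documented contract.
    """
    import importlib

    module_name, _, attr = spec.partition(":")
    if not attr:
        raise ValueError("plugin spec must look like 'module.path:attribute'")
    obj = getattr(importlib.import_module(module_name), attr)
    if not callable(obj):
        raise TypeError(f"plugin {spec!r} is not callable")
    return obj
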