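"""Forward noising process, schedules, preconditioning, and the DSM loss.

The generative process is the variance-exploding probability-flow ODE

    dx = -sigma * grad_x log p_sigma(x) dsigma,      sigma(t) = t,

whose marginals are x_t = x + z, z ~ N(0, sigma_t^2 I): forward diffusion is
plain i.i.d. Gaussian noise on every coordinate component, with scale
growing linearly in time.  Structures are kept centred at the origin so the
isotropic noise yields an SE(n)-invariant density (rotations commute with
the noising; translations are quotiented out by centering).

Training uses a single denoising-score-matching objective

    E_{x0, sigma ~ p_train} [ lambda(sigma) * || D(x_t, sigma) - x0 ||^2 ]

with the EDM preconditioning scalings (c_in, c_out, c_skip, c_noise) and
the matching weight lambda(sigma) = 1 / c_out(sigma)^2, and a log-normal
distribution over training noise levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .residues import CollapsedStructure

__all__ = [
    "NoiseSchedule",
    "Preconditioner",
    "TrainingSigmaDistribution",
    "center",
    "random_rigid_augment",
    "noise",
    "sigma_steps",
    "sample_training_sigma",
    "score_direction",
    "dsm_loss",
]


# --------------------------------------------------------------------------
# Schedule
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSchedule:
    """Discretisation of the sigma(t) = t schedule.

    ``rho`` controls the curvature of the step spacing (rho = 1 gives
    uniform spacing between sigma_max and sigma_min; larger rho concentrates
    steps at low noise).  Defaults follow the EDM sampler: sigma_min 0.01 A,
    sigma_max 80 A, rho 7.
    """

    sigma_min: float = 0.01
    sigma_max: float = 80.0
    rho: float = 7.0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def sigma_steps(schedule: NoiseSchedule) -> np.ndarray:
    """Decreasing noise levels [sigma_max, ..., sigma_min, 0], length n_steps+1.

    For n > 1 the first n levels interpolate between sigma_max and sigma_min
    in sigma^(1/rho) space; the final level is exactly 0 (the ODE is
    integrated all the way to clean data).  n_steps = 1 gives [sigma_max, 0].
    """
    n = schedule.n_steps
    if n == 1:
        return np.array([schedule.sigma_max, 0.0])
    i = np.arange(n)
    inv_rho = 1.0 / schedule.rho
    s = (
        schedule.sigma_max ** inv_rho
        + i / (n - 1) * (schedule.sigma_min ** inv_rho - schedule.sigma_max ** inv_rho)
    ) ** schedule.rho
    s[0], s[-1] = schedule.sigma_max, schedule.sigma_min   # exact endpoints
    return np.concatenate([s, [0.0]])


# --------------------------------------------------------------------------
# SE(n) handling
# --------------------------------------------------------------------------


def center(coords: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Move the unmasked-atom centroid to the origin.

    ``coords`` is (..., 3); ``mask`` broadcasts over the leading axes.
    Masked entries are left untouched.
    """
    coords = np.asarray(coords, dtype=float)
    if mask is None:
        mask = np.ones(coords.shape[:-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot center a structure with no unmasked atoms")
    centroid = coords[mask].mean(axis=0)
    out = coords.copy()
    out[mask] = coords[mask] - centroid
    return out


def random_rigid_augment(
    coords: np.ndarray, rng: np.random.Generator, trans_scale: float = 1.0
) -> np.ndarray:
    """Apply a uniform random proper rotation and a small Gaussian translation.

    The rotation is drawn uniformly from SO(3) (det R = +1: no reflection,
    preserving chirality); the translation is isotropic Gaussian with
    standard deviation ``trans_scale`` Angstrom per component.
    """
    coords = np.asarray(coords, dtype=float)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=trans_scale, size=3) if trans_scale > 0 else np.zeros(3)
    return coords @ R.T + t


def noise(
    coords: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Add i.i.d. N(0, sigma^2) noise to every unmasked coordinate component."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    coords = np.asarray(coords, dtype=float)
    if sigma == 0:
        return coords.copy()
    z = rng.normal(scale=sigma, size=coords.shape)
    if mask is not None:
        z = np.where(np.asarray(mask, dtype=bool)[..., None], z, 0.0)
    return coords + z


# --------------------------------------------------------------------------
# Preconditioning and the training objective
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Preconditioner:
    """EDM network preconditioning scalings.

    With data scale sigma_data (Angstrom):

        c_skip  = sigma_d^2 / (sigma^2 + sigma_d^2)
        c_out   = sigma * sigma_d / sqrt(sigma^2 + sigma_d^2)
        c_in    = 1 / sqrt(sigma^2 + sigma_d^2)
        c_noise = ln(sigma) / 4

    The DSM loss weight is lambda(sigma) = 1 / c_out(sigma)^2, so
    lambda * c_out^2 = 1 identically; as sigma -> 0, c_skip -> 1 and
    c_out -> 0, i.e. the network contribution vanishes on clean data.
    """

    sigma_data: float = 10.0

    def c_skip(self, sigma: float) -> float:
        return self.sigma_data**2 / (sigma**2 + self.sigma_data**2)

    def c_out(self, sigma: float) -> float:
        return sigma * self.sigma_data / math.sqrt(sigma**2 + self.sigma_data**2)

    def c_in(self, sigma: float) -> float:
        return 1.0 / math.sqrt(sigma**2 + self.sigma_data**2)

    def c_noise(self, sigma: float) -> float:
        return 0.25 * math.log(sigma)

    def loss_weight(self, sigma: float) -> float:
        """lambda(sigma) = 1 / c_out(sigma)^2."""
        return (sigma**2 + self.sigma_data**2) / (sigma * self.sigma_data) ** 2


@dataclass(frozen=True)
class TrainingSigmaDistribution:
    """Log-normal distribution over training noise levels.

    ln(sigma) ~ N(log_mean, log_std^2); samples are strictly positive.
    Defaults put the mode of sigma mid-schedule on the Angstrom scale of
    protein coordinates.
    """

    log_mean: float = 0.0
    log_std: float = 1.5

    def __post_init__(self) -> None:
        if self.log_std <= 0:
            raise ValueError("log_std must be positive")


def sample_training_sigma(
    dist: TrainingSigmaDistribution, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    """Draw sigma with ln(sigma) ~ N(log_mean, log_std^2)."""
    return np.exp(rng.normal(dist.log_mean, dist.log_std, size=size))


def score_direction(
    x_t: np.ndarray, x0_hat: np.ndarray, sigma: float | np.ndarray
) -> np.ndarray:
    """Per-atom ODE step direction d = (x_t - x0_hat) / sigma.

    Equals -sigma * (estimated score): the direction pointing from the data
    estimate toward the noisy state, normalised by the noise level.
    ``sigma`` may be a scalar or a per-atom array broadcastable against the
    leading axes of ``x_t``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("score_direction requires sigma > 0")
    return (np.asarray(x_t) - np.asarray(x0_hat)) / sigma[..., None] if sigma.ndim else (
        np.asarray(x_t) - np.asarray(x0_hat)
    ) / float(sigma)


def dsm_loss(
    denoiser,
    x0: CollapsedStructure,
    sigma: float,
    rng: np.random.Generator,
    precond: Preconditioner | None = None,
) -> float:
    """Weighted denoising-score-matching loss for one structure and noise level.

    Noises ``x0`` at level ``sigma``, runs the denoiser, and returns
    lambda(sigma) times the mean (over unmasked atoms) squared residual
    norm between the denoiser output and the clean coordinates.
    """
    if sigma <= 0:
        raise ValueError("dsm_loss requires sigma > 0")
    if not x0.atom_mask.any():
        raise ValueError("structure has no unmasked atoms")
    precond = precond or Preconditioner()
    x_t = x0.copy()
    x_t.coords37 = noise(x0.coords37, sigma, rng, mask=x0.atom_mask)
    x_t.atom_sigma = np.full(x0.atom_mask.shape, float(sigma))
    pred = denoiser(x_t, sigma)
    residual = pred.coords37[x0.atom_mask] - x0.coords37[x0.atom_mask]
    mse = float(np.mean(np.sum(residual**2, axis=-1)))
    return precond.loss_weight(sigma) * mse
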