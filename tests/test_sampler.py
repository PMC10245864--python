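"""Per-atom Euler stepping, churn, annealing, conditioning, and the full
superposition sampling loop with analytic oracles."""

import numpy as np
import pytest

from atomdiff.diffusion import NoiseSchedule, sigma_steps
from atomdiff.oracles import (
    oracle_seqpred,
    perfect_denoiser,
    random_seqpred,
    shrinkage_denoiser,
)
from atomdiff.residues import BACKBONE_SLOTS73, sequence_mask
from atomdiff.sampler import (
    SamplerConfig,
    anneal_resample_probability,
    churn_inflate,
    per_atom_euler_step,
    reconstruction_guide,
    repack_sidechains,
    replacement_condition,
    sample,
)

_BB37 = np.array([0, 1, 2, 4])


# ------------------------------------------------------------- Euler step


def test_euler_step_hand_values():
    x = np.array([[1.0, 0.0, 0.0]])
    x0 = np.zeros((1, 3))
    out = per_atom_euler_step(x, x0, np.array([2.0]), 1.0, step_scale=1.0)
    assert out[0, 0] == pytest.approx(0.5)
    out = per_atom_euler_step(x, x0, np.array([2.0]), 1.0, step_scale=1.2)
    assert out[0, 0] == pytest.approx(0.4)


def test_euler_step_to_zero_returns_x0(rng):
    x = rng.normal(size=(10, 3))
    x0 = rng.normal(size=(10, 3))
    sl = rng.uniform(0.5, 80.0, size=10)
    out = per_atom_euler_step(x, x0, sl, 0.0, step_scale=1.0)
    assert np.allclose(out, x0, atol=1e-12)


def test_euler_step_zero_delta_unchanged(rng):
    x = rng.normal(size=(6, 3))
    out = per_atom_euler_step(x, np.zeros_like(x), np.full(6, 3.0), 3.0)
    assert np.array_equal(out, x)


def test_euler_step_rejects_increasing_sigma():
    with pytest.raises(ValueError):
        per_atom_euler_step(np.zeros((1, 3)), np.zeros((1, 3)), np.array([1.0]), 2.0)


# ------------------------------------------------------------------ churn


def test_churn_zero_identity(rng):
    x = rng.normal(size=(5, 3))
    xh, sh = churn_inflate(x, 2.0, 0.0, 10, rng)
    assert np.array_equal(xh, x) and np.all(sh == 2.0)


def test_churn_inflates_sigma(rng):
    _, sh = churn_inflate(np.zeros((4, 3)), 2.0, 5.0, 10, rng)
    assert np.all(sh >= 2.0)
    # gamma capped at sqrt(2)-1
    _, sh = churn_inflate(np.zeros((4, 3)), 2.0, 1e6, 10, rng)
    assert np.allclose(sh, 2.0 * np.sqrt(2.0))


def test_churn_marginal_variance():
    """After inflation the marginal variance equals sigma_hat^2."""
    rng = np.random.default_rng(1)
    sigma, churn, n_steps, n = 3.0, 4.0, 10, 200_000
    x = rng.normal(scale=sigma, size=(n, 3))
    xh, sh = churn_inflate(x, sigma, churn, n_steps, rng)
    var = xh.var(axis=0).mean()
    target = float(sh.flat[0]) ** 2
    se = target * np.sqrt(2.0 / (3 * n - 1))
    assert abs(var - target) < 4 * se


# -------------------------------------------------------------- annealing


def test_anneal_boundaries_and_monotone():
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=30))
    sig = sigma_steps(cfg.schedule)
    ps = [anneal_resample_probability(s, cfg) for s in sig]
    assert ps[0] == pytest.approx(cfg.resample_p_start)
    assert ps[-1] == pytest.approx(cfg.resample_p_end)
    assert all(a >= b for a, b in zip(ps, ps[1:]))


# ----------------------------------------------------------- conditioning


def test_replacement_sigma_zero_exact(rng, helix50):
    known_mask = helix50.atom_mask.copy()
    known_mask[25:] = False
    noisy = helix50.copy()
    noisy.coords37 = noisy.coords37 + 5.0
    out = replacement_condition(noisy, helix50, known_mask, 0.0, rng)
    assert np.array_equal(out.coords37[known_mask], helix50.coords37[known_mask])
    assert np.array_equal(out.coords37[~known_mask], noisy.coords37[~known_mask])


def test_replacement_marginal_variance(helix50):
    rng = np.random.default_rng(2)
    known_mask = np.zeros_like(helix50.atom_mask)
    known_mask[0, 0] = True
    sigma = 2.0
    devs = []
    for _ in range(20_000):
        out = replacement_condition(helix50, helix50, known_mask, sigma, rng)
        devs.append(out.coords37[0, 0] - helix50.coords37[0, 0])
    var = np.var(devs, axis=0).mean()
    se = sigma**2 * np.sqrt(2.0 / (3 * 20_000 - 1))
    assert abs(var - sigma**2) < 4 * se


def test_reconstruction_guide_weight_zero_identity(helix50):
    out = reconstruction_guide(helix50, helix50, helix50.atom_mask, 0.0)
    assert np.array_equal(out.coords37, helix50.coords37)


def test_reconstruction_guide_reduces_residual(rng, helix50):
    known_mask = helix50.atom_mask.copy()
    x0 = helix50.copy()
    x0.coords37 = x0.coords37 + rng.normal(size=x0.coords37.shape)
    before = np.linalg.norm(x0.coords37[known_mask] - helix50.coords37[known_mask])
    out = reconstruction_guide(x0, helix50, known_mask, 0.1)
    after = np.linalg.norm(out.coords37[known_mask] - helix50.coords37[known_mask])
    assert after < before
    # unconditioned atoms untouched
    out2 = reconstruction_guide(x0, helix50, np.zeros_like(known_mask), 0.1)
    assert np.array_equal(out2.coords37, x0.coords37)


# ------------------------------------------------------------ full sampler


@pytest.mark.parametrize("n_steps", [1, 10, 100])
def test_oracle_recovery(mixed_target, n_steps):
    """Perfect denoiser + oracle sequence predictor recover the target
    exactly, for any step count."""
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=n_steps), churn=0.0, seed=5)
    out, traj = sample(
        perfect_denoiser(mixed_target), oracle_seqpred(mixed_target),
        mixed_target.length, cfg,
    )
    assert out.sequence == mixed_target.sequence
    err = np.abs(
        out.coords37[out.atom_mask] - mixed_target.coords37[mixed_target.atom_mask]
    ).max()
    assert err < 1e-6
    assert len(traj) == n_steps


def test_oracle_recovery_any_seed(mixed_target):
    for seed in (0, 1, 99):
        cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=5), churn=0.0, seed=seed)
        out, _ = sample(
            perfect_denoiser(mixed_target), oracle_seqpred(mixed_target),
            mixed_target.length, cfg,
        )
        assert out.sequence == mixed_target.sequence


def test_seeded_trajectory_bit_identical(mixed_target):
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=15), churn=3.0, seed=21)
    runs = [
        sample(shrinkage_denoiser(mixed_target, 0.9), oracle_seqpred(mixed_target),
               mixed_target.length, cfg)
        for _ in range(2)
    ]
    (o1, t1), (o2, t2) = runs
    assert np.array_equal(o1.coords37, o2.coords37)
    assert o1.sequence == o2.sequence
    for r1, r2 in zip(t1.records, t2.records):
        assert r1.sequence == r2.sequence
        assert np.array_equal(r1.x0_hat.coords37, r2.x0_hat.coords37)
        assert np.array_equal(r1.slot_sigma_after, r2.slot_sigma_after)


def test_backbone_stepped_every_iteration(mixed_target):
    """The four shared backbone slots hit every sigma of the schedule."""
    n = 12
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=n), churn=0.0, seed=3)
    _, traj = sample(
        shrinkage_denoiser(mixed_target, 0.9), oracle_seqpred(mixed_target),
        mixed_target.length, cfg,
    )
    sig = sigma_steps(cfg.schedule)
    for k, rec in enumerate(traj.records):
        bb = rec.slot_sigma_after[:, BACKBONE_SLOTS73]
        assert np.allclose(bb, sig[k + 1])


def test_per_slot_sigma_non_increasing_and_telescoping(mixed_target):
    """Per-slot sigma never increases; applied step sizes telescope to
    sigma_first - sigma_final per slot (churn-free run)."""
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=20), churn=0.0, seed=13)
    _, traj = sample(
        shrinkage_denoiser(mixed_target, 0.8), oracle_seqpred(mixed_target),
        mixed_target.length, cfg,
    )
    hist = traj.slot_sigma_history()            # (n+1, L, 73)
    assert np.all(np.diff(hist, axis=0) <= 1e-12)
    deltas = -(np.diff(hist, axis=0))           # per-step applied delta sigma
    assert np.allclose(deltas.sum(axis=0), hist[0] - hist[-1])


def test_never_selected_slots_keep_sigma(mixed_target):
    """Sidechain slots of residue types never predicted stay at sigma_max
    and are absent from the output mask; selected slots reach 0."""
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=10), churn=0.0, seed=4)
    out, traj = sample(
        perfect_denoiser(mixed_target), oracle_seqpred(mixed_target),
        mixed_target.length, cfg,
    )
    final_sigma = traj.records[-1].slot_sigma_after      # (L, 73)
    from atomdiff.residues import ATOM73

    for i, c in enumerate(out.sequence):
        sel = ATOM73.slots_for(c)
        assert np.all(final_sigma[i, sel] == 0.0)
        unsel = np.setdiff1d(np.arange(73), sel)
        # everything outside the final sequence's slots was last written at
        # some positive noise level (sigma_max if never selected)
        assert np.all(final_sigma[i, unsel] > 0.0)


def test_convergence_error_monotone_in_alpha(mixed_target):
    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=100), churn=0.0, seed=3)
    errs = []
    for alpha in (0.5, 0.9, 0.99, 1.0):
        out, _ = sample(
            shrinkage_denoiser(mixed_target, alpha), oracle_seqpred(mixed_target),
            mixed_target.length, cfg,
        )
        errs.append(
            np.abs(out.coords37[out.atom_mask]
                   - mixed_target.coords37[mixed_target.atom_mask]).max()
        )
    assert errs == sorted(errs, reverse=True)
    assert errs[-1] < 1e-6


def test_short_length_rejected(mixed_target):
    with pytest.raises(ValueError):
        sample(perfect_denoiser(mixed_target), oracle_seqpred(mixed_target),
               1, SamplerConfig())


def test_contract_violation_reports_step(mixed_target):
    def bad_seqpred(x0_hat, sigma, prev_sequence=None):
        return "A"  # wrong length

    with pytest.raises(ValueError, match="step 0"):
        sample(perfect_denoiser(mixed_target), bad_seqpred,
               mixed_target.length, SamplerConfig(schedule=NoiseSchedule(n_steps=3)))


# --------------------------------------------------------------- repacking


def test_repack_backbone_bit_identical(mixed_target):
    cfg = SamplerConfig(stage2_steps=8, stage2_sigma=10.0)
    out, traj = repack_sidechains(
        mixed_target, perfect_denoiser(mixed_target), cfg, np.random.default_rng(0)
    )
    assert np.array_equal(out.coords37[:, _BB37], mixed_target.coords37[:, _BB37])
    assert out.sequence == mixed_target.sequence
    assert np.array_equal(out.atom_mask, sequence_mask(out.sequence))
    # perfect oracle recovers the target sidechains exactly
    err = np.abs(
        out.coords37[out.atom_mask] - mixed_target.coords37[mixed_target.atom_mask]
    ).max()
    assert err < 1e-9
    assert len(traj) == 8


def test_repack_missing_backbone_rejected(mixed_target):
    broken = mixed_target.copy()
    broken.atom_mask[3, 1] = False       # drop a CA
    with pytest.raises(ValueError, match="backbone"):
        repack_sidechains(broken, perfect_denoiser(mixed_target),
                          SamplerConfig(stage2_steps=2), np.random.default_rng(0))


# ----------------------------------------------------- degradation testbed


def test_random_sequence_predictor_degrades_quality(mixed_target):
    """Uniform-random sequence selection starves sidechains of denoising
    steps: bond-length RMSE blows up versus the oracle predictor."""
    from atomdiff.geometry import bond_length_rmse

    cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=100), churn=0.0, seed=3)
    out_oracle, _ = sample(
        shrinkage_denoiser(mixed_target, 0.9), oracle_seqpred(mixed_target),
        mixed_target.length, cfg,
    )
    out_random, _ = sample(
        shrinkage_denoiser(mixed_target, 0.9),
        random_seqpred(np.random.default_rng(99)),
        mixed_target.length, cfg,
    )
    r_oracle = bond_length_rmse(out_oracle)
    r_random = bond_length_rmse(out_random)
    assert r_random >= 2.0 * r_oracle
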