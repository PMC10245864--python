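# atomdiff

All-atom protein diffusion sampling with sidechain **superpositions** — a
tested library and CLI for structural-bioinformatics and protein-design
researchers who want to study, extend or stress-test the machinery of
all-atom structure/sequence co-design without trained network weights.

## The problem and the model

Generating a complete protein means generating its backbone, its sequence
and its sidechain atoms together — but which sidechain atoms exist at a
position depends on the (unknown, evolving) sequence. `atomdiff`
implements the resolution in which the reverse diffusion acts on a
*superposition* of all twenty possible sidechains per residue.

The generative process is the variance-exploding probability-flow ODE

```
dx = −σ ∇ₓ log p_σ(x) dσ,        σ(t) = t,
```

with marginals `x_t = x + z, z ~ N(0, σ_t² I)`: forward diffusion is plain
isotropic Gaussian noise on atomic coordinates, with structures centred at
the origin so the induced density is SE(n)-invariant.  A denoiser `D(x_t,
σ) → x̂₀` supplies the score estimate `∇ₓ log p_σ ≈ (x̂₀ − x_t)/σ²` and the
ODE is integrated by Euler steps `x_{t−1} = x_t + s·Δσ·(x_t − x̂₀)/σ`.

State is kept in the **atom73** layout: 5 slots shared by every residue
type (N, CA, C, CB, O) plus disjoint per-type blocks for the remaining 68
sidechain atoms.  At each step the superposition is **collapsed** with the
current sequence into a concrete masked **atom37** structure, denoised, a
sequence is re-predicted (with an annealed resampling probability), and
the slots of the chosen residue types are stepped and **updated**.  The
crucial freedom is that *the integration step size varies per atom*:
backbone slots step every iteration, while a sidechain slot steps only
when its residue type is selected, accumulating larger Δσ between visits.
A second, cheap sampling stage re-packs the sidechains with the backbone
and sequence fixed (rotamer packing as a conditional special case).

The denoiser and sequence predictor are *contracts*, not networks:
analytic oracles (perfect, shrinkage-imperfect, random) make every code
path exactly testable, and external models plug in as callables.  A
geometry suite scores chemical validity — bond lengths and angles against
an ideal table, χ/φ/ψ torsions, Cα chirality — with bond-length RMSE as
the headline scalar (natural unrelaxed proteins score ≈ 0.02 Å; ideal
fixtures score 0).

## Worked example

```python
import numpy as np
from atomdiff import (build_fixture, mixed_rotamer_spec, shrinkage_denoiser,
                      oracle_seqpred, random_seqpred, sample, SamplerConfig,
                      NoiseSchedule, bond_length_rmse)

target = build_fixture(mixed_rotamer_spec(50, seed=7))   # all-atom fixture
cfg = SamplerConfig(schedule=NoiseSchedule(n_steps=100), churn=0.0, seed=3)

out, traj = sample(shrinkage_denoiser(target, 0.9),      # imperfect denoiser
                   oracle_seqpred(target), 50, cfg)
print(np.abs(out.coords37[out.atom_mask]
             - target.coords37[target.atom_mask]).max())  # 0.0092 A
print(bond_length_rmse(out))                              # 0.0037 A

bad, _ = sample(shrinkage_denoiser(target, 0.9),
                random_seqpred(np.random.default_rng(99)), 50, cfg)
print(bond_length_rmse(bad))                              # 8.19 A
```

With a denoiser that is 90 % oracle, co-design with the matching sequence
predictor converges to within 0.01 Å of the target and near-ideal
chemistry (0.0037 Å bond RMSE).  Swapping in a uniform-random sequence
predictor starves the sidechain slots of denoising steps and chemistry
collapses (8.19 Å bond RMSE) — the sequence-leakage failure mode, on
matched seeds.  With the *perfect* oracle the sampler recovers the target
exactly (max error < 1e-6 Å) for any step count, including a single step.

The same workflows are available from the shell:

```sh
atomdiff fixtures --preset helix --length 50 --out helix.pdb
atomdiff noise    --in helix.pdb --sigma 1.0 --seed 1 --out noisy.pdb
atomdiff sample   --length 20 --steps 100 --seed 2 --out sample.pdb
atomdiff repack   --in sample.pdb --steps 25 --out repacked.pdb
atomdiff eval     --in noisy.pdb --report json
```

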