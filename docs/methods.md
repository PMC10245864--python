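# Methods

## Model

`atomdiff` implements reverse diffusion for all-atom protein structures
under the variance-exploding probability-flow ODE `dx = −σ ∇ₓ log p_σ(x)
dσ` with `σ(t) = t`.  The marginals are `x_t ~ N(x, σ_t² I)` on every
coordinate component, so the forward process is exact Gaussian noising and
needs no superposition bookkeeping; only the reverse process does.
Structures are centred at the origin before noising; because the isotropic
Gaussian is rotation-invariant and centering quotients out translation,
the modelled density is SE(n)-invariant.  Proper rotations only
(det R = +1) are used in augmentation, preserving chirality.

### State representation

Sequence identity determines which sidechain atoms exist, so during
co-design the atom set changes between steps.  The sampler therefore keeps
the coordinates of *all twenty* possible sidechains per position in a
73-slot layout (`atom73`): five shared slots (N, CA, C, CB, O — CB is
shared because every non-glycine type has one) followed by disjoint
exclusive blocks per residue type totalling 68 sidechain slots.  Concrete
structures use the dense 37-name `atom37` layout with a boolean mask.  The
37-name vocabulary follows the AlphaFold ordering and includes a reserved
`OXT` slot for the C-terminal carboxyl oxygen that this package never
models (36 names occur inside residue types); `OXT` and hydrogens are
dropped on input everywhere.

`collapse(X, seq)` copies, per residue, the slots of `seq[i]` into atom37
channels and masks the rest; `update(X, seq, s)` writes a structure's
coordinates back into exactly those slots, leaving all others bit-
identical.  Per-slot noise levels (`slot_sigma`) record the σ at which
each slot was last written and are non-increasing over a trajectory.

### Sampling loop

Per iteration at schedule level σ_i: collapse `X_t` with the current
sequence → run the denoiser (the previous step's estimate is passed as a
self-conditioning payload; contract implementations are free to ignore
it) → with probability `p(σ)` re-predict the sequence from the denoised
estimate → update `X_0` under the *new* sequence, restricted to atoms the
denoiser output carries → collapse `X_t` and `X_0` with the new sequence →
optional churn → per-atom Euler step

```
x_{t-1}[a] = x_t[a] + s · (σ_next − σ_last[a]) · (x_t[a] − x̂₀[a]) / σ_last[a]
```

→ write back into `X_t` with `slot_sigma = σ_next`.  The network input and
the step input are distinct collapses (the sequence may have changed in
between); backbone slots are addressed by every sequence and hence stepped
at every iteration, while a sidechain slot is stepped only when selected,
so its per-step Δσ telescopes over the iterations at which it was chosen.

Ordering the `X_0` update *after* sequence re-prediction is a deliberate
design choice: the update semantics tie newly predicted coordinates to the
newly predicted residue type, and it makes the single-step limit exact —
with a perfect denoiser and oracle sequence predictor, one Euler step to
σ = 0 returns the target structure exactly, a property the test suite
asserts to < 1e-6 Å for n_steps ∈ {1, 10, 100}.  Under
update-before-re-predict, slots newly selected in the same step would move
toward stale estimates.

Slots never yet estimated hold the data mean (the origin, since structures
are centred) in `X_0`; stepping toward the prior mean is the correct
behaviour for an atom with no information.  Unselected slots between
selections are frozen — no noise re-injection — and retain their σ.

### Initialisation, churn, annealing

All 73 slots initialise i.i.d. `N(0, σ_max²)`, centred, with `slot_sigma =
σ_max`; the initial sequence is drawn uniformly at random from the seed
(at σ_max the resampling probability is 1, so it is immediately replaced
by a prediction).  Churn follows the stochastic variant of the reference
Euler sampler: γ = min(churn/n_steps, √2 − 1), σ̂ = σ(1 + γ), with fresh
noise of scale √(σ̂² − σ²) added before the step; churn = 0 recovers the
deterministic solve.  The step scale multiplies the score direction before
the Δσ multiplication (values > 1 act like low-temperature sampling).  The
sequence-resampling probability anneals **linearly in σ** from p_start
(default 1.0 at σ_max) to p_end (default 0.2 at σ = 0); the linear form is
the simplest monotone choice and its endpoints are configurable.

### Stage 2: rotamer repacking

With backbone and sequence fixed, sidechain atoms (everything beyond
N, CA, C, O) are re-initialised with Gaussian noise at `stage2_sigma`
(default 10 Å — comfortably above sidechain spatial extent, well below
σ_max since the backbone context is known) and denoised to 0 with uniform
Δσ over `stage2_steps` (default 25), without sequence re-prediction.  The
backbone is returned bit-identical.

### Conditioning

Replacement guidance overwrites conditioned atoms with `known + N(0, σ²)`
each step (exact at σ = 0).  Reconstruction guidance takes one explicit
gradient step on the squared conditioning error of the denoised estimate:
conditioned atoms move by `2 · weight · (known − x̂₀)`; weight defaults to
0.1, constant in σ.

### Training objective

The denoising-score-matching loss is `λ(σ) ‖D(x_t, σ) − x₀‖²`, reduced as
the mean over unmasked atoms of the squared residual norm (then over the
batch).  Noise levels are drawn log-normally (`ln σ ~ N(log_mean,
log_std²)`, defaults 0.0 and 1.5, putting the σ mode on the Å scale of
protein coordinates mid-schedule).  Preconditioning uses the EDM scalings
with data scale σ_data (default 10 Å, the coordinate scale of centred
50–300-residue chains):

```
c_skip = σ_d²/(σ²+σ_d²)   c_out = σσ_d/√(σ²+σ_d²)
c_in   = 1/√(σ²+σ_d²)     c_noise = ln(σ)/4       λ = 1/c_out²
```

so `λ·c_out² = 1` identically and `c_skip → 1, c_out → 0` as σ → 0.
Augmentation applies a uniform random proper rotation plus an isotropic
Gaussian translation of scale 1 Å (a "small" translation relative to the
10 Å data scale).  Training-time mask obscuring fills all 37 atom channels
— real atoms noised in place, absent atoms filled with noise of the same
scale centred on the residue's CA (keeping filler spatially local) — so
sequence identity is not recoverable from the mask pattern.

## Schedule and parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| σ_min / σ_max | 0.01 / 80 | Å | reference Euler sampler defaults |
| ρ | 7 | – | concentrates steps at low σ |
| n_steps | 100 | – | desk-scale trajectories |
| σ_data | 10 | Å | coordinate scale of centred chains |
| churn / step_scale | 0 / 1.0 | – | deterministic baseline |
| resample p_start → p_end | 1.0 → 0.2 | – | sequence stabilises late |
| stage2_sigma / steps | 10 Å / 25 | | see above |
| guidance weight | 0.1 | – | conservative pull |

The discretised schedule interpolates in σ^(1/ρ) space between σ_max and
σ_min (endpoints exact) and appends a final 0, so the ODE is integrated
all the way to clean data; n_steps = 1 gives [σ_max, 0].

## Synthetic fixtures and the geometry suite

Fixtures are built from internal coordinates by NeRF placement: each atom
placed from three references by (bond length, bond angle, torsion).
Backbone parameters are Engh–Huber-style standards; sidechain z-matrices
express rotatable torsions as χ angles and fix rigid groups, with aromatic
rings laid out as exact regular polygons (imidazole side 1.370 Å, benzene
side 1.390 Å) so ring closures are exact.  The ideal bond-length/angle
tables are *measured once from reference residue builds of this same
dataset*, making builder and metrics exactly self-consistent: any fixture
built at any rotamer scores bond-length RMSE 0 (proline excepted — its
ring closes only at the reference torsions, as in real chemistry, so
fixtures keep proline at the reference pucker).  Branch-atom handedness
(e.g. which of CG1/CG2 is placed at +122°) follows the shipped table; Cα
chirality is validated against the community backbone→CB reconstruction
formula.

Metrics: bond lengths/angles over the canonical bond topology plus
peptide C–N bonds (chain-break cutoff 2.5 Å); χ₁–χ₄ over the standard
quadruples, with 180°-symmetric terminal dihedrals (ASP χ₂, GLU χ₃, PHE
χ₂, TYR χ₂) reported in [−90°, 90°); φ/ψ with termini and breaks absent;
chirality by the sign of the improper dihedral (N, CA, C, CB) — negative
(ideal ≈ −122.7°) is L, positive is D, |improper| < 5° is undetermined.
Bond-length RMSE is computed per structure (pooling across structures is
a caller-side mean).  No relaxation is applied before measuring.  All
metrics are invariant under proper rigid motions; reflection flips
chirality.

**What fixtures do not show.**  They have exact covalent geometry but no
notion of sterics, packing, hydrogen bonding or secondary-structure
realism beyond the requested torsions; passing the suite demonstrates the
correctness of the sampling/bookkeeping/measurement machinery, not sample
quality of any trained model on real proteins.  Oracles likewise bound
what the degradation testbed shows: the random-sequence run degrades
chemistry *relative to* the oracle run under identical seeds, a
qualitative, not quantitative, reproduction of the failure mode.

## Numerical conventions

Torsions use the IUPAC sign convention, range (−180°, 180°]; collinear
reference triples are rejected (tolerance 1e-8 on the cross-product
norm).  Euler steps require `σ_last ≥ σ_next` per atom (tolerance 1e-12);
atoms at `σ_last = σ_next` are untouched, and stepping an atom from
`σ_last = 0` is rejected (no score is defined there).  Coordinates are Å
throughout; PDB files use chain `A`, 1-based residue numbering (0-based
internally), occupancy 1.00, and the B-factor column carries the per-atom
σ (0.00 for finished samples).  Altloc resolution keeps the
highest-occupancy conformer.  All randomness flows through
`numpy.random.Generator` seeded from the config, and runs are reproducible
bit-for-bit from (config, seed).

## Known limitations

* The neural denoiser and sequence predictor are contracts only; no
  trained weights ship with the package, so sample-quality statistics of
  trained models (self-consistency rates, diversity, novelty) are out of
  scope.
* Single chains, canonical residues, heavy atoms only; no OXT, hydrogens,
  ligands, modified residues or mmCIF.
* The ideal-geometry table is a self-consistent standard-values dataset,
  not a fit to any structural database; absolute RMSE values on real PDB
  files reflect both real deviation and table choice.
* Whether churn noise should also enter unselected superposition slots,
  and what exactly self-conditioning should carry, are left as hooks
  (defaults: frozen slots; previous denoised estimate).
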