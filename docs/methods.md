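# Model and methods

This note records the models implemented in `diffmd`, the defaults and the
reasoning behind choices the design left open. Everything quantitative
here is computed by the test suite or `scripts/acceptance.py`; nothing is
quoted from elsewhere.

## Potential energy

Units throughout: nm, ps, kJ/mol, elementary charge, Kelvin, amu; angles
in radians internally.

**Bonded.** Harmonic bonds `k (r − r₀)²` and angles `k (θ − θ₀)²` (note
the convention without the ½; the XML export layer converts to the
`½ k x²` convention and back). Proper torsions use the periodic form
`k (1 + cos(nφ − δ))`. Amplitudes `k` of the 13 trainable torsion types
(33 terms in total) are part of the parameter vector; phases are frozen.
The 13 types are the backbone φ, ψ and their side-chain variants
(φ′ = C-N-CA-CB, ψ′ = CB-CA-C-N) as exact quadruples, plus wildcard
middle-bond types (ω around C-N, rotation around CA-CB, N-CA, CA-C,
N-terminal ammonium, serine hydroxyl, aromatic ring, and two aliphatic
side-chain bond types). A torsion matches the most specific type; exact
quadruples take precedence over wildcards, both orientations are tried;
unmatched torsions carry no energy.

**Non-bonded.** Lennard-Jones with Lorentz–Berthelot combining and
Coulomb (k_e = 138.935458 kJ mol⁻¹ nm e⁻²) run over all atom pairs except
1-2/1-3 exclusions, with no distance cutoff; 1-4 pairs are scaled by the
two trainable weights. Salt screening is *not* applied to the vacuum
Coulomb term — it lives in the solvation term, so the infinite-κ limit
removes only the solvent contribution.

**Generalized-Born solvation.** The polar term is

E = −½ k_e Σ_ij (1/ε_p − e^(−κ f_ij)/ε_w) q_i q_j / f_ij,
f_ij = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))),

over the full pair matrix including i = j (the Born self terms,
f_ii = R_i), with ε_p = 1, ε_w = 78.5 fixed and κ defaulting to
0.7 nm⁻¹ (≈100 mM salt at 300 K). Effective radii R_i come from
pairwise HCT descreening integrals with per-element screening factors
applied to offset-reduced intrinsic radii, followed by the OBC
rescaling R_i = 1/(1/ρ̃_i − tanh(αΨ − βΨ² + γΨ³)/ρ_i) with Ψ = ρ̃_i I_i
and per-element (α, β, γ). The six intrinsic-radius classes are
{H, H-on-N, C, N, O, carbonyl/carboxylate O}; hydroxyl oxygens take the
O class, types O and O2 the carbonyl class.

*Neck correction.* The reference GB model defines the neck integral by
per-radius-pair tables. Tables would go stale the moment the radii train,
so `diffmd` uses an analytic surrogate with the same role and the same
trainable handles: a rational bump (Mongan-style falloff
`0.3/(1 + δ² + 0.3 δ⁶)`, δ = (r − d₀)/0.1 nm) centred at
d₀ = ρ_i + ρ_j + probe — where the solvent probe just bridges the two
spheres — multiplied by the trainable neck scale and windowed by a
logistic (width 0.01 nm) at the trainable neck cutoff. The smooth window
keeps a nonzero gradient for the cutoff parameter. Consequences: the neck
contribution is a peaked function of separation, so Born radii are
monotone under burial only with the neck disabled (true of any neck-type
correction), and absolute radii differ from tabulated implementations at
the few-percent level.

**Surface area.** ACE-style nonpolar term
`factor · Σ_i 4π(ρ_i + probe)² (ρ̃_i/R_i)⁶` using the *effective* radii
in the burial ratio. Whether the reference models use intrinsic or
effective radii here differs between implementations; the term is
isolated in one function so the alternative is a one-line change.

## Charges

Partial charges are stored per residue template (the same atom type can
carry different base charges in different residues). Training never
touches them directly: a per-type scaling s_t is learned, and after
scaling, the residue's excess charge Δ = Σ q′ − formal charge is removed
in proportion to |q′|, so every residue keeps its formal charge to
round-off for any positive scalings. All-zero scaled charges with a
nonzero formal charge are rejected as degenerate.

Embedded template charges (ALA, GLY, SER, charged terminal variants,
ACE/NME caps) are Amber-family values verified to sum exactly to the
formal charge; bond/angle constants are Amber-like defaults. The
registry ships as a versioned JSON data file.

## Dynamics and gradients

**Integrator.** BAOAB splitting of Langevin dynamics; with γ = 0 and the
noise disabled it reduces exactly to velocity Verlet (asserted in a
test). Defaults mirror the training protocol: 1 fs timestep (bonds are
not constrained), 300 K, γ = 0.1 ps⁻¹, energy minimisation (steepest
descent with backtracking line search, force tolerance 10 kJ/mol/nm) but
no equilibration before production. Noise is counter-based
(Philox keyed on (seed, step)), so any trajectory segment can be replayed
bit-exactly from a stored state without storing random numbers.

**Reverse pass.** The loss depends on the trajectory only through the
running sums ΣX and ΣX² of the Cα pair distances recorded every
`record_interval` steps, so the reverse pass seeds each recorded frame
with dL/dΣX + 2X·dL/dΣX² and propagates coordinate/velocity adjoints
backwards step by step. Memory is bounded by checkpointing: states are
saved every 100 steps; each block is replayed from its checkpoint and
differentiated in 10-step taped sub-chunks (an implementation detail
that changes nothing mathematically — verified by the
checkpointed-vs-whole-graph test at 1e-10 relative). At each block
boundary the coordinate and velocity adjoint blocks are independently
rescaled to norm 0.1 when either exceeds it ("either norm" read as
per-block; configurable). Gradients do not flow through the energy
minimisation into the starting structure.

**Forces.** Forces are hand-derived per term and assembled from the same
taped primitives as the energies, so the whole step remains
differentiable with respect to coordinates and parameters while keeping
the per-step expression graph small. The analytic force is asserted to
match the gradient of the energy to machine precision, and mixed second
derivatives (∂²E/∂x∂θ — what the trajectory adjoint actually consumes)
are checked against finite differences of the force.

**Precision.** Double precision by default; a single-precision mode
exists and is used for the larger gradient-reproducibility runs, where it
halves memory and time without a noticeable change in the gradients.

## Loss

Per unordered residue pair (i < j): means and standard deviations of the
Cα distance from the recorded sums (σ floored at 1e-3 nm so rigid pairs
stay finite; the floor also guards the square root's derivative at zero
variance), two-way closed-form Gaussian KL, log-compression
ln(D + 1) of each direction, separation weight min(|i−j|, 10)/10, and
the mean over all pairs. The mean's denominator includes zero-weight
pairs by default (`include_zero_weight=False` excludes them; for chains
of more than one residue every i < j pair has positive weight, so the
choice only matters for the degenerate |i−j| = 0 diagonal, which is
never enumerated).

## Training loop

Per epoch and protein: minimise, simulate (twice with different seeds for
IDPs; repeats averaged elementwise), compute loss and gradient, divide by
the median absolute gradient entry (all 108 entries; an all-zero gradient
skips normalisation with a warning), damp LJ σ and hydrogen-type entries
×0.02, then update with learning rate 4e-4 under a 0.5% per-protein and
3% per-epoch cap on each parameter's change relative to its epoch-start
magnitude (a zero-valued parameter — none among the defaults — would use
an absolute fallback cap of 0.005). Ordering (median → class weight →
cap) follows the narrative order of the training recipe. Multiple runs
are compared by final-epoch mean training loss; ties break to the lowest
run index.

## Synthetic data

The generator builds idealised Ala/Gly chains from internal coordinates
(NeRF construction; extended φ=ψ=180° or helical φ=−57°, ψ=−47°; ideal
bond lengths/angles; charged N/C termini), a single tethered particle
with E = ½k|x|² (Gibbs variance kT/k per axis — the analytic target for
integrator validation), and rigid multi-copy fixtures for the
contact/oligomer operators. Reference distance statistics are produced
by the engine itself running a *stated* parameter vector — this keeps
the structure of the training problem (match another Hamiltonian's
distance distributions) while staying desk-scale. What passing tests do
**not** show: agreement with explicit-solvent water structure, real
protein sequences/sidechains beyond Ala/Gly/Ser, or μs-scale
conformational ensembles.

## Problem sizes and stochastic bounds

Desk-scale sizes used by the tests and the acceptance script, chosen so
the full suite runs on one CPU: toy chains of 2–15 residues;
gradient-vs-finite-difference checks on a two-residue glycine system over
200 steps; checkpointing exactness over 500 steps; integrator sampling
with a tethered particle over 1e6 steps (γ = 10 ps⁻¹ so the pooled
Monte-Carlo error ≈1.6% makes the 5% band ≈3σ); gradient-reproducibility
pairs at 15 residues/20 ps (20 ps of 1 fs steps, recording every 50 fs) —
the suite and the acceptance script share this experiment, because
shorter runs measurably degrade both the sign agreement and the
correlation of paired stochastic gradients. The
reference vector for reproducibility runs is the default perturbed by
±3% multiplicative Gaussian noise — the scale of parameter movement that
force-field training of this kind actually produces. Gradient sign
agreement between paired runs is evaluated over parameters whose
gradients are nonzero in both runs and at least 1e-3 of the largest
magnitude; the Pearson correlation uses all 108 entries.

Run length matters for the reproducibility measures: halving the peptide
and the simulation time measurably lowers both the sign agreement and
the correlation of paired gradients, because each short run's
conformational transient from the ideal starting helix contributes its
own bias to the torsion-amplitude gradients. The closed-loop
self-consistency check (training statistics compared against
same-parameter references) carries a pure finite-sampling KL residual of
order 0.05–0.25 at 10 ps for a 5-residue toy; the test bounds it at the
measured sampling floor rather than at zero.

## Known limitations

* The neck surrogate reproduces the role, not the tabulated values, of
  the reference neck correction.
* Only the 16 in-scope atom types and Ala/Gly/Ser (+caps, charged
  termini) templates are embedded; other residues raise a clear error.
* No periodic electrostatics, constraints, virtual sites or explicit
  solvent; the optional box applies only to the analysis operators'
  minimum-image distances.
* The HCT integral has derivative kinks at its branch boundaries
  (`L = max(|r−s|, ρ̃)`); energies are continuous but
  finite-difference checks of trajectory gradients can disagree with the
  exact one-sided derivative for parameters whose gradients are tiny.
* Hydrogens missing from input PDBs are placed with idealised geometry,
  not by template internal coordinates.
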