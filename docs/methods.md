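# Methods

This note documents the models and procedures implemented in `cgforge`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## CG resolution, typing and force mapping

Each residue is represented by five beads — backbone N, CA, C, O plus the
side-chain CB — and glycine by four (no CB). Within a residue beads are
ordered N, CA, CB, C, O; this order is a package convention chosen to make
array layouts deterministic. Exactly one bead per residue carries a
residue-dependent integer type: the CB bead, or the CA bead for glycine.
The remaining beads carry one of four generic backbone types. The full
vocabulary is 24 ids: N=0, CA=1, C=2, O=3, then the 20 residue types 4–23
assigned alphabetically by one-letter code (A=4, C=5, …, Y=23). Because
amino-acid identity lives in a single bead type, a point mutation is a
retyping operation.

The force-aggregation operator `M_F` assigns to each bead the force on its
preserved heavy atom plus the forces on hydrogens attached to it through
constrained bonds. When a topology is read from a plain PDB, every X–H
covalent bond (connectivity from standard residue templates) is treated as
constrained, which matches the constrained-hydrogen dynamics of the
source all-atom force fields. `M_F` is linear and conserves the total
force over the aggregated atoms; both properties are asserted in tests to
machine precision.

Terminal residues receive no special beads or types, and protonation
variants (HID/HIE/HIP, CYX, …) collapse onto their parent residue type.

## Units

Internal units are nm, kJ/mol, ps and K throughout; `k_B` =
0.008314462… kJ/(mol K). Angstrom and kcal/mol appear only at I/O
boundaries: PDB coordinates, the 0.5 Å decoy noise convention, and ddG
values reported in kcal/mol.

## Prior energy

The prior is a fixed, pre-fit term whose only job is to keep simulations
out of unphysical configurations; it has no attractive nonbonded
interactions and cannot stabilize secondary or tertiary structure on its
own (asserted by a prior-only simulation test). Functional forms:

* bonds and angles: harmonic, `U = k/2 (x − x0)²`;
* dihedrals: cosine series `U = Σ_n c_n cos(nφ − δ_n)`, n = 1…3;
* nonbonded repulsion: `U = ε[(σ/r)^p − 1 + p(r/σ − 1)]` for r < σ, zero
  beyond, with p = 6 by default. This truncated power law is strictly
  decreasing on (0, σ) and C¹ at the cutoff, so forces are continuous —
  a plain `ε(σ/r)^p` truncated at σ would leave a force discontinuity of
  εp/σ at the boundary.

Pairs separated by ≤ 2 bonds are excluded from repulsion; those distances
are governed by the bond and angle terms.

Fitting is moment matching against CG marginals at the data temperature:
harmonic stiffness `k = k_B T / var`, equilibrium = mean; dihedral
coefficients by linear least squares of `−k_B T log(histogram)` (64 bins,
pseudo-count 1) on the cos/sin basis; the repulsion radius σ from the 2%
quantile of the nonbonded pair-distance marginal with ε = k_B T. A term
key with fewer than 20 samples falls back to the pooled type-generic fit,
with a logged warning. Repulsion distances are clamped at 10⁻³ nm with a
warning counter so pathological inputs cannot produce infinite forces.

**Caveat that shaped the design**: each marginal is inverted as if
independent. A term class fitted on strongly correlated data absorbs that
correlation as a systematic bias — e.g. torsion marginals shaped by
nonbonded attractions yield a dihedral prior that tilts the whole
landscape, and a distance-featurized network cannot fully cancel a 4-body
bias. `fit_priors` therefore takes a `term_classes` argument so the prior
can be restricted to the classes it should represent; the end-to-end
recovery study (below) fits bonds, angles and repulsion, matching the
term classes of its generator. CG models are known to be sensitive to
prior choices, and this is the package's controlled way of exercising
that sensitivity.

## Trainable energy

The many-body energy is a continuous-filter graph network in the
SchNet/CGSchNet family: learned per-type embeddings, Gaussian radial
basis expansion of pair distances on [0, cutoff], a filter-generating
dense network, two continuous-filter convolution blocks with residual
updates, and a per-bead energy head summed into the scalar energy. A
cosine switching envelope multiplies every filter, making the energy
continuous (to 10⁻⁸ in tests) as pairs cross the cutoff, so conservative
forces exist everywhere: `F = −∇_R U` by reverse-mode differentiation of
the same computation that produces U. There is no attention and no
explicit long-range term; interactions are strictly local within the
cutoff.

Defaults (configuration, not constants): embedding 64, 2 interaction
blocks, 32 radial basis functions, cutoff 1.2 nm. The desk-scale recovery
study uses a smaller instance (48/2/20, cutoff 1.0 nm).

Because no deep-learning framework is assumed, the package carries a
small reverse-mode autodiff core (`cgforge.autodiff`) whose
vector-Jacobian products are themselves built from primitive operations,
so the gradient graph can be differentiated again — the force-matching
loss needs exactly this: its parameter gradient is a mixed second
derivative through the force computation. First and second derivatives
are verified against central finite differences (10⁻⁹–10⁻¹⁰ relative).
A hand-written forward/backward pass (`energy_forces_fast`) serves the
simulation hot loop, where only dE/dR is needed; it is asserted to agree
with the autodiff route to ~10⁻¹⁴, giving a dual-route check on both.

Neighbour lists are brute-force all-pairs up to 200 beads and a cell list
above; the two are tested for exact agreement.

## Training

Labels are delta forces: mapped atomistic forces minus prior forces, so
the network learns only the correction on top of the prior. Decoy frames
take every 50th frame and displace every coordinate by i.i.d. Gaussian
noise of sd 0.5 Å, with identically zero delta-force labels; they teach
the network to predict no correction in distorted regions where the prior
should dominate, and are mixed into batches at their natural proportion
with no special weight.

The loss is the mean over frames of `(1/3N) Σ_j ‖label_j − F_net,j‖²`,
with N taken per frame so mixed-size batching generalizes the
single-system formula. A per-frame loop oracle and the batched
implementation agree to 10⁻¹⁰ relative (asserted).

Optimization: Adam with cosine learning-rate decay (floor 5% of the peak),
gradient-norm clipping at 10, early stopping on validation loss.
Train/validation splits are contiguous trajectory blocks, not random
frames, to limit autocorrelation leakage; the checkpoint with the lowest
validation loss is returned, and a non-finite loss aborts with the last
finite checkpoint. Any dataset tag can be excluded by configuration
(the ablation hook).

## Sampling

Langevin dynamics uses the BAOAB splitting, which gives accurate
configurational averages at moderate time steps. Defaults: timestep
0.002 ps, friction 1/ps, unit masses. CG dynamics are not physical
dynamics — only sampled thermodynamics is meaningful — so masses and
friction are sampling knobs; tests that need tight statistics use
near-critical friction for faster decorrelation. Runs are bitwise
reproducible per seed; non-finite energies abort with the last valid
frame and step index.

Parallel tempering runs one replica per ladder temperature (geometric
spacing by default), swaps *configurations* between neighbours on
alternating even/odd sweeps with the Metropolis rule
`min{1, exp[(β_i−β_j)(U_i−U_j)]}`, rescales velocities by √(T_new/T_old),
and records attempted/accepted counts per pair. At save time every frame's
reduced energy is evaluated at every ladder temperature, giving the
(frames × temperatures) matrix MBAR consumes.

## Analysis

* **RMSD**: optimal rigid-body superposition (Kabsch, SVD with proper
  rotation), per frame.
* **RMSF**: frames aligned to the running mean structure, iterated to
  convergence; per-site root-mean-square displacement from the converged
  mean. With few sites the 6 absorbed rigid-body dofs bias RMSF low;
  tests use enough sites to make this negligible.
* **Q (fraction of native contacts)**: soft switch
  `1/(1 + exp[β(r − λ r⁰)])` averaged over native pairs, β = 50 nm⁻¹.
  Native pairs are CB (CA for glycine) bead pairs within 0.8 nm in the
  native structure at sequence separation ≥ 3. The tolerance factor is
  λ = 1.5: native CG bead contacts sit at 0.5–0.8 nm, and the atomistic
  convention λ = 1.8 would place the switching threshold at 0.9–1.4 nm,
  counting most coil configurations as contacts. This is a convention
  adapted to the bead resolution, not a literature fact.
* **TICA**: symmetrized time-lagged covariance estimators and the
  generalized eigenproblem `C_τ v = λ C_0 v`; symmetrization keeps
  |λ| ≤ 1. Singular C_0 is ridge-regularized with a warning.
* **MBAR**: the self-consistent free-energy iteration in log space
  (logsumexp), converged to 10⁻⁸ in the state free energies;
  per-frame weights at any target temperature follow from the converged
  normalizers. With a single state the weights reduce to 1/n exactly.
* **Free-energy surfaces**: weighted histograms, `F = −log(mass/max)` in
  k_B T, minimum at 0, empty bins +inf (never plotted as 0); CSV export.

## Mutations and ddG

`mutate_topology` retypes the CB bead (non-GLY ↔ non-GLY), or rebuilds
the topology from the mutated sequence for GLY cases (CB removed or
added). The stability change is one-sided exponential averaging
(Zwanzig) in each state:

    dG_state = −k_B T ln ⟨exp(−β ΔU)⟩_state ,  ddG = dG_folded − dG_unfolded

computed stably via logsumexp, reported in kcal/mol, with the sign
convention that positive ddG destabilizes the fold. The estimator lives
in one function (`ddg_from_energy_diffs`) so an alternative (e.g. BAR)
can be swapped in. Errors are bootstrap: 99 resamples of batches of
10,000 frames per state, drawn with replacement. The effective sample
size `(Σw)²/Σw²` of each exponential average is reported, and results
with ESS < 100 are flagged unreliable. Frames are assigned folded at
Q ≥ 0.6 and unfolded at Q ≤ 0.2 by default (configurable); GLY-involving
mutations are rejected on the perturbative path because reweighting has
no coordinates for a created or removed bead.

## Synthetic systems

The generators produce equilibrium "atomistic" frames with exactly known
forces, so every pipeline stage can be checked against ground truth:

* Bead positions are sampled from a differentiable ground-truth potential
  (harmonic bonds/angles, Gaussian pair wells, the same C¹ repulsion as
  the prior, optional quartic pair double wells) by long-stride BAOAB
  runs over several independent walkers.
* Each bead carries harmonically tethered satellite atoms flagged as
  constrained hydrogens (stiffness 4×10⁴ kJ/mol/nm², far above backbone
  stiffness — enforced timescale separation). Satellites are drawn from
  their exact conditional Boltzmann distribution, and stored forces are
  the exact negative gradient of (ground truth + tethers). Aggregation
  through `M_F` then cancels the tether reactions exactly, which is the
  property that makes the mapping nontrivial to test.
* The standard training chain has stiff bonds (k = 4000 kJ/mol/nm², so
  thermal bond fluctuations stay well below the 0.5 Å decoy noise, as in
  real proteins), one attractive end-to-end Gaussian well, and distinct
  per-bead types — a type-blind network could not represent an
  end-specific interaction from distances alone.
* A 12-bead two-state foldamer couples helix-like (i, i+3)+ contact wells
  (depth 3 kJ/mol) to local angle terms that prefer *extended* geometry,
  so the fold is carried entirely by the nonlocal wells and a prior
  fitted on local statistics cannot hold it.
* An isolated bead pair with a quartic double well has the exactly known
  radial free energy `F(d) = U(d) − 2 k_B T ln d`, the quadrature oracle
  for sampler and reweighting checks.
* Umbrella windows bias the centre-of-mass distance of two bead clusters
  and store *unbiased* ground-truth forces with per-window (centre,
  stiffness) metadata — close-approach repulsive configurations that
  equilibrium sampling would rarely visit.

What the generators do not emulate: explicit solvent (forces are exact
gradients, with none of the orthogonal solvent noise that makes real
force matching a variational rather than regression problem), system-size
diversity, and sequence diversity. Passing tests therefore demonstrate
the machinery — mapping, labelling, optimization, sampling, reweighting —
not transferability to real proteins.

## End-to-end recovery study

`cgforge.endtoend.run_recovery_study` is the master consistency check:
generate the standard 6-bead chain (4,000 frames at 300 K plus 2,000 at
450 K for configurational coverage — the same role the umbrella and decoy
sets play for the real model), map, fit the prior (bonds, angles,
repulsion), build delta labels and decoys, train a 48-dim 2-block network
for 50 epochs, then compare (a) held-out forces of prior+network against
the exact ground-truth forces on an independent trajectory and (b) the
simulated free-energy profile along the end-to-end distance against the
same profile sampled from the ground truth (64 walkers × 8,000 BAOAB
steps each; bins with ≥ 100 samples on both sides; profiles compared
after removing the mean offset, since each is referenced to its own
minimum). Typical results: force RMSE 2–7% of the force standard
deviation, free-energy deviation 0.15–0.3 k_B T. Force labels are exact
functions of configuration here, so broader sampling (the hot frames)
sharpens the fit without any reweighting.

Problem sizes throughout the tests and the acceptance script are chosen
at desk scale — single-CPU minutes, not GPU-days; they are stated above
and in the docstrings.

## Known limitations

* The published model's hyperparameters, prior parameterization, training
  schedule and PT ladders are not public in the main text; defaults here
  are documented stand-ins, and results with them are not expected to
  reproduce published protein-level numbers.
* The network featurization is pairwise distances only; systematic
  many-body biases (e.g. a mis-fit torsional prior) cannot be fully
  corrected by it, as the recovery study demonstrates.
* Electrostatics and long-range interactions are absent by design.
* The perturbative ddG path requires wild-type/mutant phase-space
  overlap; the ESS flag is a guard, not a cure, and GLY-involving
  mutations need a bead-placement rule that is deliberately not provided.
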