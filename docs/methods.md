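# Methods

`spisim` simulates, at desk scale, what happens to a single biomolecule in
the femtoseconds it spends inside an intense focused X-ray pulse, and how
that damage degrades the diffraction pattern the experiment ultimately
measures.  The pipeline has three stages — stochastic ionization dynamics
coupled to Coulomb-only molecular dynamics, formation of reciprocal-space
diffraction volumes from the damage snapshots, and ensemble statistics over
many stochastic realizations — mirroring the structure of production
start-to-end single-particle-imaging simulation frameworks, but sized so a
full ensemble study runs in minutes on one CPU core.

## Irradiation model

The nominal pulse is 4.96 keV photon energy, 5×10¹¹ photons, 9 fs FWHM
duration, focused to 250 nm × 160 nm FWHM.  Because the molecule is three
orders of magnitude smaller than the focus, the fluence is uniform over the
sample; the on-axis fluence rate is flux(t)/(2π σx σy), which integrates to
≈1.1×10⁵ photons/Å² for the nominal parameters.  Two temporal profiles are
provided: a smooth Gaussian envelope, and a SASE-like spiky profile built
by modulating the envelope with the squared magnitude of a complex Gaussian
random field whose coherence time (default 0.25 fs, the ~coherence time of
a SASE beam in this photon-energy range) sets the spike width.  The spiky
profiles are statistical emulations — only their envelope and normalization
matter to the analysis, and their seed-ensemble average converges to the
smooth envelope (tested).

## Atomic data

Per-element electronic data live in a compact embedded table: shell
structure and occupations, per-shell binding energies (standard X-ray data
compilations, state-independent approximation), per-shell photoionization
cross sections tabulated at the 4.96 keV working energy with an (E₀/E)³
extrapolation and hard edge cutoffs, and K-hole Auger rates from core-hole
level widths (Γ = ħ/τ; e.g. τ ≈ 6.7 fs for carbon).  Supported elements:
H, C, N, O, Mg, P, S, Zn.  Fluorescence is neglected (K-fluorescence yield
for second-row elements is below 1%), so every K hole decays by Auger
emission with energy B(1s) − 2·B(valence).

Elastic form factors use the International-Tables four-Gaussian
parameterization shipped with `gemmi`, with the constant term renormalized
so that f(0) equals the electron count exactly.  An ion's form factor is
the neutral curve scaled by n_bound/Z — exact at q = 0, approximate in
shape at high q; the configuration-resolved factors a first-principles
atomic code would give are out of scope, and the choice is isolated behind
one function.  The incoherent (Compton) scattering function uses the
closed form S(q) = n_bound·(1 − (f(q)/Z)²), which has the correct limits
S(0) = 0 and S(∞) = n_bound.

Electron-impact ionization uses the binary-encounter-Bethe closed form per
shell, with the orbital kinetic energy approximated by the binding energy.
It is threshold-correct (σ = 0 at and below B) and accurate to a few tens
of percent for the sub-keV electrons that dominate secondary ionization —
adequate here, since no printed cross-section model exists to reproduce.

## Damage dynamics

Each *realization* is one stochastic history of the irradiated molecule:

1. **Photoionization** — per atom and shell, an event fires with
   P = 1 − exp(−σ Φ Δt); the occupation is decremented and an electron is
   born at a 0.3 Å random offset with KE = E_photon − B, isotropic.
2. **Auger decay** — per K hole, P = 1 − exp(−Γ Δt); one valence electron
   fills the hole, a second leaves with the element's mean Auger energy.
3. **Collisional ionization** — free electrons sweep their straight-line
   path each step; neighbour atoms (k-d tree query) are ionized when the
   path passes within the total BEB impact parameter b = √(σ_tot/π), the
   shell being sampled ∝ σ_shell.  The incident electron pays the binding
   energy; the secondary is born at rest at the atom.  Using the *total*
   cross-section disc (rather than concentric per-shell discs) is what
   makes the simulated event rate equal n σ_tot v Δt in a uniform gas,
   which the tests verify against kinetic theory.

These processes are operator-split on a 0.01 fs macro step, interleaved
with molecular dynamics.  Only Coulomb forces act (bond breaking is fast at
these ionization levels); neutral atoms neither feel nor exert forces.

**Fast-electron transport.**  A 4.7 keV photoelectron moves at ~400 Å/fs
and leaves a ≤100 Å sample in attoseconds — far below any affordable MD
step.  Electrons born above a threshold (default 200 eV) are therefore
transported ballistically in one pass: a straight exit path with the same
impact-parameter collision sampling (each collision costs the binding
energy and spawns a secondary at rest), then an escape test against the
monopole Coulomb barrier of the instantaneous net cluster charge.  An
electron that falls below the threshold mid-path is handed to the MD at
that point.  Only slow/trapped electrons are explicit MD particles, which
is also where the interesting plasma physics (central trapping, screening)
happens.

**Integration.**  Velocity-Verlet with a step chosen per macro step from
two bounds — displacement (c·s/v per particle) and free-fall
(c·√(s·m/F), which catches electrons starting at rest beside an ion) with
c = 0.25 — and held constant within the macro step to retain near-symplectic
behaviour.  Softening is per-species: 0.1 Å for ion–ion pairs (far below
the 1.5 Å minimum interatomic distance, so ion dynamics is effectively
exact) and 1.0 Å for any pair involving a classical electron.  The larger
electron softening is the standard classical stand-in for the spatial
extent of a bound orbital: it prevents unphysical deep classical capture,
keeps the integrator's energy drift at the 10⁻³ level over a full pulse,
and makes desk-scale ensembles affordable.  A particle exceeding c/10
aborts the run with a diagnostic (never observed under nominal conditions).

**Escape ledger.**  An electron farther than 3× the molecule radius from
the centre of mass with positive total energy is moved to an escaped-charge
ledger and removed from the force sums.  Charge conservation —
Σ(atomic charges) = explicit + escaped electrons — holds exactly at every
step and is asserted at the end of every realization.

**Force solvers.**  The production path uses an O(n²) direct sum (numba)
below 3000 charged particles and a serial Barnes–Hut octree above.  The
tree stores, per node, separate positive and negative monopoles at their
charge centroids plus traceless quadrupoles, so the expansion is
dipole-free for arbitrarily sign-mixed cells; at opening angle 0.3 the
maximum force error against the direct sum is ~3×10⁻³ on 10³ mixed
charges, and the measured cost on 10²–10⁴ particles fits n·log n far
better than n².  The direct sum doubles as the oracle in the tests.

## Diffraction

Intensities are computed on an oversampled cubic q-grid (spacing
Δq = 2π/(s·D) with oversampling s and molecule extent D; edge at
q = 2π/d_edge; production values s = 2.8, d_edge = 3.5 Å) in Thomson
units:

    I(q) = |Σ_j f_j(q) e^{iq·r_j}|² + Σ_j S_j(q) + N_free

with damage-modified f_j per atom's current ion state, the incoherent
background S_j, and one flat Thomson unit per free electron inside the
sampling box (free electrons scatter incoherently; coherent inter-electron
terms are omitted).  The undamaged reference keeps only the coherent term
with neutral atoms.  Structure factors are evaluated with a separable
phase-factor kernel grouped by (element, charge state), making a 47³ grid
with 500 atoms cost well under a second per snapshot.

Ten snapshots per realization sit at the median-photon times of ten
equal-photon-content intervals of the pulse; time integration weights each
snapshot image by its interval's photon count and divides by the total
photon count.  Equal-photon (rather than equal-time) placement weights
damage states by their contribution to the detector signal; equal-time
spacing is also implemented and tested against the Gaussian closed form.

Damage dynamics runs on the randomly rotated molecule, but snapshots are
rotated back to the common molecular frame before imaging so that all
realization volumes share one grid; orientation matters only through the
damage itself, which the rank test below shows to be negligible.
A flat-Ewald-free detector projection (distance, pitch, Ewald-sphere
mapping, Thomson prefactor, solid angle, polarization factor, Poisson
sampling) is provided for 2-D pattern synthesis but the statistical
analysis operates on reciprocal-space volumes.

## Ensemble statistics

- Per-species mean bound electrons and mean lab-frame displacement
  |r(t) − r(start)| vs snapshot time (no centre-of-mass removal: the
  exploding system has near-zero net momentum, so the difference is
  negligible).
- Radial profiles of both quantities at the snapshot nearest time zero,
  binned by initial distance from the centre of mass.
- Per-voxel ensemble mean, sample SD (n−1) and relative SD σ_px/I_px of
  the time-integrated volumes; relative SDs averaged on equal-width
  constant-|q| shells (zero-mean voxels flagged and excluded).
- Amplitude R-factor per resolution bin,
  R = Σ|√I_damaged − √I_ideal| / Σ√I_ideal over voxels with bins labelled
  by d = 2π/q, plus a cumulative variant; the amplitude (rather than
  intensity) form is the crystallographic convention.
- Subset convergence: the relative SD of the N-realization mean image vs
  N from random resampling, with the per-realization plateau divided by
  √N as the central-limit reference.  With the plateau near 0.2, a
  25-realization mean is accurate to ≈4%.
- Orientation independence: a Kruskal–Wallis rank test of total final
  ionization across orientation groups, with type-I calibration verified
  on synthetic null ensembles.

## Synthetic study system

The deposited production structure (a ~240,000-atom ribonucleoprotein
assembly) is too large for desk-scale ensembles, so the generator builds
random clusters with biomolecule-like composition (H 0.41 / C 0.27 /
N 0.10 / O 0.20 / P 0.02), ≥1.5 Å minimum separation, and ~0.1 atoms/Å³
number density.  The standard study system is 500 atoms (radius ≈ 10.6 Å)
under the nominal pulse, 25 realizations across 5 orientations — sized so
the full ensemble plus volumes runs in roughly ten minutes on one core.
The generator reproduces geometry and stoichiometry statistics only: no
secondary structure, no hydration shell, no realistic bonding.  Passing
trend tests on these clusters therefore demonstrates that the machinery
reproduces the *qualitative* damage phenomenology (monotone charging,
edge-reduced ionization, R-factor growth toward finer resolution,
orientation independence) — not the printed numbers for the full-size
assembly, which sit far outside desk-scale compute.  Scale-dependent
quantities (absolute charge states, displacement magnitudes, plateau
levels) differ from a 10⁶× larger system and are reported as cluster-scale
values.

Tiny exact fixtures (single atom, 10 Å pair, 3×3×3 cubic lattice) pin the
diffraction identities in closed form, and iid lognormal volume ensembles
with configured relative SD drive the estimator and convergence tests.

## Numerical choices and limitations

- Units: Å, fs, eV; Coulomb constant 14.3996 eV·Å; electron mass
  0.056856 eV·fs²/Å².
- Deterministic per seed: one `numpy` Generator per realization drives
  every stochastic draw in creation order.
- Electron birth offset 0.3 Å; secondary electrons born at rest (simplest
  energy bookkeeping; differential cross sections out of scope).
- The escape barrier uses the monopole approximation of the cluster
  potential; the full potential is used for explicit-electron escape.
- Auger eligibility requires ≥2 electrons outside the K shell; double-K
  holes decay at twice the single-hole rate.
- Known limitations: no recombination, no three-body capture, no quantum
  effects for slow electrons, hydrogenic energy scaling of photo cross
  sections between tabulated edges, single mean Auger energy per element.
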