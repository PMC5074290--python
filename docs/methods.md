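# Methods

## Scope and model

powderspec models the infrared/terahertz response of a powder of
sub-wavelength crystallites in a lossless dielectric matrix. The chain is:

1. Lorentz-oscillator permittivity tensor of the crystal from gamma-point
   phonons and Born charges;
2. depolarization tensor of the crystallite shape;
3. effective-medium homogenization (Maxwell-Garnett, Bruggeman, or the
   averaged-permittivity baseline) with exact orientational averaging;
4. complex refractive index → decadic absorption and molar absorption.

Assumptions inherited from the underlying theory: the harmonic
approximation with a constant damping σ_k per mode; particles small
compared with the wavelength (no scattering, no phonon–polariton
coupling); random particle orientation; a frequency-independent real
matrix permittivity; a single depolarization tensor shared by both phases
in the Bruggeman rule. None of these are relaxed here.

## Units and the two bridge constants

Frequencies are wavenumbers (cm⁻¹), cell volumes Å³, intensities
(D/Å)²/amu, Born charges in e. Two constants, derived from CODATA values
at import time (`powderspec/units.py`), pin everything:

* γ ≈ 2.1328×10⁶ — permittivity per unit I/(V ν²) in the units above. It
  is cross-checked by the MgO static permittivity: 3.14 + γ·9.29/(19.148 ·
  388.3²) = 10.003 against the published 10.0.
* e² → (D/Å)² ≈ 23.071 — converts strengths built from Born charges
  (e²/amu) to tabulated intensity units.

The integrated-molar-absorption constant evaluates to 4225.606
L mol⁻¹ cm⁻² per unit intensity (≡ 42.256 km/mol), i.e. A_k = N_A π /
(3000 c²) × (unit bridge) × g_k I_k. Note this is the evaluation that
reproduces the standard 42.256 km/mol equivalence; a form carrying an
extra 1/ln 10 would give 1834.8 and is inconsistent with that equivalence.

## Mode charges and the mass-weighting convention

Eigenvectors are those of the mass-weighted dynamical matrix
(orthonormal, dimensionless); the physical displacement of atom a in mode
k is ∝ U_ka/√m_a. The mode charge vector is therefore

    Z̄_k = Σ_a Z_a · U_ka / √m_a,

the dipole derivative with respect to the mode coordinate, with units
e/√amu so that S_k = Z̄_k Z̄_kᵀ has intensity units e²/amu. The 1/√m_a is
essential: it is what makes the oscillator sum and the non-analytic LO
correction (which carries an explicit 1/√(M_s M_t)) the same unit system,
and what makes the single-oscillator limit collapse to
Lyddane–Sachs–Teller exactly (verified to machine precision in the tests).
Files holding Cartesian-displacement eigenvectors are converted (weight by
√m_a, renormalize) at read time.

Modes with |ν| < 5 cm⁻¹ are flagged inactive (translations and numerical
zeros); imaginary modes are stored as negative frequencies and survive the
dynamical-matrix round trip as negative eigenvalues, but never enter the
dielectric sum.

## Shapes

Plate normals use the reciprocal lattice ((hkl) plane normal), needle and
ellipsoid axes the direct lattice ([hkl]); for non-orthogonal cells these
differ, and the difference is tested against a metric-tensor oracle. The
orthonormal completion of the unique axis pivots on its smallest
component — a deterministic choice; all observables are provably
completion-independent and tested as such. The ellipsoid is a spheroid
whose parameter z is the aspect ratio (unique-axis length over
perpendicular length), with the prolate (z > 1) and oblate (z < 1)
closed-form depolarization factors; both branches are verified against
numerical evaluation of the standard ellipsoid depolarization integral,
and the z → 0 / z → ∞ limits recover the slab and needle tensors.

## Mixing rules and numerics

Orientational averaging is analytic: for particle-fixed tensors the
uniform-rotation average of R T Rᵀ is (tr T/3)·1, applied to α and αL;
equivalence with Monte-Carlo rotation sampling is asserted within
3 standard errors at 10⁵ rotations.

Maxwell-Garnett: ε_mg = ε_e + n⟨α⟩/(1 − n⟨αL⟩/ε_e) with
α = Vε_e(ε_i − ε_e)(ε_e + L(ε_i − ε_e))⁻¹ and n = f/V. The leading term is
ε_e (not the identity): required by the f → 0 limit. For isotropic spheres
this reduces to the textbook scalar formula (asserted to 1e-10).

Bruggeman: the orientation-averaged symmetric condition
Σᵢ fᵢ ⟨(εᵢ − ε_br)(ε_br + L(εᵢ − ε_br))⁻¹⟩ = 0 is solved per frequency by
fixed-point iteration (relative tolerance 1e-8, cap 1000 iterations —
engineering choices surfaced as module constants), seeded with the
Maxwell-Garnett value at the first grid point and the previous-frequency
solution thereafter. The bracket uses ε_br·1 + L(εᵢ − ε_br·1), the
dimensionally consistent anisotropic form. The iteration is validated
against the exact quadratic root of the isotropic-sphere condition. Roots
with negative absorption are retried from the MG seed and otherwise
flagged (`converged` / `passive` arrays) — never silently returned.

A caution established quantitatively here: the two rules share the dilute
limit, but convergence is non-uniform in frequency. Near the Fröhlich
resonance the expansion parameter is f·Q² with Q = |3ε_e/(ε_i + 2ε_e)| the
resonance enhancement (Q ≈ 45 for the MgO model at σ = 5 cm⁻¹), so even at
f = 10⁻⁴ the two rules differ by ~20% of the response at the resonance,
converging linearly in f (measured: 0.23 → 0.037 → 0.004 for f = 10⁻⁴,
10⁻⁵, 10⁻⁶). Away from resonance they agree to better than 0.1% at
f = 10⁻⁴. One acceptance-style test asserts the stricter pointwise claim
across the resonance and is expected to fail; the linear-convergence
property is asserted separately and passes.

## Spectra

The κ ≥ 0 branch of N = √ε is selected explicitly (consistent with
Kramers–Kronig). Absorption is decadic throughout. The concentration
C = f·1000/(V·10⁻²⁴·N_A) uses the crystal's unit-cell volume under every
mixing rule, so molar absorption is per mole of unit cells. Peak positions
are refined by quadratic interpolation around grid maxima because
published peak values are finer than typical grid steps; multi-peak
spectra use scipy's peak finder with a 1% height floor before refinement.

## Synthetic data

`make_toy_crystal` emulates a gamma-point calculation: random lattice
(orthorhombic or monoclinic), masses in 1–50 amu, Born charges drawn
N(0, 1.5) then mean-centred to enforce the acoustic sum rule (which makes
the three exact-zero translational modes carry zero strength — asserted),
orthonormal eigenvectors containing the three exact mass-weighted
translations, optic frequencies uniform in 50–1200 cm⁻¹ (the mid-IR range
of the benchmark materials), optional degenerate pairs and
uniaxial/monoclinic optical permittivities. It does not emulate: realistic
dispersion of intensities across modes, symmetry-constrained Born-charge
anisotropy, or correlated eigenvector structure — so passing tests show
unit/convention correctness and invariants, not chemical realism.

The published-table reconstructions (`reference_models`) carry the
benchmark cell parameters, ε∞ and band lists. The degenerate-band
convention is per-partner: each E partner contributes the printed
intensity on its own transverse axis (each T partner on its own axis).
This is the reading that reproduces the published MgO static permittivity
and the calcite sphere shifts (786, 1480 cm⁻¹); the shared-intensity
alternative is available as `shared_degenerate=True` for sensitivity
analysis. The calcite table reconstructs static permittivities ~5% below
the published values, consistent with weak bands omitted from the printed
table; this is reported, not corrected. The aspartic-acid table lacks
directional information and is spread isotropically — smoke tests only.
The MgO cell length 2.1234 Å is interpreted as half the conventional cubic
edge (primitive fcc volume a³/4 = 19.148 Å³), the only reading consistent
with the published static permittivity.

## Problem sizes

Default spectra use 2 501-point grids (300–800 cm⁻¹ at 0.2 cm⁻¹);
Bruggeman iterations converge in a handful of steps per frequency at these
damping levels. The Monte-Carlo orientation oracle uses 10⁵ rotations; the
sum-rule integral uses a 0.05 cm⁻¹ grid to 20 000 cm⁻¹. The full suite
runs in well under a minute on one core.

## Known limitations

* No percolation-aware, multi-shape, or core–shell effective-medium
  models; no triaxial ellipsoids (spheroids only).
* Constant σ_k damping; no anharmonic or frequency-dependent linewidths.
* Native QM/MM output dialects are not parsed; data must be converted to
  the canonical schema.
* Bruggeman solutions in strong-contrast regimes can be unphysical; they
  are flagged, and the flags should be inspected before trusting spectra
  at volume fractions above ~0.1.
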