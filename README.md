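# powderspec

Predicts the infrared and terahertz absorption of a powdered crystalline
material dispersed in a non-absorbing matrix (PTFE, KBr, Nujol,
polyethylene), starting from the output of a gamma-point lattice-dynamics
calculation: mode frequencies, mass-weighted eigenvectors, Born effective
charge tensors and the optical permittivity tensor.

It is aimed at people who compute phonons with solid-state QM/MM codes and
want to compare against measured pellet or mull spectra, where the particle
shape and the supporting medium shift and reshape the absorption bands —
often by more than 100 cm⁻¹ for ionic materials.

## The model

1. **Lorentz oscillators.** The crystal permittivity tensor is a sum over
   damped oscillators at the transverse-optic (TO) frequencies ν_k:

   ε(ν) = ε∞ + (γ/V) Σ_k S_k / (ν_k² − ν² − iσ_k ν)

   with oscillator-strength tensors S_k = Z̄_k Z̄_kᵀ built from the mode
   charge vectors Z̄_k = Σ_a Z_a U_ka/√m_a (Born charges Z_a, mass-weighted
   eigenvectors U). The unit bridge γ is derived from CODATA constants for
   intensities in (D/Å)²/amu, volumes in Å, frequencies in cm⁻¹.

2. **LO frequencies.** The non-analytic long-wavelength correction added to
   the reconstructed dynamical matrix along a chosen wave-vector direction
   (h k l) yields the longitudinal-optic frequencies; for a single-oscillator
   isotropic crystal this reduces exactly to the Lyddane–Sachs–Teller
   relation ν_LO = ν_TO √(ε_s/ε∞).

3. **Shape and homogenization.** A crystallite is a spheroid (sphere, plate,
   needle, or ellipsoid of aspect ratio z) described by its unit-trace
   depolarization tensor L. Randomly oriented inclusions at volume fraction
   f in a matrix of permittivity ε_e homogenize via Maxwell-Garnett,
   Bruggeman (iterative, flagged when unphysical), or the shape-free
   averaged-permittivity rule.

4. **Spectra.** N = √ε_eff (κ ≥ 0 branch), decadic absorption coefficient
   α = 4π ν κ log₁₀e, molar absorption a = α/C with C the molar
   concentration of unit cells including the fill fraction.

## Worked example

MgO has a single triply degenerate TO mode at 388.3 cm⁻¹ with intensity
9.29 (D/Å)²/amu, optical permittivity 3.14 and a primitive-cell volume of
19.15 Å (fcc, conventional edge 4.2468 Å). Built-in model:

```python
import powderspec as ps

model = ps.from_oscillator_table(ps.reference_models()["mgo"], sigma=10.0)
print(ps.static_permittivity(model)[0, 0])      # 10.003017741045806

scenario = ps.MixingScenario(
    method="maxwell", volume_fraction=0.1, matrix_permittivity=2.0,
    shape=ps.depolarization(ps.ShapeSpec("sphere")),
    crystal_volume=model.cell_volume,
)
table = ps.powder_spectrum(model, scenario, ps.SpectralGrid(300, 800, 0.2))
print(ps.peak_position(table.frequencies, table.molar_absorption))
# 534.8638189706758
```

The static permittivity evaluates to 10.0, and 10% MgO spheres in a
PTFE-like matrix absorb near 535 cm⁻¹ — shifted ~150 cm⁻¹ above the TO
frequency by the internal-field coupling, just below the dilute-limit
Fröhlich resonance at 543.7 cm⁻¹. The LO frequency from the synthetic
two-atom MgO crystal:

```python
print(ps.lo_frequencies(ps.mgo_crystal(), (0, 0, 1))[-1])  # 693.0556 cm^-1
```

## Command-line tool

```sh
powderspec -method maxwell -sphere -plate 0 0 1 -needle 0 0 1 \
    -vf 0.1 -matrix ptfe -sigma 5 -vmin 300 -vmax 800 -i 0.2 \
    -LO 0 0 1 -csv run.csv phonon.yaml
```

Input is a canonical phonon file (YAML with header
`format: powderspec-phonon v1`; see `powderspec/phonon_data.py` for the
schema — converters from QM/MM-code output should target it). Repeatable
flags (`-method`, shapes, `-vf`, `-mf`, `-LO`, `-ignore`, `-mode`,
`-mode_sigma`, `-plot`) fan out into one scenario per combination. The CSV
holds the command line, a per-mode block (frequency, intensity, integrated
molar absorption, peak height, damping) and the spectrum table (frequency,
then Re ε, Im ε, α, a per scenario).

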