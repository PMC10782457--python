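# adcfold

Damped (complex-polarization-propagator, CPP) linear response and excited
states at the ADC(2) level of theory, with the doubles manifold treated
implicitly by matrix folding.  The package computes UV/vis absorption and
electronic circular dichroism (ECD) spectra of small closed-shell molecules
from an XYZ geometry and a basis-set name, and validates every folded
quantity against an explicit dense singles+doubles matrix on desk-scale
systems.

## The method

ADC(2) — the second-order algebraic-diagrammatic construction for the
polarization propagator — represents the shifted Hamiltonian in a basis of
correlated singly (p–h) and doubly (2p–2h) excited intermediate states,
giving the Hermitian eigenproblem **M Y = Y Ω** built on the MP2 ground
state.  At second order the 2p–2h/2p–2h block is diagonal (orbital-energy
differences *d*), which allows two exact reductions to the p–h space:

* **Damped response.**  The complex linear equation
  `(M − (ω + iγ)1) X = B` is folded through the doubles resolvent
  `w = 1/(d − ω − iγ)` into a frequency-dependent effective singles problem
  `(M′(ω) − ω − i(M″(ω) + γ)) X_s = B_s′`, solved in a subspace of real
  trial vectors with either one *common* pooled subspace for all response
  equations or a *separate* subspace per frequency.  The imaginary part of
  the damped dipole response gives the absorption cross section
  `σ(ω) = (4πω/c)·Im ᾱ(ω)`, and the mixed linear-momentum/magnetic-dipole
  response gives Δε(ω) for ECD (velocity gauge).
* **Excited states.**  Folding turns the eigenproblem nonlinear,
  `M_eff(ω) Y_s = ω Y_s` with
  `M_eff(ω) = M_ss + M_sd (ω − M_dd)⁻¹ M_ds`; a reduced-space block method
  refines each eigenvalue with Newton–Raphson steps on
  `Θ(ω) = yᵀM_eff(ω)y` and collapses the subspace under controlled
  conditions.  Contracting converged eigenvectors with modified transition
  moments (complete through second order in the p–h block, including all 13
  second-order terms) yields oscillator and rotatory strengths.

The SCF reference, Gaussian-basis integrals (McMurchie–Davidson), the MO
transformation via batched auxiliary-Fock-matrix builds, MP2 amplitudes and
all ADC(2) contractions are implemented in the package; no external quantum
chemistry program is required.

## Worked example

Excited states of water (STO-3G), then a damped absorption spectrum:

```bash
adcfold states --xyz water.xyz --basis sto-3g --nstates 6 --output water
adcfold cpp --xyz water.xyz --basis sto-3g --freqs 0.40:0.50:5au \
        --gamma 1000cm-1 --output waterspec
```

`water_states.csv` (abridged):

```
state,energy_au,energy_ev,converged,osc_strength,...
1,0.403687,10.984880,True,6.4e-59,...
4,0.471041,12.817678,True,0.003283,...
```

States 1–3 are the spin-forbidden triplet components of the lowest
excitation (oscillator strength numerically zero); state 4 is the first
dipole-allowed singlet at 12.82 eV with f = 0.00328.  The CPP spectrum
`waterspec_spectrum.csv`

```
omega_au,omega_ev,sigma_au,delta_epsilon
0.4500000000,12.24512381,2.884322672436e-03,
0.4750000000,12.92540847,2.091016720406e-02,
0.5000000000,13.60569312,3.476083782163e-03,
```

peaks at the grid point nearest that singlet, with γ = 1000 cm⁻¹ setting
the Lorentzian width.  Δε is only written when the run includes the
magnetic-dipole/linear-momentum operators (achiral water would give zeros).

The same workflow drives chiral molecules: `--operators
dipole,linmom,magdip` adds the ECD spectrum, and mirror-image geometries
flip its sign exactly.

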