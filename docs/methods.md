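# Methods

## Model and working equations

All correlated quantities are formulated in spin orbitals over a restricted
Hartree–Fock reference (closed shell only; the interleaved spin-orbital
ordering keeps orbital energies ascending within the occupied and virtual
blocks).  The ADC(2) secular matrix is used in its standard strict form:

* p–h/p–h block through second order in the fluctuation potential — the
  zeroth-order orbital-energy-difference diagonal, the first-order
  `⟨aj||ib⟩` coupling, and the second-order differential-correlation terms
  built from the first-order doubles amplitudes
  `t_ijab = ⟨ij||ab⟩/(ε_i+ε_j−ε_a−ε_b)`;
* p–h/2p–2h coupling through first order,
  `M_{ia,klcd} = −⟨kl||id⟩δ_ac + ⟨kl||ic⟩δ_ad + ⟨al||cd⟩δ_ik − ⟨ak||cd⟩δ_il`,
  for the doubles phase convention `|Φ_ijkl⟩ = a†_a a†_b a_j a_i |Φ_0⟩`
  with ordered index pairs i<j, a<b (this restriction makes the 2p–2h
  block strictly diagonal and the folding denominators unambiguous);
* 2p–2h/2p–2h block at zeroth order (diagonal `ε_a+ε_b−ε_i−ε_j`).

Because the working equations are nowhere re-derivable from a single
reference implementation in this environment, the test suite contains an
*order-tracked numerical intermediate-state-representation oracle*
(`tests/isr_oracle.py`): it builds, in the full determinant space of very
small systems, the Møller–Plesset ground-state orders, the precursor
excited states, the Gram–Schmidt/symmetric orthonormalization between and
within excitation classes, and reads off every truncated block and the
modified transition moments numerically.  All closed-form expressions in
the package agree with this construction to machine precision on random
spin-orbital systems (arbitrary one- and two-body operators with proper
permutational symmetry) and on molecular fixtures.

### Modified transition moments

The p–h block of the modified transition moments is complete through
second order.  For a one-particle operator with MO blocks d_oo, d_ov,
d_vo, d_vv:

```
F_ia  = d_ai                                    (0th)
      + Σ_jb t_ijab d_jb                        (1st)
      + 13 second-order terms:
        −½ Σ_j ρ_oo[i,j] d_aj  −½ Σ_b d_bi ρ_vv[b,a]     (MP2 densities)
        +½ Σ t_ijab t_jkbc d_ck                           (t² chain)
        + Σ_jb td2_ijab d_jb  with td2 = (L_vv + L_oo − P(ij)P(ab)R)/D
          (ladder-vv ⟨ab||cd⟩, ladder-oo ⟨kl||ij⟩, four ring permutations)
        + Σ_b d_ab s2_ib − Σ_j d_ji s2_ja  (orbital-relaxation-like, with
          s2 split into its ⟨vo||vv⟩ and ⟨oo||ov⟩ pieces)
```

Seven of the thirteen terms (the t² chain, both ladders and the four
rings) carry the doubly nested occupied/virtual pair-loop structure that
dominates the formal N^6 scaling; the ladder-vv term is the ⟨vv||vv⟩
class.  The 2p–2h block is kept through first order,
`F_d = P(ab) d_vv·t2 − P(ij) d_oo·t2`.  All second-order intermediates are
operator-independent and are computed once per workspace, so batching over
operator components reuses them by construction.

## Folding and solvers

With `w(ω) = 1/(d − ω − iγ)` elementwise over the doubles diagonal d, the
folded response matrix splits as `M′(ω) = M_ss − C_sd diag(Re w) C_ds` and
`M″(ω) = C_sd diag(Im w) C_ds`; the complex equation is solved in the
coupled real symmetric 2×2-block form.  Trial subspaces are real;
per-frequency σ′/σ″ pairs are cached per subspace column.  Choices the
formulation leaves open were fixed as follows:

* New trial vectors are spawned from the real and imaginary parts of
  preconditioned residuals, `r/(diag(M_ss) − ω)` with the denominator
  floored at 1e-3 hartree in magnitude (standard Davidson practice; the
  solver is testably worse without it).
* Orthonormalization is modified Gram–Schmidt with one re-orthogonalization
  pass; vectors with post-projection norm below 1e-8 are dropped.
* "Relative residual" means ‖r‖/‖B_s′‖ per system, threshold 1e-4 by
  default.
* Both ±ω branches of a response function are enqueued as separate systems
  (the −ω branch is solved at negative signed frequency and conjugated),
  so one response function costs two reduced-space solves.
* The common-subspace strategy pools trial vectors across operators *and*
  frequencies (a flag exists only at the API level through grouping, and
  pooling everything is the default); the separate strategy groups systems
  by (signed frequency, γ).  Counters record both the σ-pairs actually
  computed (one per new vector per distinct frequency it is propagated to)
  and the product accounting "new vectors × unconverged response functions
  per iteration"; for separate subspaces the computed count equals the
  trial-vector count identically.

The nonlinear eigensolver starts from the lowest ADC(1) eigenpairs,
diagonalizes the projected `M_eff(ω_current)` each iteration, tracks the
current root by maximal overlap with its previous Ritz vector, applies the
Newton–Raphson update `ω ← ω − (Θ(ω) − ω)/(Θ′(ω) − 1)`, and expands with
preconditioned residuals of the current root and the next four higher
unconverged roots (block width 5).  The subspace is collapsed — retaining
converged eigenvectors plus the Ritz vectors of the active block — when its
dimension would exceed the maximum (default 200) or no candidate survives
the linear-dependence filter.  Convergence requires both the residual norm
(default 1e-5) and the Newton eigenvalue error (default 1e-6 hartree).
Converged doubles parts are reconstructed as `Y_d = (ω − d)⁻¹ C_ds Y_s` and
the full vector is normalized; roots whose residual stops improving over a
12-iteration window are flagged and skipped, never reported silently.

## Backend

Gaussian integrals use McMurchie–Davidson Hermite expansions with Boys
functions from the confluent hypergeometric function; Cartesian shells of
arbitrary angular momentum are supported by the recursions, and the shipped
basis registry (STO-3G; 6-31G for H, O; shell compositions of cc-pVDZ,
aug-cc-pVDZ and 6-311G** for counting) uses s and p shells for actual
integral evaluation.  The MO two-electron transformation follows the
auxiliary-Fock-matrix route: per MO pair (k,l) a Coulomb-type Fock build of
the pair density is transformed back to the MO basis; pairs are processed
in batches so peak memory is bounded by batch size × one AO matrix, and
results are bit-identical for any batch size.  One-electron operators are
the electric dipole −(r−O), linear momentum −i∇, and magnetic dipole
−½L̂ = −½(r−O)×p̂ (atomic units without the 1/c, which lives in the
spectral prefactors); the gauge origin O defaults to the nuclear center of
mass and is configurable.

## Spectral conventions

σ(ω) = (4πω/c)·Im ᾱ(ω) in atomic units with c = 1/α.  For ECD the
velocity-gauge rotatory strength is
`R_v = −(1/ω_f) Re Σ_α x(p_α) x(m_α)*` and Δε(ω) is obtained from the
imaginary part of the damped mixed p/m response with the standard
rotatory-strength (1 au = 235.7220 × 10⁻⁴⁰ cgs) and integrated-CD
(R = 22.97 ∫ Δε/E dE) constants, in L·mol⁻¹·cm⁻¹.  Lorentzian stick
broadening uses area-normalized lines scaled to the same units, so CPP and
broadened-stick spectra are directly comparable; they agree exactly at line
centers and to O(γ/ω) elsewhere.  One common γ damps all states.

## Synthetic model problems

`models.generate` emulates the folded block structure: a diagonally
dominant symmetric singles block with a prescribed spectral density
(states per unit energy over the drawn window; near-identity orthogonal
mixing, default 0.02, because real ADC singles blocks are diagonally
dominant — with a dense random rotation the diagonal preconditioner is
useless and every solve degenerates to spanning the full space), a dense
Gaussian coupling of prescribed norm, and a doubles diagonal drawn strictly
above the singles range by default so folding denominators behave like the
physical method in a UV window.  The generator reproduces the qualitative
solver-cost trend: average separate-subspace iteration counts grow
monotonically with the density-of-states knob.  It does not emulate
integral sparsity, spin symmetry, or realistic transition-moment
structure, so model-problem tests validate solver behavior, not chemistry.

## Fixture sizes and what the tests show

All oracle tests run on fixtures of at most ~40 spin orbitals in the
correlated space (H2/6-31G, LiH/STO-3G, H2O/STO-3G, twisted H2O2/STO-3G;
full singles+doubles dimensions up to ~2400), where the dense matrix, its
complete diagonalization and direct complex solves are exact references.
Passing them shows the folded formalism, the solvers and the property
chain are internally exact; it does not certify basis-set or method
accuracy against experiment, and the shipped basis registry is deliberately
small.  The determinant-space ISR oracle is limited to ~6–8 spin orbitals
by combinatorics, which is sufficient to pin every closed-form coefficient.

## Known limitations

Closed-shell references only; no spatial-symmetry adaptation (degenerate
multiplets are resolved numerically); no resolution-of-identity or
distributed-memory paths (the batched Fock-build transformation preserves
the incremental-construction contract on a single process); folded roots
are only reachable below the 2p–2h diagonal onset, as in the physical
method; velocity-gauge Δε retains the usual finite-basis gauge-origin
dependence, which is recorded as a diagnostic rather than removed.
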