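# Methods

## The sampling problem

Equilibrium molecular dynamics crosses free-energy barriers at rates that
fall exponentially with barrier height, so the slow conformational
transitions that matter — dihedral flips, chain compaction, loop docking —
are rare events on affordable timescales.  `pathmd` implements a
hybrid-Hamiltonian enhanced-sampling scheme in which the propagated
gradient combines the unbiased force field with history-dependent bias
terms built from the system's own phase-space path, optionally filtered
toward experimental distance restraints.  Everything is exercised on
small analytic model systems, so every component can be validated against
closed forms or brute-force oracles.

## Hybrid gradient

The engine propagates BAOAB Langevin dynamics under the total gradient

    ∇H(C) = ∇H(A) (1 + α_md)
          + ∇H(B)_ab · α′ |∇H(A)| / |∇H(B)_ab|
          + ∇H(B)_σ  · α′ |∇H(A)| / |∇H(B)_σ|

where ∇H(A) is the system gradient and the two bias terms are
renormalized so each carries a fixed fraction α′ of the global unbiased
gradient norm (a zero-norm term is omitted — never 0/0).  The couplings
are redrawn every step from independent uniforms ξ:

    α_md = η_md β_md (1 − ξ),    α′ = η′ β′ (1 − ξ′),

so the bias magnitude fluctuates between 0 and ηβ.  No bias energy is
ever reported: the recorded potential of a trajectory is V(A) only, and
the bias acts purely through forces.  A scalar hybrid-energy combination
is available as a diagnostic (`hybrid_energy`) but is never propagated.

## Path variables and the two bias components

Each step contributes a per-atom action-path increment

    dL = (p + dp) ∘ dq

(elementwise momentum-times-displacement; dq uses the minimum image on
periodic coordinates).  Every atom k is tracked under N_R parallel
biases i with window ladders τ1_i = i·τ1 and τ2_i = i·τ2, addressing
dynamical heterogeneity with a spread of coupling timescales.

**Adaptive-bias component.**  When a τ1_i window closes, the
window-accumulated increment vector, divided by the window length and
scaled by a constant fluctuation amplitude γ″ and a fresh standard
normal ζ, is frozen as that rung's gradient until the next closure:

    g_ik = γ″ ζ_ik (Σ_window dL_k) / τ1_i .

Because ζ is zero-mean, the component is an unbiased, slowly varying
random tilt whose direction derives from the recent path history; with
γ″ = 0 it vanishes identically.

**Path-sampling component.**  A running coordinate σ_ik accumulates the
scalar dL every step.  At every τ2_i boundary a repulsive Gaussian hill
(height W, width δσ) is deposited at the current σ_ik; the accumulated
hills push σ away from previously visited stretches of the path:

    Φ_ik = W Σ_c (σ−σ_c)/δσ² · exp(−(σ−σ_c)²/(2 δσ²)),

mapped back to atoms through the chain vector (p + dp).  Hills are
independent one-dimensional kernels per (i, k) — a joint kernel over all
coordinates would never be revisited.  A well-tempered variant (hill
height damped by exp(−U_acc/ΔE), ΔE = 1000 kJ/mol) is implemented but
off by default.  Since σ grows with the accumulated kinetic action, the
component acts as a ratchet against path reversal and as a forward kick
wherever progress stalls; with the global renormalization its applied
magnitude is always α′|∇H(A)| whenever it is nonzero.

**Hill width.**  δσ must live on the scale of the σ excursion between
deposits, not of the per-step increment (which is ~10³ times smaller —
a width tied to it would make every hill force underflow).  The default
is therefore calibrated at the first deposit as

    δσ = max(0.5 × std of the running σ path so far, floor = 1e-4),

and can be overridden with a fixed value (`hill_dsigma`).

**Principal-component filtering.**  Optionally (`use_pca`) the per-atom
bias direction is replaced by the eigenvector of the smallest eigenvalue
of the covariance of its recent history (window N_R·τ1 by default) —
the slowest mode — with the raw magnitude preserved, a deterministic
sign (first nonzero component positive) and lowest-axis tie-breaking;
rank-deficient windows fall back to the raw bias with a warning.

## Distance-restraint reweighting

Restraints (NOE- or crosslink-style records: an atom group, a single
partner atom, a target distance d0) never add energy.  Instead, at each
step the bias gradient on each restrained atom is reweighted by its
cosine overlap with the restraint vector q12 = q1 − q2 of the
minimum-distance pair:

    ∇H(B)_R = ∇H(B) · cos Ξ · sign(d12 − d0),

with cos Ξ taken against +q12 for the group-1 atom and −q12 for the
partner.  Because the bias enters as a gradient (force = −gradient),
the resulting force component along the restraint has magnitude
|bias|·cos²Ξ and always points toward fulfilment — attraction when the
pair is too far, repulsion when too close, and exactly zero at d12 = d0
(sign(0) = 0 by convention).  The reweighted magnitude never exceeds the
unrestrained one (|cos Ξ| ≤ 1), which the stack asserts along every run.
Multiple restraints on one atom compose in record order.  Restraints
whose atoms coincide (d12 = 0) are skipped for that step.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| N_R | 5 | — | parallel bias rungs |
| τ1, τ2 | 1.0, 2.5 | ps | adaptive-bias / hill-deposit base periods |
| β_md′, β′ | 1e-4 | — | coupling magnitudes |
| η_md′ | 1.0 | — | fluctuation range, unbiased renormalization |
| η′ | 2000 (toy configs) | — | fluctuation range of the bias |
| γ″ | 1e-4 | — | adaptive-bias fluctuation constant |
| W | 0.1 | kJ/mol | hill height |
| δσ | auto | σ units | hill width (see above) |
| ΔE | 1000 | kJ/mol | well-tempered scale (off by default) |
| dt | 0.005 | ps | timestep |
| kB | 0.0083144621 | kJ/mol/K | fixed unit system (kJ/mol, nm, ps, amu) |

The one deliberate departure from the macromolecular parameterization is
η′.  The renormalization uses the *global* gradient norm: in a protein,
stiff bonded terms across thousands of atoms make |∇H(A)| three to four
orders of magnitude larger than the force along any slow mode, so
β′ = 1e-4 yields a bias comparable to the slow-mode forces.  A one- or
ten-particle toy surface has no such separation — the global norm *is*
the local force — so the bundled toy configs restore the same effective
bias-to-mode-force ratio (mean α′ ≈ 0.1) through η′ = 2000.  The
`CouplingParams` class defaults remain β = 1e-4, η = 1.0.

## Model systems

All systems are analytic with hand-derived gradients, verified against
central differences (1e-6 relative) in the suite:

- `double_well_1d`/`_2d`: V = a((x/b)²−1)² per coordinate; minima ±b,
  barrier a.  Defaults a = 5 kJ/mol (≈2 kBT at 300 K) for equilibrium
  checks; the kinetics studies use a = 8 (≈3.2 kBT, rare-event regime).
- `muller_brown`: the classical four-Gaussian surface, scaled ×0.1 so
  its barriers are thermally crossable.
- `torsion_surface`: V = a(1−cos 3φ) + b(1−cos ψ), a periodic
  three-basin surrogate for a backbone dihedral landscape.
- `bead_chain`: harmonic bonds (k = 250 kJ/mol/nm², r0 = 0.25 nm) plus
  purely repulsive WCA nonbonded interactions between non-bonded pairs —
  deliberately without any attraction, so compaction in a steering run
  can only come from the restraint-filtered bias.

The restraint-fixture generator emulates a chemical-crosslink table:
pairs at least 3 bonds apart, a group of consecutive beads versus one
bead, a shared d0 (0.75 nm by default, the usual crosslinker length
scale).  It is deterministic per seed.  These fixtures are synthetic:
they share only the *shape* of experimental NOE/crosslink tables, so
passing tests demonstrate the mechanics of restraint-filtered biasing,
not agreement with any measured protein ensemble.

## Analyses

- **Transition kinetics** — waiting times between threshold crossings
  with hysteresis: a crossing counts only after the series dwells in the
  destination region ≥ `dwell_time` (default 1 ps), so a noise spike is
  never double-counted.  Zero events give an explicit no-transition
  result rather than NaN.
- **Arrhenius fits** — unweighted OLS of ln(1/τ) on 1/T; Ea = −slope·R,
  R = 8.314 J/mol/K.  On the bundled dialanine tables this reproduces
  the published activation energies (21.05, 18.8, 9.2 kJ/mol) within a
  fraction of a percent to ~0.5%.
- **Acceleration factor** — ρ = τ_u/τ_b.
- **Free-energy landscapes** — ΔF = −kBT ln(P/P_ref) from 1-D/2-D
  histograms, in kBT units.  Default reference P_max (minima at 0,
  ΔF ≥ 0); `ref="min"` gives the literal minimal-probability reference
  (populated bins ≤ 0, basins most negative — the convention of typical
  landscape figures).  Empty bins are masked.
- **Multi-exponential relaxation** — variable projection (amplitudes by
  linear least squares inside a log-rate optimization), 10 seeded
  multi-starts, modes sorted by rate.
- **Dipole statistics** — normalized fluctuation autocorrelation and the
  standard fluctuation estimate ε(0) = 1 + (⟨M²⟩−⟨M⟩²)/(3ε₀VkBT) for
  dipole series in e·nm.
- **Restraint fulfilment** — Δ(t) = d(t) − d0 per restraint with
  min/mean and fulfilled-fraction summaries, plus an optional ΔF profile
  of Δ.

## Validation studies and their problem sizes

`pathmd.validation` fixes the study conditions; `scripts/acceptance.py`
re-runs them end to end.

- *Boltzmann recovery*: 64 independent double-well walkers (a = 5),
  2×10⁵ steps; the well-population ratio is checked against the analytic
  value 1 with a standard error taken across walkers, and the histogram
  free-energy profile against the bin-integrated Boltzmann weights.
- *Acceleration*: a = 8, friction 0.3/ps.  Unbiased baselines from one
  ensemble run of 20 walkers × 6×10⁵ steps (~75 escapes each); 20
  biased runs of 10⁵ steps.  Reported: per-pair ρ, the pooled ratio,
  and a one-sided Mann-Whitney test on pooled waiting times.  Under
  these conditions the default bias yields ρ ≈ 2.
- *Steering*: 10-bead chain, one restraint spanning beads 0–9 (initial
  distance 2.25 nm, d0 = 0.75 nm), 20 seeds × 1.5×10⁴ steps, restrained
  vs unrestrained biased runs compared on the last-quarter mean Δ.

Run lengths are the package's own choices, sized so a full study
completes in minutes on one core while leaving clear statistical margins.

## Numerical choices and edge cases

- BAOAB splitting: accurate configurational sampling at moderate dt; at
  γ = 0 it reduces to velocity Verlet (energy drift < 1e-4 relative over
  10⁴ steps is tested).  The thermostat noise is drawn every step even
  at γ = 0, so the stream is consumed identically across configurations.
- One RNG stream per stochastic component (thermostat, coupling ξ,
  adaptive ζ, fixtures), all derived from the master seed.  This makes
  the unbiased limit exact: with β′ = β_md′ = 0 a biased-stack run is
  byte-identical to the plain engine at the same seed.
- The bias gradient is frozen over the step it is applied to (it derives
  from the previous displacement); the system gradient is refreshed
  within the step.
- Window and deposit periods are converted to whole step counts by
  rounding to the nearest step (minimum 1).
- Hills beyond 8 δσ contribute < 1e-13 of W and are skipped before any
  exponential is evaluated; all rungs share one σ row, so the rung-summed
  force is evaluated in a single flattened pass (tested equal to the
  per-rung sum).
- Non-finite forces abort a run with a diagnostic rather than
  propagating NaNs.
- Degenerate inputs: empty hill histories give zero force; a zero bias
  vector has cos Ξ = 0; coincident restrained atoms skip the restraint
  for that step; an all-in-one-bin histogram is flagged degenerate.

## Known limitations

- The toy systems have no force-field realism: no electrostatics, no
  solvent, no constraints.  Conclusions about proteins do not follow
  from these tests; they validate the machinery, not the biology.
- σ accumulates (p+dp)·dq, which has a positive mean (≈2·KE·dt per
  step), so the path coordinate drifts and hills act mainly against
  reversals and stalls rather than building a confining landscape; the
  free-energy estimator is therefore histogram-based, never a hill sum.
- The per-pair acceleration factor fluctuates strongly with the random
  coupling history; only ensembles of replicates are meaningful.
- Restraint group semantics use the minimum distance, not r⁻⁶ NOE
  averaging.
- Atom indices in restraint files are 0-based.
- The τ ladders are shared across atoms; per-atom window overrides (an
  extension the formalism admits for strongly heterogeneous systems) are
  not implemented.
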