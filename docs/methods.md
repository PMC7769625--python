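# Methods

## Model

The membrane model is an eight-variable conductance-based description of a
cerebellar stellate cell: membrane potential `V`, six first-order gating
variables (`h`, `n`, `nA`, `hA`, `hT`, `mHVA`) and the cytosolic Ca²⁺
concentration `Ca` (μM). Na⁺ activation `m` and T-type activation `mT`
are fast and evaluated at their voltage-dependent steady states; the
A-type activation `nA` is dynamic with τ = 5 ms. All steady-state curves
are Boltzmann sigmoids `x∞ = 1/(1+exp(−(V−v_x)/s_x))`. The delayed
rectifier activates with `τ_n(V) = 6/(1+exp((V+23)/15))` ms; Na⁺
inactivation uses a peaked profile centred at `Vc = −74 mV`,

```
τ_h(V) = y0 + 2·A·w / (4π (V−Vc)² + w²),
```

with baseline `y0 = 0.1 ms` and peak `y0 + 2A/w ≈ 14.1 ms`. The placement
of π in this expression is the single most consequential numerical choice
in the package: the alternative convention that normalizes the peak by π
(peak ≈ 4.6 ms) speeds Na⁺ inactivation recovery enough to remove the
Hopf bifurcation from the fast subsystem's depolarized branch, and with it
every square-wave bursting solution. The reading above restores the full
phenomenology (tonic ≈ 29 Hz post-runup, 14 spikes per burst at
g_HVA = 0.232 μS·cm⁻²) and is therefore adopted throughout.

The Ca²⁺ balance `dCa/dt = −ε(α(I_T + I_HVA) + k·Ca)` couples the two
Ca²⁺ currents (inward, hence negative, below E_Ca = +22 mV) to a linear
extrusion with rate `k = 0.1 ms⁻¹`; the time-scale factor `ε = 0.015`
makes Ca²⁺ the slowest variable (effective time constant ≈ 0.7 s). `Ca`
is not clamped at zero; in every studied regime it stays positive because
the influx term vanishes only at E_Ca.

Two presets differ only in six gating constants (`v_m, s_m, v_h, v_nA,
v_hA, s_hA`) and represent the cell before and after *runup*, the gradual
increase in excitability over ~25 min of whole-cell recording.

## Numerics

- **Integration.** LSODA with rtol 1e-8 / atol 1e-10 and equispaced dense
  output at 0.025 ms (upstrokes change by < 2 mV between samples).
  Kernels are numba-compiled; identical inputs give bit-identical output.
  Halving the tolerances moves spike times of a 2-s tonic trace by
  < 0.5 ms.
- **Equilibria.** At a fixed point every gate equals its steady state and
  `Ca* = −α(I_T+I_HVA)/k`, so the fixed-point problem reduces to one
  scalar current-balance equation in V, bracketed on a dense grid over
  [−120, 20] mV and polished by Brent's method. This closed form doubles
  as an independent oracle for the continuation code (agreement ≤ 1e-8 mV
  is asserted in the tests).
- **Continuation.** Pseudo-arclength with a bordered-Newton corrector and
  the analytic Jacobian. Saddle-nodes are detected by a sign change of
  det J (robust against the small constant Ca eigenvalue −εk masking the
  fold eigenvalue) and Hopf points by a sign change of the leading complex
  pair's real part; both are refined by bisection along the branch and
  certified from the eigenvalues at the refined point — indicator jumps
  caused by eigenvalue pairs changing character (real ↔ complex) are
  discarded by the certificate.
- **Periodic orbits.** Single shooting on the frozen-(h_A, Ca) fast
  subsystem with the period free and an anchoring phase condition; the
  monodromy matrix comes from integrating the 6×6 variational equations,
  so every accepted point carries Floquet multipliers (trivial multiplier
  within 1e-4 of +1). The arclength metric scales voltage by 25 mV,
  gates by 0.3, the period by its seed value and h_A by 2e-3 so that
  steps are commensurate. SNP/PD events are multiplier crossings of ±1.
- **Homoclinic approaches.** Near a homoclinic connection the monodromy
  grows like exp(λ_u T); single shooting therefore stalls before the
  period formally diverges. A branch end is declared a homoclinic
  approach when the period has grown above the smallest period on the
  branch *and* the last computable orbit passes within 2.0 (state-space
  norm, dominated by mV in V) of a saddle equilibrium. In practice the
  isolated family's ends stall within 0.05–0.07 of the saddle and the
  Hopf family within ~1.1, with monotonically growing periods, so the
  criterion separates cleanly from ordinary fold turns. With it, the
  square-wave configuration at Ca = 0.25 μM yields exactly three
  homoclinic terminations: one ending the subcritical-Hopf family of the
  Z-curve (HC₁) and two ending the isolated spiking family near the lower
  fold (HC₂ beyond the SNP, HC₃ beyond the PD).
- **Critical manifold.** Per-(h_A, Ca) node root bracketing of the scalar
  balance; folds located by bisection on the root count; the Hopf locus by
  bisection on the upper sheet's complex pair. Root counts are 1 or 3
  everywhere on the default grids.

## Attractor probing and classification

Bursting orbits in this model are isolas that frequently coexist with a
stable rest state (the depolarized equilibrium is weakly stable even at
control conductances), so a single initial condition routinely misses
them. Classification of a parameter set therefore integrates a battery of
three initial conditions — cold start at −70 mV, deep start at −85 mV,
and a start with the slow pair preloaded (h_A = 0.3, Ca = 0.3 μM) — and
reports the most complex attractor found (CB > SW > PB > T > ESS > Q).
Regime sweeps visit cells in serpentine order with inherited initial
conditions and retry any quiescent outcome once from the probe state,
which is what lets the sweep hold on to the bursting family through the
bistable windows between isolas.

Decision rules (defaults exposed in `DetectorSettings`): spikes are local
maxima above −20 mV separated by ≥ 2 ms; bursts split at inter-spike gaps
exceeding 3× the median ISI; a *pseudo-plateau* burst has a spike-free
segment of ≥ 20 ms above −35 mV (threshold − 15 mV) after its last spike,
with non-growing intra-burst spike peaks — calibrated so that the
square-wave, tonic and pseudo-plateau exemplars in this model separate
with wide margins (post-spike supra-level runs are 37–95 ms in the PB
configurations and 0 ms in SW/tonic). Chaotic bursting is a
spikes-per-burst sequence with no period ≤ 4; the ESS/Q boundary is
−65 mV, between the depolarization-block rests of this model
(−62…−39 mV) and hyperpolarized rest (below −70 mV). The classification
of all printed parameter sets is stable under ±10% changes of the
detector threshold.

## Synthetic surrogates

The surrogate generator renders spike trains as Gaussian bumps (width
1 ms, amplitude 60 mV) on a −65 mV baseline, with exact ground-truth
spike times and burst bounds, optional geometric amplitude decay into a
−32 mV plateau (pseudo-plateau morphology; damped peaks are floored at
−14 mV so they remain above the detector threshold), and additive
Gaussian measurement noise on V only. The plateau level sits 6σ below
the spike threshold at the maximum calibrated noise (2 mV), so detection
F1 = 1.0 is an invariant, not a statistical accident. What passing these
tests shows is that the detector stack is exact on additive-Gaussian
surrogates; it does not establish robustness to real-electrode artifacts,
drift or seal noise, which are out of scope.

## Problem sizes

Default study conditions: 20–30 s simulations for steady-state burst
counts (≥ 10 bursts after a 25% transient discard, analysis over the
last 80%), 50–60 s for chaos detection, 33×9 (h_A × Ca) manifold grids
for overlays, and one-dimensional sweeps of 10–14 cells for the
spike-adding trend. These sizes resolve every feature they are used to
measure; enlarging them changes no reported value.

## Known limitations

- The two printed quantities that do not reproduce exactly are the
  10-spike burst at g_HVA = 0.253 μS·cm⁻² (this realization places the
  10-spike isola at ≈ 0.259–0.260, and 0.253 lands on a 14-spike isola
  from every probed initial condition) and the chaotic point at
  (g_KCa, g_HVA) = (3, 0.215) (periodic 5-spike bursting here; chaos
  appears at (3, 0.21)). Both are ~2% parameter shifts of structures the
  model itself makes exponentially sensitive; the companion anchors
  (14 spikes at 0.232, the Hopf at ≈ 18.5 vs ≈ 20, three homoclinics)
  reproduce.
- Full-system periodic-orbit isolas are traced by simulation with
  inherited states, not by collocation continuation; unstable envelopes
  and exact SNP/PD loci of the full system are therefore not computed.
- Homoclinic connections are reported as approach events, not converged
  connecting orbits.
- Three-time-scale decomposition and canard analysis are not attempted.
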