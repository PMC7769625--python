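# cscburst

Cerebellar stellate cells (CSCs) are spontaneously active inhibitory
interneurons that normally fire tonically (5–30 Hz) and never burst — yet
under pharmacological manipulation (4-aminopyridine, cadmium) they produce
two distinct bursting patterns. `cscburst` implements a conductance-based
model of a CSC that explains this: a Hodgkin–Huxley-type membrane equation
with Na⁺, delayed-rectifier K⁺, leak, A-type K⁺ and T-type Ca²⁺ currents,
extended with a high-voltage-activated (HVA) Ca²⁺ current, a
Ca²⁺-activated K⁺ current gated by a fifth-order Hill function of
cytosolic Ca²⁺, and a Ca²⁺ flux-balance equation:

```
C dV/dt  = I_app − I_Na − I_K − I_L − I_A − I_T − I_K(Ca) − I_HVA
dx/dt    = (x∞(V) − x) / τ_x ,   x ∈ {h, n, nA, hA, hT, mHVA}
dCa/dt   = −ε (α (I_T + I_HVA) + k·Ca)
```

with `I_Na = g_Na m∞³ h (V−E_Na)`, `I_K = g_K n⁴ (V−E_K)`,
`I_K(Ca) = g_K(Ca) · Ca⁵/(k_Ca⁵+Ca⁵) · (V−E_K)`, and instantaneous Na⁺ and
T-type activation. Two gating presets capture the *runup* of excitability
during whole-cell recording (`pre_runup`, `post_runup`).

The package is the full analysis stack around that model, aimed at
computational neuroscientists studying bursting dynamics:

- **simulate** — stiff integration (LSODA, rtol 1e-8) under constant,
  step, hold-release and paired-synaptic-input protocols;
- **features** — spike detection, burst segmentation, ISI return maps,
  first-spike latency, and classification into tonic (T), square-wave
  (SW), pseudo-plateau (PB) and chaotic (CB) bursting, depolarization
  block (ESS) or rest (Q);
- **bifurcation** — pseudo-arclength continuation of equilibria with
  certified saddle-node/Hopf detection, SNIC (type I excitability)
  testing, single-shooting continuation of fast-subsystem periodic orbits
  with Floquet multipliers from the variational equations, and
  two-parameter regime sweeps with bistability probing;
- **slowfast** — the critical manifold over the two slow variables
  (h_A, Ca), fold/Hopf/homoclinic loci, and burst overlays that expose the
  fold/homoclinic (square-wave) and fold/sub-Hopf (pseudo-plateau)
  mechanisms;
- **synthetic** — surrogate burst trains with exact ground truth for
  validating the detector stack.

## Worked example

```python
import cscburst as cb

post = cb.ModelParameters.post_runup()

# spontaneous activity at control conductances
traj = cb.integrate(post, duration=4000.0)
print(cb.classify_regime(traj))            # -> T  (tonic, ~29 Hz)

# potentiating the HVA Ca2+ current switches the cell to bursting
burst = cb.integrate(post.replace(g_HVA=0.232), duration=30000.0)
print(cb.classify_regime(burst))           # -> SW
print(cb.spikes_per_burst(burst))          # -> 14

# where does the K(Ca) conductance destabilize the rest state?
sw = post.replace(g_HVA=0.249)
branch = cb.continue_equilibria(sw, "g_KCa", (0.1, 30.0))
print([(e.kind, round(e.param, 2)) for e in branch.events])
# -> [('HB', 1.2), ('SN', 7.84), ('SN', 8.2), ('HB', 18.47)]
```

The two Hopf points bracket the conductance range in which the rest state
is unstable; beyond the upper one (≈18.5 μS·cm⁻²) the cell sits in
depolarization block. The 14-spike count is one member of a family of
*isolas* of bursting orbits: probing `g_HVA = 0.25` and `0.26` with
`cb.burst_trajectory` (which scans a battery of initial conditions,
because these orbits coexist with a stable rest state) finds 12- and
10-spike bursts — spike adding in this model is non-sequential, and
neighbouring isolas overlap in small bistable windows.

The `examples/` directory holds one short narrative script per capability
(tonic firing, square-wave bursting, regime classification, bifurcation
diagrams, slow-fast dissection, surrogate validation); each prints the
numbers it computes and says what they mean. A thin CLI mirrors the
common entry points:

```
cscburst simulate --set g_HVA=0.232 --duration 30000 --out burst.tsv
cscburst classify burst.tsv
cscburst run --config fig15_map --out out/
```

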