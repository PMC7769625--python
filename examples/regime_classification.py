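"""Classify the firing regime at pharmacologically motivated conductance sets.

Each parameter set emulates a drug condition: potentiated HVA (low-dose
4-AP) gives square-wave bursting; strongly potentiated HVA (high-dose 4-AP)
or potentiated K(Ca) with reduced g_K (4-AP + Cd2+) gives pseudo-plateau
bursting.  Because bursting orbits often coexist with a stable rest state,
classification probes a small battery of initial conditions and reports the
most complex attractor found.
"""
import cscburst as cb

post = cb.ModelParameters.post_runup()
cases = [
    ("control", {}),
    ("HVA up, A-type down", {"g_HVA": 0.26, "g_A": 6.0}),
    ("HVA up", {"g_HVA": 0.235}),
    ("K down, K(Ca) up, HVA up", {"g_K": 12.0, "g_KCa": 7.0, "g_HVA": 0.22}),
    ("HVA strongly up", {"g_HVA": 0.77}),
    ("depolarization block", {"g_HVA": 1.5}),
]
for name, overrides in cases:
    label = cb.classify_parameter_set(post.replace(**overrides))
    print(f"{name:>26}: {label}")

# T = tonic, SW = square-wave bursting, PB = pseudo-plateau bursting,
# CB = chaotic bursting, ESS = elevated steady state (block), Q = rest.
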