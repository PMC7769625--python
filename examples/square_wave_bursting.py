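"""Square-wave bursting induced by potentiating the HVA Ca2+ current.

Raising g_HVA from its control value (0.08 uS/cm^2) mimics the potentiation
produced by a low dose of 4-AP and switches the cell from tonic firing to
square-wave bursting.  The number of spikes per burst is extremely
sensitive to g_HVA because the bursting orbits live on a family of isolas.
"""
import cscburst as cb

post = cb.ModelParameters.post_runup()
for g_hva in (0.232, 0.25, 0.26):
    params = post.replace(g_HVA=g_hva)
    try:
        traj = cb.burst_trajectory(params, duration=25000.0)
    except ValueError:
        print(f"g_HVA = {g_hva}: no bursting attractor found")
        continue
    feats = cb.extract_features(traj)
    print(f"g_HVA = {g_hva}: regime {feats.regime}, "
          f"spikes/burst {cb.spikes_per_burst(traj)}, "
          f"active {feats.active_durations.mean():.0f} ms / "
          f"silent {feats.silent_durations.mean():.0f} ms")

# Note the non-sequential spike adding: a 2% change in g_HVA can move the
# count by several spikes because adjacent isolas differ by more than one.
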