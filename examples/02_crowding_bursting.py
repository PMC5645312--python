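"""Transcriptional bursting under macromolecular crowding.

Sweeps the local density Gamma through the crowding-scaled telegraph
model (k_on ~ Gamma^-0.36, k_off ~ Gamma^-1.36, so the binding
equilibrium grows linearly with density while both rates slow) and
summarizes the steady-state mRNA ensembles.
"""

import numpy as np

import chromden as cd

params = cd.TelegraphParams()  # activating TF, rates in /min
spec = cd.SweepSpec(
    gamma_values=np.array([1.0, 8.0, 22.0, 43.0, 71.0, 99.0]),
    n_trajectories=200,
    t_end_min=1000.0,
    burn_in_min=500.0,
    seed=11,
    dip_replicates=2000,
)
summaries = cd.sweep(params, spec)
print(cd.sweep_table(summaries).round(4).to_string(index=False))
print("-> pulse frequency falls with density (slower rebinding kinetics);")
print("   CV rises then falls; the dip test flags bimodality at high Gamma")

curve = cd.bifurcation_curve(summaries)
for _, row in curve.iterrows():
    modes = ", ".join(f"{m:.0f}" for m in row["modes"])
    print(f"Gamma {row['gamma']:5.0f}: {row['n_modes']} expression state(s) at mRNA ~ [{modes}]")
print("-> condensation bifurcates an activating gene toward a second, higher state")
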