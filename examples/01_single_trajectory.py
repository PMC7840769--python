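"""Simulate one enzyme end-tracking a treadmilling filament.

A single FtsI-like enzyme starts at the shrinking end of a 50-subunit
FtsZ filament treadmilling at 25 nm/s, with diffusion constant
0.04 um^2/s and a 10 k_BT binding well, and is classified with the
persistence criteria (distance to the end < 100 nm, unidirectional
following > 4 s).
"""

import endtrack as et

params = et.RatchetParams(
    D=0.04e6,       # nm^2/s  (0.04 um^2/s)
    U0=10.0,        # k_BT
    V_Z=25.0,       # nm/s
    t_max=120.0,    # s
    seed=2,
    dt=et.choose_dt(0.04e6, 10.0, 25.0),
)

traj = et.simulate_trajectory(params)
persistent, runs = et.classify_end_tracking(traj)

print(f"simulated {traj.t[-1]:.1f} s at dt = {params.dt:.2e} s")
print(f"first escape beyond 100 nm of the filament: {traj.first_escape:.2f} s")
print(f"persistent end-tracking: {persistent}")
for v, d, T in zip(runs.speeds, runs.durations, runs.distances):
    print(f"  run: {T:7.1f} nm in {d:5.1f} s  ->  {v:5.1f} nm/s")
print(
    "\nThe run speed matches the treadmilling speed: the enzyme is pulled\n"
    "forward 5 nm at a time by sequential loss of binding wells at the\n"
    "shrinking end (a Brownian ratchet), not by any motor stroke."
)
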