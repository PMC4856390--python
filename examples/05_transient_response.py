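"""Time course of the voltage after a brief current pulse.

Crank–Nicolson integration of the full time-dependent cable equation on a
tapering cable: a 2 ms, 1 nA pulse is injected at two sites and the
response at the proximal end is timed.  More distal inputs arrive later
and smaller — the diffusive delay and attenuation that the steady-state
transfer analysis summarises.
"""

import numpy as np

from cabletaper import PassiveParams, make_quadratic_cable, solve_transient

params = PassiveParams(r_a=60.0, g_l=5.0e-4, tau=20.0)
L, r_L = 500.0, 0.25
cable = make_quadratic_cable(L, r_L, (1.5 - r_L) / L**2, 1001)


def pulse(t_ms: float) -> float:
    return 1.0 if t_ms <= 2.0 else 0.0


for site in (150.0, 350.0):
    times, x, V = solve_transient(
        cable, params, inj_x=site, I_shape=pulse, T=60.0, dt=0.25, n=401
    )
    v0 = V[:, 0]  # proximal-end trace
    k = int(np.argmax(v0))
    print(
        f"pulse at {site:5.1f} um: proximal peak {v0[k]:5.2f} mV "
        f"at t = {times[k]:5.2f} ms"
    )
print("(membrane time constant tau = 20 ms; pulse duration 2 ms)")
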