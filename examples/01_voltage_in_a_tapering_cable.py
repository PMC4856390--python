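"""Steady voltage in a cable with noisy, periodically varying radius.

Builds a 1 mm synthetic dendrite whose radius oscillates about 0.5 µm,
injects 1 nA at three sites, and compares the first-order multiple-scales
solution against the finite-difference oracle under identical boundary
conditions (semi-infinite continuation at the soma end, sealed distal tip).
"""

from cabletaper import PassiveParams, compare_voltages, make_periodic_cable

params = PassiveParams(r_a=60.0, g_l=5.0e-4)  # fly tangential-cell values
cable = make_periodic_cable(
    length=1000.0, mean_radius=0.5, period=125.0,
    amplitude_range=0.03, n_points=2001, seed=1,
)

report = compare_voltages(
    cable, params, inj_sites=[300.0, 600.0, 900.0], smooth_window_um=125.0
)

print("taper-rate parameter: median eps =", round(report["median_epsilon"], 4))
for site in report["sites"]:
    print(
        f"injection at {site['inj_x_um']:6.1f} um: peak {site['v_num_peak_mV']:7.2f} mV, "
        f"max rel error {site['max_rel_error']:.4f}, mean {site['mean_rel_error']:.5f}"
    )
print(f"worst-case relative error over all sites: {report['max_rel_error']:.4f}")
# The error is of the order of eps: the closed-form solution tracks the
# exact voltage to a few percent on a visibly wiggly cable, and to <1% once
# the radius varies slowly on the scale of the electrotonic length.
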