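"""Passive membrane parameters and unit conventions.

External units throughout the package: lengths in µm, voltages in mV,
currents in nA, resistances in MΩ, time in ms.  The passive constants keep
the units they are conventionally quoted in: axial resistivity r_a in Ω·cm
and specific membrane conductance g_l in S/cm².  Every expression that mixes
a radius with r_a or g_l converts µm → cm in one place (this module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: µm per cm — the single geometric conversion constant.
UM_PER_CM = 1.0e4


@dataclass(frozen=True)
class PassiveParams:
    """Passive electrical constants of a dendritic membrane.

    Parameters
    ----------
    r_a
        Axial (cytoplasmic) resistivity in Ω·cm.
    g_l
        Leak conductance per unit membrane area in S/cm².
    tau
        Membrane time constant in ms (τ = c_m / g_l); only used by the
        transient solver.
    """

    r_a: float
    g_l: float
    tau: float = 20.0

    def __post_init__(self) -> None:
        if not (self.r_a > 0 and self.g_l > 0 and self.tau > 0):
            raise ValueError("r_a, g_l and tau must all be strictly positive")


# Named parameter sets for the cell classes the method is usually applied to
# (fly tangential HS/VS cells, dentate gyrus granule cells, cerebellar
# Purkinje cells and neocortical layer-V pyramidal cells).
PARAM_SETS: dict[str, PassiveParams] = {
    "fly_hs": PassiveParams(r_a=60.0, g_l=5.0e-4),
    "fly_vs": PassiveParams(r_a=60.0, g_l=5.0e-4),
    "granule": PassiveParams(r_a=210.0, g_l=4.0e-5),
    "purkinje": PassiveParams(r_a=150.0, g_l=5.0e-5),
    "layer5": PassiveParams(r_a=150.0, g_l=5.0e-5),
}


def electrotonic_length_um(r_um: np.ndarray | float, params: PassiveParams):
    """Local electrotonic length λ(x) = sqrt(r(x) / (2 r_a g_l)), in µm.

    λ is the distance over which voltage decays e-fold on a uniform cable of
    radius r; it is the fast spatial scale of the passive voltage.
    """
    r_cm = np.asarray(r_um, dtype=float) / UM_PER_CM
    lam_cm = np.sqrt(r_cm / (2.0 * params.r_a * params.g_l))
    out = lam_cm * UM_PER_CM
    if np.ndim(r_um) == 0:
        return float(out)
    return out
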