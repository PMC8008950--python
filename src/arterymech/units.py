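"""Unit conventions and conversion factors.

Geometry is carried in micrometres, pressure in mmHg at the interface and
kPa internally, transducer force in mN, stresses in kPa.  With those choices
a stress [kPa] times an area [um^2] equals 1e-6 mN, which is the single
conversion the force-balance formulas need.
"""

MMHG_TO_KPA: float = 0.133322
"""1 mmHg in kPa."""

KPA_UM2_TO_MN: float = 1e-6
"""kPa * um^2 expressed in mN (1e3 Pa * 1e-12 m^2 = 1e-9 N)."""


def mmhg_to_kpa(p_mmhg):
    return p_mmhg * MMHG_TO_KPA
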