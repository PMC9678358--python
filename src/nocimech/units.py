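"""Internal unit system: micrometre / millinewton / megapascal.

All geometry is carried in μm, pressures and elastic moduli in MPa, and
forces in mN.  The system is self-consistent through

    1 MPa × 1 μm² = 1 μN = 1e-3 mN,

so Hertzian expressions evaluated in (MPa, μm) yield μN and are converted
to mN with :data:`UN_PER_MN` exactly once, here.
"""

from __future__ import annotations

#: micronewtons per millinewton
UN_PER_MN: float = 1000.0

#: standard gravity used for the water-column force calibration, m/s²
STANDARD_GRAVITY: float = 9.8

#: density of pure water used for calibration, g/mL
WATER_DENSITY: float = 1.0


def un_to_mn(force_un: float) -> float:
    """Convert μN (native MPa·μm² unit) to mN."""
    return force_un / UN_PER_MN


def mn_to_un(force_mn: float) -> float:
    """Convert mN to μN."""
    return force_mn * UN_PER_MN
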