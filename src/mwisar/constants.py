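"""Physical constants and global sign conventions.

All propagation phases in the forward model follow the ``exp(+j*omega*tau)``
convention (PHASE_SIGN = +1); range compression uses the matching
forward-sign DFT so positive delays land in positive delay bins.
"""

C0 = 299_792_458.0
"""Speed of light in vacuum, m/s."""

EPS0 = 8.8541878128e-12
"""Vacuum permittivity, F/m."""

Z0 = 376.730
"""Impedance of free space, ohm."""

PHASE_SIGN = +1
"""Sign of the propagation phase exponent exp(PHASE_SIGN * j * omega * tau)."""
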