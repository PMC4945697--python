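"""Canonical unit system: gram - millimetre - second.

All quantities inside the package are carried in this system:

===========  =======================  ==========================
quantity     canonical unit           relation to familiar units
===========  =======================  ==========================
pressure     g mm^-1 s^-2             1 mmHg  = 133.32
flow         mm^3 s^-1                1 mL/s  = 1000
volume       mm^3                     1 mL    = 1000
resistance   g mm^-4 s^-1             1 mmHg s/mL = 0.13332
compliance   mm^4 s^2 g^-1            1 mL/mmHg   = 7.5008
elastance    g mm^-4 s^-2             --
energy       g mm^2 s^-2              1 J     = 1e9
===========  =======================  ==========================

The single mmHg conversion constant used throughout the package is defined
here; 133.32 g/(mm s^2) per mmHg is consistent with a preload of 4 mmHg
printed as 533.320 in the heart-parameter table.
"""

from __future__ import annotations

#: g mm^-1 s^-2 per mmHg (defined once; do not redefine elsewhere).
MMHG = 133.32

#: canonical energy units (g mm^2 s^-2) per joule.
JOULE = 1.0e9

#: mm^3/s per L/min.
L_PER_MIN = 1.0e6 / 60.0


def mmhg_to_canonical(p_mmhg: float) -> float:
    """Convert a pressure in mmHg to canonical g mm^-1 s^-2."""
    return p_mmhg * MMHG


def canonical_to_mmhg(p: float) -> float:
    """Convert a canonical pressure to mmHg."""
    return p / MMHG


def canonical_to_joules(energy: float) -> float:
    """Convert a canonical energy (g mm^2 s^-2) to joules."""
    return energy / JOULE


def flow_to_l_per_min(q: float) -> float:
    """Convert a canonical flow (mm^3/s) to L/min."""
    return q / L_PER_MIN
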