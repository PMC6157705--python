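"""Reciprocal-space conversions.

A real-space repeat distance d maps to a Bragg peak at q = 2*pi/d and
vice versa (q in nm^-1 when d is in nm).  Used e.g. to place the lipid
lamellar peak: bilayer stacks with d ~ 4.26 nm scatter at q ~ 1.47 nm^-1.
"""

from __future__ import annotations

import math

__all__ = ["spacing_to_q", "q_to_spacing"]


def spacing_to_q(d: float) -> float:
    """Scattering-vector magnitude q = 2*pi/d for a repeat distance d > 0."""
    if d <= 0:
        raise ValueError("spacing must be positive")
    return 2.0 * math.pi / d


def q_to_spacing(q: float) -> float:
    """Real-space repeat distance d = 2*pi/q for a peak position q > 0."""
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * math.pi / q
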