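"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places.

    Applied to the double-precision value as computed (multiply, add 0.5,
    floor), which is what reported percentages in this package use; note
    that a real-valued exact half that is not representable in binary
    rounds according to its double approximation.
    """
    scale = 10.0 ** ndigits
    r = math.floor(abs(x) * scale + 0.5) / scale
    return math.copysign(r, x)


def population_sd(values) -> float:
    """Standard deviation with divisor n (not n-1)."""
    n = len(values)
    if n == 0:
        raise ValueError("population_sd of empty sequence")
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)
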