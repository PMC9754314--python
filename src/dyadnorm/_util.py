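"""Small shared numeric helpers."""
from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; estimation outputs
    here must follow the conventional half-away-from-zero rule so that,
    e.g., 30.5 -> 31 and -0.5 -> -1.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def clip_estimate(value: int, floor: int = 1) -> int:
    """Apply the integer floor used for all emitted estimates."""
    return max(floor, int(value))
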