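"""Small shared numeric helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away"]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (the convention used for all
    presented percentages, SEs and CI bounds; Python's builtin ``round``
    rounds ties to even)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
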