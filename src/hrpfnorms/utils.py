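"""Small shared helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed norm tables).

    Python's built-in ``round`` is banker's rounding; published reference
    tables round 0.005 up, so centile cells and band edges use this instead.
    """
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
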