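"""Small shared helpers: significant-figure rounding and p-value formatting."""

from __future__ import annotations

import math


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_p(p: float, decimals: int = 4) -> str:
    """Render a p-value the way mutation-spectrum tables print them.

    Values that round to zero at the requested precision are shown as a
    bound ("< .0001" for 4 decimals); everything else is fixed-point.
    """
    threshold = 0.5 * 10 ** (-decimals)
    if p < threshold:
        return "< ." + "0" * (decimals - 1) + "1"
    return f"{p:.{decimals}f}"
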