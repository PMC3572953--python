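"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures.

    Returns 0.0 for exactly zero input; sign is preserved.
    """
    if x == 0 or not math.isfinite(x):
        return float(x)
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + digits - 1)


def format_sig(x: float, digits: int = 2) -> str:
    """Render ``x`` at ``digits`` significant figures, scientific for small values.

    Matches the reporting style used for p-values in the output tables,
    e.g. ``format_sig(1.0563e-4)`` -> ``'1.1e-04'`` and
    ``format_sig(4.175)`` -> ``'4.2'``.
    """
    if x == 0:
        return "0"
    if not math.isfinite(x):
        return str(x)
    if 0.01 <= abs(x) < 1000:
        return f"{x:.{digits}g}"
    return f"{x:.{digits - 1}e}"
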