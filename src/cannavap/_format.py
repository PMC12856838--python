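"""Rounding and display conventions for reported quantities.

Reports round pressures to two significant figures, enthalpies to one
decimal, phase fractions to two decimals, and heat-capacity changes to the
nearest integer; full-precision values always travel alongside in JSON.
"""

from __future__ import annotations

import math

__all__ = ["round_sig", "format_pressure", "format_enthalpy", "format_fraction"]


def round_sig(x: float, n_digits: int = 2) -> float:
    """Round to ``n_digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    decimals = n_digits - 1 - math.floor(math.log10(abs(x)))
    return round(x, decimals)


def format_pressure(p: float) -> str:
    """Pressure at two significant figures in scientific notation."""
    return f"{round_sig(p, 2):.1e}"


def format_enthalpy(h: float) -> str:
    return f"{h:.1f}"


def format_fraction(f: float) -> str:
    return f"{f:.2f}"
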