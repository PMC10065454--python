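"""Small shared helpers (presentation rounding)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["round_half_up", "round_frame"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Head counts and money are carried as reals through the pipeline and
    only rounded at report time; conventional half-up rounding (not
    banker's) is used so that e.g. 366.5 young rams reports as 367.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_frame(frame: pd.DataFrame, ndigits: int = 0, columns: list[str] | None = None) -> pd.DataFrame:
    """Half-up round selected numeric columns of a report table.

    With ``ndigits=0`` the result columns become integers.
    """
    out = frame.copy()
    cols = columns if columns is not None else [
        c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])
    ]
    for c in cols:
        rounded = out[c].map(lambda v: round_half_up(v, ndigits))
        out[c] = rounded.astype(int) if ndigits == 0 else rounded
    return out
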