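"""Small shared helpers: half-up rounding and FAERS date handling."""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed report tables).

    numpy/python banker's rounding would send 0.05 -> 0.0; printed
    percentages in regulatory tables use half-up.
    """
    x = float(x)
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """count/total as a half-up-rounded percentage; 0.0 when total == 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


# FAERS dates are plain digit strings: YYYYMMDD, YYYYMM or YYYY.
_PRECISION_BY_LEN = {8: "day", 6: "month", 4: "year"}


def date_precision(s: object) -> str | None:
    """'day' / 'month' / 'year' for a FAERS date string, None if unusable."""
    if s is None or (isinstance(s, float) and s != s):
        return None
    t = str(s).strip()
    if not t.isdigit():
        return None
    return _PRECISION_BY_LEN.get(len(t))


def date_sort_key(s: object) -> int:
    """Integer ordering key for a possibly partial FAERS date.

    Partial dates are padded to their earliest day (YYYYMM -> YYYYMM01,
    YYYY -> YYYY0101) so they remain usable for deduplication ordering.
    Unparseable dates sort first (key 0).
    """
    p = date_precision(s)
    if p is None:
        return 0
    t = str(s).strip()
    if p == "month":
        t += "01"
    elif p == "year":
        t += "0101"
    return int(t)


def parse_full_date(s: object) -> _dt.date | None:
    """A datetime.date for a full-precision YYYYMMDD string, else None."""
    if date_precision(s) != "day":
        return None
    t = str(s).strip()
    try:
        return _dt.date(int(t[:4]), int(t[4:6]), int(t[6:8]))
    except ValueError:
        return None


_EPOCH_ORDINAL = _dt.date(1970, 1, 1).toordinal()


def dates_to_strings(ordinals: np.ndarray) -> np.ndarray:
    """Vector of proleptic ordinals -> YYYYMMDD strings (vectorized)."""
    ords = np.asarray(ordinals, dtype=np.int64)
    days = ords - _EPOCH_ORDINAL
    dt = pd.to_datetime(days * 86_400_000_000_000)  # ns since epoch
    num = (dt.year * 10_000 + dt.month * 100 + dt.day).to_numpy()
    out = num.astype("U8").astype(object)
    out[ords <= 0] = ""
    return out


def map_uniques(s: pd.Series, func, dtype=object, na_value=None) -> np.ndarray:
    """Apply a scalar function once per unique value of a Series.

    Spontaneous-report columns (dates, units, codes, drug names) repeat a
    small set of distinct values, so factorize + per-unique evaluation beats
    per-element string methods by an order of magnitude.
    """
    codes, uniques = pd.factorize(s)
    mapped = np.array([func(u) for u in uniques], dtype=dtype)
    out = np.full(len(s), func(na_value) if na_value is not None else func(None),
                  dtype=dtype)
    ok = codes >= 0
    out[ok] = mapped[codes[ok]]
    return out


def date_sort_keys(dates: pd.Series) -> np.ndarray:
    """Vectorized :func:`date_sort_key` over a string Series."""
    return map_uniques(dates, date_sort_key, dtype=np.int64)
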