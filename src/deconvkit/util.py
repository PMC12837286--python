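"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = ["largest_remainder"]


def largest_remainder(fractions, n: int) -> np.ndarray:
    """Integer apportionment of ``n`` units proportional to ``fractions``.

    Floors the raw quotas, then distributes the remaining units to the
    largest fractional parts; ties broken by position (earlier label wins).
    Fractions need not sum to one — they are renormalized. Always returns
    non-negative integers summing exactly to ``n``.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise DomainError("fractions must be a non-empty 1-D vector")
    if (f < 0).any():
        raise DomainError("fractions must be non-negative")
    total = f.sum()
    if total <= 0:
        raise DomainError("fractions sum to zero")
    raw = f / total * n
    out = np.floor(raw).astype(int)
    remainder = n - int(out.sum())
    if remainder > 0:
        frac_part = raw - out
        # descending fractional part, ties by ascending position
        order = np.lexsort((np.arange(f.size), -frac_part))
        out[order[:remainder]] += 1
    return out
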