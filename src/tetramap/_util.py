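"""Small shared helpers: rounding, map functions, errors."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

MISSING = -1  # integer sentinel for a missing dosage call


class TetramapError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(TetramapError):
    pass


class DomainError(TetramapError):
    """An argument is outside its documented domain."""


class DataError(TetramapError):
    """Input data violate a documented precondition."""


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round to `decimals` places with ties going away from zero.

    Matches how the reported assembly/BUSCO percentages are formatted
    (e.g. 38.29... -> 38.3).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    if denominator == 0:
        raise DomainError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, decimals)


def haldane_cm(r) -> np.ndarray | float:
    """Map a recombination fraction to centimorgans, d = -50*ln(1-2r).

    Assumes no crossover interference. r is clipped just below 0.5 so the
    transform stays finite; such pairs carry ~zero weight downstream anyway.
    """
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.5 - 1e-9)
    out = -50.0 * np.log1p(-2.0 * r)
    return float(out) if out.ndim == 0 else out


def inverse_haldane(d) -> np.ndarray | float:
    d = np.asarray(d, dtype=float)
    out = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(out) if out.ndim == 0 else out


def check_rate(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise InvalidConfigError(f"{name} must be in [0, 1], got {value!r}")
    return value
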