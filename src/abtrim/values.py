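"""Sentinel values for censored and not-determined concentrations.

Bioanalytical concentration tables carry three kinds of cell: a finite
number (nM), a value below the lowest calibration standard (censored at a
known limit), and a value that cannot be determined at all (ND).  ND is a
distinct sentinel — never 0, never a silent NaN — and propagates through
ratios and downstream statistics by exclusion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Union


class NDType:
    """Singleton marker for a not-determined value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ND"

    def __bool__(self) -> bool:
        return False


#: The not-determined sentinel.
ND = NDType()


@dataclass(frozen=True)
class Censored:
    """A concentration below the limit of detection.

    Carries the censoring limit (the lowest calibration standard, in nM)
    so downstream code can reason about the bound without inventing a value.
    """

    limit: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.limit) or self.limit < 0:
            raise ValueError(f"censoring limit must be finite and >= 0, got {self.limit}")


#: A concentration cell: a finite float in nM, Censored, or ND.
Value = Union[float, Censored, NDType]

_CENSORED_RE = re.compile(r"^CENSORED(?P<limit>[0-9.eE+-]+)$")


def is_nd(value: object) -> bool:
    return isinstance(value, NDType)


def is_censored(value: object) -> bool:
    return isinstance(value, Censored)


def is_numeric(value: object) -> bool:
    return isinstance(value, (int, float)) and math.isfinite(value)


def format_value(value: Value) -> str:
    """Render a cell for the tidy-CSV dialect ("NA" / "CENSORED<limit>")."""
    if is_nd(value):
        return "NA"
    if isinstance(value, Censored):
        return f"CENSORED{value.limit:g}"
    if is_numeric(value):
        return f"{float(value):.10g}"
    raise ValueError(f"cannot format {value!r} as a concentration cell")


def parse_value(token: str) -> Value:
    """Parse a cell of the tidy-CSV dialect; inverse of :func:`format_value`."""
    token = token.strip()
    if token in ("NA", "ND", "nd", ""):
        return ND
    match = _CENSORED_RE.match(token)
    if match:
        return Censored(float(match.group("limit")))
    try:
        value = float(token)
    except ValueError as exc:
        raise ValueError(f"unparseable concentration cell: {token!r}") from exc
    if not math.isfinite(value):
        raise ValueError(f"non-finite concentration: {token!r}")
    return value
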