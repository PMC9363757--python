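"""Canonical EEG frequency band definitions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ..core.types import ValidationError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, ``low_hz <= f < high_hz``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValidationError(
                f"band {self.name}: low {self.low_hz} must be < high {self.high_hz}"
            )


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 48.0)

CANONICAL_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}
_ALIASES = {"d": DELTA, "t": THETA, "a": ALPHA, "b": BETA, "g": GAMMA}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name (case-insensitive)."""
    key = name.strip().lower()
    if key in _BY_NAME:
        return _BY_NAME[key]
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValidationError(
        f"unknown band {name!r}; expected one of {sorted(_BY_NAME)}"
    )


def resolve_bands(names: Iterable[str] | str | None) -> tuple[BandDefinition, ...]:
    """Map band names (or 'all'/None) to definitions."""
    if names is None or names == "all":
        return CANONICAL_BANDS
    if isinstance(names, str):
        names = [names]
    return tuple(get_band(n) for n in names)


def channel_pairs(channels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """All unordered distinct channel pairs, first channel earlier in
    montage order; 32 channels give 496 pairs."""
    return tuple(
        (channels[i], channels[j])
        for i in range(len(channels))
        for j in range(i + 1, len(channels))
    )
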