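"""Age-band schemas for abridged life tables.

An :class:`AgeSchema` is an ordered, contiguous set of age bands starting at
age 0 with exactly one open-ended terminal band, plus the per-band separation
fractions ``ax`` (the average number of years lived within a band by those who
die in it) used to convert central death rates into death probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Sentinel width flagging the open-ended terminal band in record files.
OPEN_WIDTH = -1


@dataclass(frozen=True)
class AgeSchema:
    """Ordered age banding with separation fractions.

    Parameters
    ----------
    name:
        Identifier of the schema (used in configs and file metadata).
    lower:
        Band lower bounds in years, contiguous from 0.
    width:
        Band widths in years; ``np.inf`` for the single terminal open band.
    ax:
        Separation fractions in years, one per band.  Must satisfy
        ``0 < ax < width`` for closed bands; the open band's entry is unused
        (its person-years follow the constant-hazard closure ``L = l/m``).
    """

    name: str
    lower: tuple[float, ...]
    width: tuple[float, ...]
    ax: tuple[float, ...]

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        width = np.asarray(self.width, dtype=float)
        ax = np.asarray(self.ax, dtype=float)
        if not (lower.size == width.size == ax.size) or lower.size == 0:
            raise ConfigurationError("age schema: lower, width and ax must have equal, non-zero length")
        if lower[0] != 0:
            raise ConfigurationError("age schema: bands must start at age 0")
        open_mask = np.isinf(width)
        if open_mask.sum() != 1 or not open_mask[-1]:
            raise ConfigurationError("age schema: exactly one open-ended band, and it must be terminal")
        closed_w = width[:-1]
        if np.any(closed_w <= 0):
            raise ConfigurationError("age schema: closed-band widths must be positive")
        if not np.allclose(lower[1:], lower[:-1] + width[:-1]):
            raise ConfigurationError("age schema: bands must be contiguous")
        if np.any(ax[:-1] <= 0) or np.any(ax[:-1] >= closed_w):
            raise ConfigurationError("age schema: need 0 < ax < width for closed bands")

    # -- array views ------------------------------------------------------
    @property
    def n_bands(self) -> int:
        return len(self.lower)

    @property
    def lowers(self) -> np.ndarray:
        return np.asarray(self.lower, dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return np.asarray(self.width, dtype=float)

    @property
    def axs(self) -> np.ndarray:
        return np.asarray(self.ax, dtype=float)

    @property
    def open_lower(self) -> float:
        """Lower bound of the terminal open band."""
        return float(self.lower[-1])

    def width_codes(self) -> np.ndarray:
        """Widths with the open band encoded as :data:`OPEN_WIDTH` (for CSV)."""
        w = self.widths.copy()
        w[-1] = OPEN_WIDTH
        return w


def abridged_5y_schema(open_age: int = 85, a0: float = 0.3, name: str | None = None) -> AgeSchema:
    """The default abridged schema: 0, 1-4, 5-9, ..., (open_age)+.

    The infant band gets ``a0`` (infant deaths concentrate early in the first
    year of life); all other closed bands use the midpoint, width/2.
    """
    if open_age < 10 or open_age % 5 != 0:
        raise ConfigurationError("abridged schema: open_age must be a multiple of 5, >= 10")
    lower = [0.0, 1.0] + [float(x) for x in range(5, open_age + 1, 5)]
    width = [1.0, 4.0] + [5.0] * (open_age // 5 - 1) + [np.inf]
    ax = [a0, 2.0] + [2.5] * (open_age // 5 - 1) + [np.nan]
    return AgeSchema(name or f"abridged_5y_{open_age}", tuple(lower), tuple(width), tuple(ax))


def single_open_band_schema(name: str = "single_open_band") -> AgeSchema:
    """A degenerate schema with one open band from age 0 (e0 = 1/m exactly)."""
    return AgeSchema(name, (0.0,), (np.inf,), (np.nan,))


_REGISTRY = {
    "abridged_5y_85": lambda: abridged_5y_schema(85),
    "abridged_5y_90": lambda: abridged_5y_schema(90),
    "single_open_band": single_open_band_schema,
}


def get_schema(schema_id: str) -> AgeSchema:
    """Look up a named age schema."""
    try:
        return _REGISTRY[schema_id]()
    except KeyError:
        raise ConfigurationError(
            f"unknown age schema {schema_id!r}; known: {sorted(_REGISTRY)}"
        ) from None
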