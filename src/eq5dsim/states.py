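"""EQ-5D health states.

A health state is a response profile on the five EQ-5D dimensions —
mobility (MO), self-care (SC), usual activities (UA), pain/discomfort (PD)
and anxiety/depression (AD) — with 3 response levels per dimension for the
EQ-5D-3L (243 states) or 5 for the EQ-5D-5L (3125 states). States are
written as 5-digit strings in fixed dimension order, e.g. ``"21232"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")
N_DIMENSIONS = 5
LEVELS = {"3L": 3, "5L": 5}
VERSIONS = ("3L", "5L")


class StateError(ValueError):
    """Invalid health-state specification."""


def check_version(version: str) -> str:
    if version not in LEVELS:
        raise StateError(f"unknown EQ-5D version {version!r}; expected one of {VERSIONS}")
    return version


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D response profile.

    Parameters
    ----------
    version : {"3L", "5L"}
    levels : tuple of 5 ints
        Response levels in dimension order MO, SC, UA, PD, AD; each in
        1..3 (3L) or 1..5 (5L).
    """

    version: str
    levels: tuple

    def __post_init__(self):
        check_version(self.version)
        levels = tuple(int(v) for v in self.levels)
        if len(levels) != N_DIMENSIONS:
            raise StateError(f"expected 5 levels, got {len(levels)}")
        top = LEVELS[self.version]
        for dim, lev in zip(DIMENSIONS, levels):
            if not 1 <= lev <= top:
                raise StateError(
                    f"level {lev} on {dim} outside 1..{top} for version {self.version}"
                )
        object.__setattr__(self, "levels", levels)

    @classmethod
    def from_string(cls, version: str, text: str) -> "HealthState":
        text = str(text).strip()
        if len(text) != N_DIMENSIONS or not text.isdigit():
            raise StateError(f"state string must be 5 digits, got {text!r}")
        return cls(version, tuple(int(c) for c in text))

    def to_string(self) -> str:
        return "".join(str(v) for v in self.levels)

    @property
    def index(self) -> int:
        """Position in the canonical enumeration (MO most significant)."""
        base = LEVELS[self.version]
        idx = 0
        for lev in self.levels:
            idx = idx * base + (lev - 1)
        return idx


def n_states(version: str) -> int:
    return LEVELS[check_version(version)] ** N_DIMENSIONS


@lru_cache(maxsize=None)
def enumerate_levels(version: str) -> np.ndarray:
    """All states of a version as an (n_states, 5) int array, canonical order."""
    base = LEVELS[check_version(version)]
    grids = np.meshgrid(*[np.arange(1, base + 1)] * N_DIMENSIONS, indexing="ij")
    arr = np.stack([g.ravel() for g in grids], axis=1)
    arr.setflags(write=False)
    return arr


def levels_to_index(levels: np.ndarray, version: str) -> np.ndarray:
    """Canonical enumeration index for an (n, 5) array of levels."""
    base = LEVELS[check_version(version)]
    levels = np.asarray(levels)
    weights = base ** np.arange(N_DIMENSIONS - 1, -1, -1)
    return (levels - 1) @ weights


def validate_levels(levels: np.ndarray, version: str) -> np.ndarray:
    base = LEVELS[check_version(version)]
    levels = np.asarray(levels, dtype=int)
    if levels.ndim != 2 or levels.shape[1] != N_DIMENSIONS:
        raise StateError("levels must be an (n, 5) array")
    if levels.min(initial=1) < 1 or levels.max(initial=1) > base:
        bad = levels[(levels < 1).any(axis=1) | (levels > base).any(axis=1)][0]
        raise StateError(f"state {''.join(map(str, bad))} invalid for version {version}")
    return levels


def strings_to_levels(strings, version: str) -> np.ndarray:
    """Parse an iterable of 5-digit state strings into an (n, 5) level array."""
    arr = np.array([[int(c) for c in str(s).strip()] for s in strings], dtype=int)
    if arr.size == 0:
        arr = arr.reshape(0, N_DIMENSIONS)
    return validate_levels(arr, version)


def levels_to_strings(levels: np.ndarray) -> list:
    return ["".join(str(int(v)) for v in row) for row in np.asarray(levels)]
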