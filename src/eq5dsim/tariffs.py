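"""EQ-5D value sets (tariffs) as declarative data.

A tariff converts a health state into a utility anchored at 1 (full health)
and 0 (dead); utilities below zero describe states valued worse than dead.
Published value sets are additive models over per-level decrements plus, in
some countries, structural terms: an "any dysfunction" constant, an N3-style
indicator (any dimension at the worst level), or count-based interaction
terms. All of these are expressed here through a small indicator language so
that no country needs its own code path:

``level_dummy(dim, level)``
    1 when the state has exactly that response level on that dimension.
``any_level_ge(k)``
    1 when any dimension is at level >= k.
``count_levels_ge(k, offset)``
    max(0, #{dimensions at level >= k} - offset).
``square_of_count(k, offset)``
    the square of the count above.

The utility of a state is ``full_health_value - sum(coef * indicator)``.

The tariff tables shipped under ``data/tariffs`` are *synthetic*
reconstructions (see each file's ``notes``): they mirror the structure of the
Dutch, US and Japanese value sets and reproduce the well-known anchor
decrements exactly, but the remaining coefficients are plausible inventions,
not the published ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .states import (
    DIMENSIONS,
    LEVELS,
    HealthState,
    check_version,
    enumerate_levels,
    validate_levels,
)

INDICATORS = ("level_dummy", "any_level_ge", "count_levels_ge", "square_of_count")

#: Equality tolerance for utilities (coefficients are printed decimals).
UTILITY_TOL = 1e-9


class TariffError(ValueError):
    """Malformed tariff definition."""


class TermNotFoundError(KeyError):
    """No main-effect decrement exists for the requested (dimension, level)."""


@dataclass(frozen=True)
class TariffTerm:
    """One additive term of a value set.

    ``coefficient`` is the utility decrement applied when the indicator
    fires (negative coefficients add utility back, as in count-based
    interaction models). ``coefficient_str`` preserves the printed decimal
    for bit-exact file round-trips.
    """

    indicator: str
    coefficient: float
    dimension: str = None
    level: int = None
    offset: int = 0
    coefficient_str: str = None

    def __post_init__(self):
        if self.indicator not in INDICATORS:
            raise TariffError(f"unknown indicator {self.indicator!r}")
        if self.indicator == "level_dummy":
            if self.dimension not in DIMENSIONS:
                raise TariffError(f"level_dummy needs a dimension, got {self.dimension!r}")
        elif self.dimension is not None:
            raise TariffError(f"{self.indicator} takes no dimension")
        if self.level is None:
            raise TariffError(f"{self.indicator} needs a level threshold")
        if self.coefficient_str is None:
            object.__setattr__(self, "coefficient_str", repr(float(self.coefficient)))

    def key(self):
        return (self.indicator, self.dimension, self.level, self.offset)

    def evaluate(self, levels: np.ndarray) -> np.ndarray:
        """Indicator value on an (n, 5) level array; non-negative by design."""
        if self.indicator == "level_dummy":
            d = DIMENSIONS.index(self.dimension)
            return (levels[:, d] == self.level).astype(float)
        count = (levels >= self.level).sum(axis=1)
        if self.indicator == "any_level_ge":
            return (count > 0).astype(float)
        clipped = np.maximum(0, count - self.offset).astype(float)
        if self.indicator == "count_levels_ge":
            return clipped
        return clipped**2  # square_of_count


@dataclass
class Tariff:
    """A value set: country label, EQ-5D version, and additive terms."""

    country: str
    version: str
    terms: list
    full_health_value: float = 1.0
    range: tuple = None
    notes: str = ""
    _table: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        check_version(self.version)
        top = LEVELS[self.version]
        seen = set()
        for term in self.terms:
            if not 1 <= term.level <= top:
                raise TariffError(
                    f"term level {term.level} outside 1..{top} for {self.version} tariff"
                )
            if term.key() in seen:
                raise TariffError(f"duplicate term {term.key()}")
            seen.add(term.key())
        table = self.utility_table()
        if abs(table[0] - self.full_health_value) > UTILITY_TOL:
            raise TariffError(
                f"full health scores {table[0]!r}, declared {self.full_health_value!r}"
            )
        lo, hi = float(table.min()), float(table.max())
        if self.range is None:
            self.range = (lo, hi)
        else:
            self.range = (float(self.range[0]), float(self.range[1]))
            if lo < self.range[0] - UTILITY_TOL or hi > self.range[1] + UTILITY_TOL:
                raise TariffError(
                    f"scored utilities span [{lo}, {hi}], outside declared range {self.range}"
                )

    # -- scoring -----------------------------------------------------------

    def utilities(self, levels: np.ndarray) -> np.ndarray:
        """Score an (n, 5) level array."""
        levels = validate_levels(levels, self.version)
        u = np.full(len(levels), float(self.full_health_value))
        for term in self.terms:
            u -= term.coefficient * term.evaluate(levels)
        return u

    def utility_table(self) -> np.ndarray:
        """Utilities of every state of this version, canonical order (cached)."""
        if self._table is None:
            levels = enumerate_levels(self.version)
            u = np.full(len(levels), float(self.full_health_value))
            for term in self.terms:
                u -= term.coefficient * term.evaluate(levels)
            self._table = u
        return self._table

    def score(self, state) -> float:
        """Utility of one state (HealthState or 5-digit string)."""
        if isinstance(state, str):
            state = HealthState.from_string(self.version, state)
        if state.version != self.version:
            raise TariffError(
                f"state is {state.version} but tariff {self.country} is {self.version}"
            )
        return float(self.utilities(np.array([state.levels]))[0])

    def decrement(self, dimension: str, level: int) -> float:
        """Main-effect decrement (level_dummy coefficient) for a response level."""
        for term in self.terms:
            if (
                term.indicator == "level_dummy"
                and term.dimension == dimension
                and term.level == int(level)
            ):
                return float(term.coefficient)
        raise TermNotFoundError(
            f"no main-effect term for {dimension} level {level} in {self.country} "
            f"{self.version} tariff"
        )


def score_state(state, tariff: Tariff) -> float:
    return tariff.score(state)


def get_decrement(tariff: Tariff, dimension: str, level: int) -> float:
    return tariff.decrement(dimension, level)


# -- serialisation ---------------------------------------------------------


def _term_to_dict(term: TariffTerm) -> dict:
    d = {"indicator": term.indicator, "coefficient": term.coefficient_str}
    if term.dimension is not None:
        d["dimension"] = term.dimension
    d["level"] = term.level
    if term.offset:
        d["offset"] = term.offset
    return d


def _term_from_dict(row: dict, index: int) -> TariffTerm:
    try:
        coef_str = str(row["coefficient"])
        return TariffTerm(
            indicator=row["indicator"],
            coefficient=float(coef_str),
            dimension=row.get("dimension"),
            level=int(row["level"]),
            offset=int(row.get("offset", 0)),
            coefficient_str=coef_str,
        )
    except (KeyError, ValueError, TypeError, TariffError) as exc:
        raise TariffError(f"bad tariff term at row {index}: {row!r} ({exc})") from exc


def tariff_from_dict(doc: dict) -> Tariff:
    for key in ("country", "version", "terms"):
        if key not in doc:
            raise TariffError(f"tariff file missing {key!r}")
    terms = [_term_from_dict(row, i) for i, row in enumerate(doc["terms"])]
    rng = doc.get("range")
    return Tariff(
        country=str(doc["country"]),
        version=str(doc["version"]),
        terms=terms,
        full_health_value=float(doc.get("full_health_value", 1.0)),
        range=(float(rng["min"]), float(rng["max"])) if rng else None,
        notes=str(doc.get("notes", "")),
    )


def load_tariff(path) -> Tariff:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TariffError(f"{path}: not a tariff document")
    return tariff_from_dict(doc)


def write_tariff(tariff: Tariff, path) -> None:
    doc = {
        "country": tariff.country,
        "version": tariff.version,
        "full_health_value": float(tariff.full_health_value),
        "range": {"min": float(tariff.range[0]), "max": float(tariff.range[1])},
        "notes": tariff.notes,
        "terms": [_term_to_dict(t) for t in tariff.terms],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- embedded value sets ---------------------------------------------------

BUILTIN_COUNTRIES = ("NL", "US", "JP")
_BUILTIN_FILES = {
    (c, v): f"{c.lower()}_{v.lower()}_synthetic.yaml"
    for c in BUILTIN_COUNTRIES
    for v in ("3L", "5L")
}
_builtin_cache = {}


def builtin_tariff(country: str, version: str) -> Tariff:
    """One of the six embedded (synthetic-reconstruction) value sets."""
    key = (country.upper(), version.upper())
    if key not in _BUILTIN_FILES:
        raise TariffError(
            f"no embedded tariff for {country}/{version}; have "
            f"{sorted(_BUILTIN_FILES)}"
        )
    if key not in _builtin_cache:
        ref = resources.files("eq5dsim.data.tariffs").joinpath(_BUILTIN_FILES[key])
        with resources.as_file(ref) as path:
            _builtin_cache[key] = load_tariff(path)
    return _builtin_cache[key]


def resolve_tariff(spec: str) -> Tariff:
    """Resolve ``"NL-3L"`` style builtin ids or a file path to a Tariff."""
    text = str(spec)
    parts = text.replace("_", "-").split("-")
    if len(parts) == 2 and parts[0].upper() in BUILTIN_COUNTRIES:
        return builtin_tariff(parts[0], parts[1])
    return load_tariff(text)


def main_effects_only(tariff: Tariff) -> Tariff:
    """Copy of a tariff with every non-level_dummy (interaction) term removed."""
    terms = [t for t in tariff.terms if t.indicator == "level_dummy"]
    return replace(tariff, terms=terms, range=None, _table=None)
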