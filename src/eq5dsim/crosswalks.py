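"""Crosswalks between EQ-5D versions.

A crosswalk assigns, to each state of one EQ-5D version, a utility on the
value-set scale of the other version (5L states valued on a 3L tariff, or
3L states on a 5L tariff). The model here carries per-dimension row-
stochastic transition matrices P_d(target level | source level); under
cross-dimension independence the crosswalked utility of a source state s is

    E[u] = sum over target states t of  prod_d P_d(t_d | s_d) * u_tariff(t)

As an escape hatch for published state-to-index tables, a model may also
carry a full lookup ``{country: {state string: utility}}``; when a lookup
covers the target tariff's country it takes precedence over the matrices.

The matrices shipped under ``data/crosswalks`` are synthetic stand-ins with
the qualitative shape of the published 5L<->3L crosswalks (adjacent-level
mass, deterministic endpoints), not the published tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .states import (
    DIMENSIONS,
    LEVELS,
    HealthState,
    enumerate_levels,
    levels_to_index,
    levels_to_strings,
    n_states,
    validate_levels,
)
from .tariffs import Tariff

ROW_SUM_TOL = 1e-9

DIRECTIONS = {"5L_to_3L": ("5L", "3L"), "3L_to_5L": ("3L", "5L")}


class CrosswalkError(ValueError):
    """Malformed or inconsistent crosswalk specification."""


@dataclass
class CrosswalkModel:
    """Per-dimension transition matrices and/or a full state lookup."""

    direction: str
    matrices: np.ndarray = None  # (5, n_source_levels, n_target_levels)
    lookup: dict = None  # {country: {state string: utility}}
    notes: str = ""
    _mapping: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise CrosswalkError(
                f"direction must be one of {sorted(DIRECTIONS)}, got {self.direction!r}"
            )
        src, tgt = DIRECTIONS[self.direction]
        if self.matrices is not None:
            m = np.asarray(self.matrices, dtype=float)
            expect = (5, LEVELS[src], LEVELS[tgt])
            if m.shape != expect:
                raise CrosswalkError(f"matrices shape {m.shape}, expected {expect}")
            if (m < -ROW_SUM_TOL).any():
                raise CrosswalkError("negative transition probability")
            sums = m.sum(axis=2)
            if np.abs(sums - 1.0).max() > ROW_SUM_TOL:
                d, s = np.unravel_index(np.abs(sums - 1.0).argmax(), sums.shape)
                raise CrosswalkError(
                    f"row {DIMENSIONS[d]} source level {s + 1} sums to {sums[d, s]!r}"
                )
            self.matrices = m
        if self.lookup is not None:
            want = n_states(src)
            for country, table in self.lookup.items():
                if len(table) != want:
                    missing = self._missing_states(table, src)
                    raise CrosswalkError(
                        f"lookup for {country} covers {len(table)} of {want} source "
                        f"states; first missing: {missing[0] if missing else '?'}"
                    )
        if self.matrices is None and self.lookup is None:
            raise CrosswalkError("crosswalk needs matrices and/or a lookup table")

    @staticmethod
    def _missing_states(table, version):
        all_states = set(levels_to_strings(enumerate_levels(version)))
        return sorted(all_states - set(table))

    @property
    def source_version(self) -> str:
        return DIRECTIONS[self.direction][0]

    @property
    def target_version(self) -> str:
        return DIRECTIONS[self.direction][1]

    def mapping_matrix(self) -> np.ndarray:
        """Joint (n_source_states, n_target_states) transition matrix.

        Kronecker product of the five per-dimension matrices, in canonical
        state order (MO most significant).
        """
        if self.matrices is None:
            raise CrosswalkError("no transition matrices loaded")
        if self._mapping is None:
            m = self.matrices[0]
            for d in range(1, 5):
                m = np.kron(m, self.matrices[d])
            self._mapping = m
        return self._mapping

    def expected_utilities(self, tariff: Tariff) -> np.ndarray:
        """Matrix-derived crosswalked utility of every source state."""
        self._check_target(tariff)
        return self.mapping_matrix() @ tariff.utility_table()

    def _check_target(self, tariff: Tariff):
        if tariff.version != self.target_version:
            raise CrosswalkError(
                f"crosswalk {self.direction} needs a {self.target_version} target "
                f"tariff, got {tariff.country} {tariff.version}"
            )

    def utilities(self, levels: np.ndarray, tariff: Tariff) -> np.ndarray:
        """Crosswalked utilities for an (n, 5) array of source-version levels."""
        self._check_target(tariff)
        levels = validate_levels(levels, self.source_version)
        if self.lookup and tariff.country in self.lookup:
            table = self.lookup[tariff.country]
            return np.array([table[s] for s in levels_to_strings(levels)])
        idx = levels_to_index(levels, self.source_version)
        return self.expected_utilities(tariff)[idx]


def crosswalk_utility(state, model: CrosswalkModel, target_tariff: Tariff) -> float:
    """Crosswalked utility of one source state (HealthState or string)."""
    if isinstance(state, str):
        state = HealthState.from_string(model.source_version, state)
    if state.version != model.source_version:
        raise CrosswalkError(
            f"state is {state.version} but crosswalk maps from {model.source_version}"
        )
    return float(model.utilities(np.array([state.levels]), target_tariff)[0])


@dataclass
class ConsistencyReport:
    """Per-country diff between matrix-derived utilities and a lookup table."""

    max_abs_diff: float
    mean_abs_diff: float
    n_states: int
    violations: dict  # {country: [(state, matrix value, lookup value), ...]}

    @property
    def n_violations(self) -> int:
        return sum(len(v) for v in self.violations.values())


def consistency_check(
    model: CrosswalkModel, target_tariff: Tariff, tolerance: float = 1e-6
) -> ConsistencyReport:
    """Compare the independence-model utilities against the loaded lookup."""
    if model.matrices is None or not model.lookup:
        raise CrosswalkError("consistency check needs both matrices and a lookup")
    expected = model.expected_utilities(target_tariff)
    strings = levels_to_strings(enumerate_levels(model.source_version))
    diffs, violations = [], {}
    for country, table in model.lookup.items():
        if country != target_tariff.country:
            continue
        vals = np.array([table[s] for s in strings])
        d = np.abs(vals - expected)
        diffs.append(d)
        bad = np.nonzero(d > tolerance)[0]
        violations[country] = [(strings[i], float(expected[i]), float(vals[i])) for i in bad]
    if not diffs:
        raise CrosswalkError(f"lookup has no entry for country {target_tariff.country!r}")
    alld = np.concatenate(diffs)
    return ConsistencyReport(
        max_abs_diff=float(alld.max()),
        mean_abs_diff=float(alld.mean()),
        n_states=len(strings),
        violations=violations,
    )


# -- file formats ----------------------------------------------------------


def load_crosswalk(path) -> CrosswalkModel:
    """Load a transition-matrix CSV (``dimension,source_level,target_level,
    probability`` with an optional ``# direction:`` comment line)."""
    direction, rows, notes = None, [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("direction:"):
                    direction = body.split(":", 1)[1].strip()
                else:
                    notes.append(body)
                continue
            rows.append(line)
    reader = csv.DictReader(rows)
    needed = {"dimension", "source_level", "target_level", "probability"}
    if reader.fieldnames is None or not needed <= set(reader.fieldnames):
        raise CrosswalkError(f"{path}: expected columns {sorted(needed)}")
    entries = []
    for i, row in enumerate(reader):
        try:
            entries.append(
                (
                    row["dimension"],
                    int(row["source_level"]),
                    int(row["target_level"]),
                    float(row["probability"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CrosswalkError(f"{path}: bad row {i + 2}: {row!r} ({exc})") from exc
    if not entries:
        raise CrosswalkError(f"{path}: no transition rows")
    if direction is None:
        src_max = max(e[1] for e in entries)
        tgt_max = max(e[2] for e in entries)
        direction = "5L_to_3L" if src_max > tgt_max else "3L_to_5L"
    if direction not in DIRECTIONS:
        raise CrosswalkError(f"{path}: unknown direction {direction!r}")
    src, tgt = DIRECTIONS[direction]
    mats = np.zeros((5, LEVELS[src], LEVELS[tgt]))
    for dim, s, t, p in entries:
        if dim not in DIMENSIONS:
            raise CrosswalkError(f"{path}: unknown dimension {dim!r}")
        if not (1 <= s <= LEVELS[src] and 1 <= t <= LEVELS[tgt]):
            raise CrosswalkError(f"{path}: levels ({s},{t}) outside {direction} shape")
        mats[DIMENSIONS.index(dim), s - 1, t - 1] = p
    return CrosswalkModel(direction=direction, matrices=mats, notes=" ".join(notes))


def write_crosswalk(model: CrosswalkModel, path) -> None:
    if model.matrices is None:
        raise CrosswalkError("nothing to write: model has no matrices")
    src, tgt = DIRECTIONS[model.direction]
    with open(path, "w", newline="") as fh:
        fh.write(f"# direction: {model.direction}\n")
        if model.notes:
            fh.write(f"# {model.notes}\n")
        writer = csv.writer(fh)
        writer.writerow(["dimension", "source_level", "target_level", "probability"])
        for d, dim in enumerate(DIMENSIONS):
            for s in range(LEVELS[src]):
                for t in range(LEVELS[tgt]):
                    writer.writerow([dim, s + 1, t + 1, repr(float(model.matrices[d, s, t]))])


def load_lookup(path, direction: str) -> dict:
    """Load a ``state,country,utility`` lookup CSV into {country: {state: u}}."""
    lookup = {}
    with open(path) as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        needed = {"state", "country", "utility"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise CrosswalkError(f"{path}: expected columns {sorted(needed)}")
        for i, row in enumerate(reader):
            try:
                lookup.setdefault(row["country"], {})[str(row["state"]).strip()] = float(
                    row["utility"]
                )
            except (ValueError, TypeError) as exc:
                raise CrosswalkError(f"{path}: bad row {i + 2}: {row!r} ({exc})") from exc
    src = DIRECTIONS[direction][0]
    want = n_states(src)
    for country, table in lookup.items():
        if len(table) != want:
            missing = CrosswalkModel._missing_states(table, src)
            raise CrosswalkError(
                f"{path}: lookup for {country} covers {len(table)}/{want} states; "
                f"first missing: {missing[0] if missing else '?'}"
            )
    return lookup


def write_lookup(model: CrosswalkModel, tariffs, path) -> None:
    """Materialise the independence-model utilities as a lookup CSV."""
    strings = levels_to_strings(enumerate_levels(model.source_version))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["state", "country", "utility"])
        for tariff in tariffs:
            utils = model.expected_utilities(tariff)
            for s, u in zip(strings, utils):
                writer.writerow([s, tariff.country, repr(float(u))])


_BUILTIN_FILES = {
    "5L_to_3L": "xw_5l_to_3l_synthetic.csv",
    "3L_to_5L": "xw_3l_to_5l_synthetic.csv",
}
_builtin_cache = {}


def builtin_crosswalk(direction: str) -> CrosswalkModel:
    """Embedded synthetic crosswalk for a direction."""
    if direction not in _BUILTIN_FILES:
        raise CrosswalkError(f"no embedded crosswalk for direction {direction!r}")
    if direction not in _builtin_cache:
        ref = resources.files("eq5dsim.data.crosswalks").joinpath(_BUILTIN_FILES[direction])
        with resources.as_file(ref) as p:
            _builtin_cache[direction] = load_crosswalk(p)
    return _builtin_cache[direction]
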