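"""Keyed parameter storage with a defaulting hierarchy.

Parameters are stored under ``(mechanism, part_id, name)`` keys, where
``mechanism`` and ``part_id`` may be unspecified (``None``).  Lookup walks a
fixed most-specific-to-least-specific search order, so sparse "ball-park"
parameter sets (often just a handful of global defaults) can drive full
compilation and be refined later without touching the model:

1. ``(mechanism instance name, part_id, name)``
2. ``(mechanism type,          part_id, name)``
3. ``(None,                    part_id, name)``
4. ``(mechanism instance name, None,    name)``
5. ``(mechanism type,          None,    name)``
6. ``(None,                    None,    name)``

Part-specific entries beat mechanism-specific ones, which beat the global
default.  Every successful resolution reports (and logs) which key matched
so that defaulted values can be audited.

Parameter files are UTF-8 delimited text (tab or comma, auto-detected) with
header columns ``mechanism``, ``part_id``, ``param_name``, ``value``; blank
cells mean "unspecified" and ``#`` lines are comments.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .core import CRNForgeError

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterKey",
    "ParameterEntry",
    "ParameterDatabase",
    "MissingParameterError",
    "ParameterFileError",
    "search_keys",
    "find_parameter",
    "load_parameter_file",
    "write_parameter_file",
]

REQUIRED_COLUMNS = ("mechanism", "part_id", "param_name", "value")


@dataclass(frozen=True)
class ParameterKey:
    """(mechanism, part_id, name) triple; None fields mean "unspecified"."""

    mechanism: str | None
    part_id: str | None
    name: str

    def __post_init__(self):
        if not self.name:
            raise CRNForgeError("parameter name must be non-empty")

    def __str__(self):
        m = self.mechanism if self.mechanism is not None else "*"
        p = self.part_id if self.part_id is not None else "*"
        return f"(mechanism={m}, part_id={p}, name={self.name})"


@dataclass(frozen=True)
class ParameterEntry:
    key: ParameterKey
    value: float
    provenance: str = ""

    def __post_init__(self):
        value = float(self.value)
        if not math.isfinite(value):
            raise CRNForgeError(f"parameter {self.key} has non-finite value {value}")
        object.__setattr__(self, "value", value)


class MissingParameterError(CRNForgeError, KeyError):
    """No database key matched; carries the full attempted key sequence."""

    def __init__(self, name: str, attempted: Iterable[ParameterKey]):
        self.name = name
        self.attempted = list(attempted)
        keys = "; ".join(str(k) for k in self.attempted)
        super().__init__(
            f"no parameter found for {name!r}; attempted keys in order: {keys}"
        )

    def __str__(self):
        return self.args[0]


class ParameterFileError(CRNForgeError):
    """Malformed parameter file (carries a row number where possible)."""


class ParameterDatabase:
    """Mapping of :class:`ParameterKey` to :class:`ParameterEntry`.

    Accepts shorthand on construction: ``{"kb": 100}`` stores a global
    default key, ``{("mech", "part", "kb"): 100}`` a fully specified one.
    Lookups never mutate the database.
    """

    def __init__(self, entries: Mapping | Iterable[ParameterEntry] | None = None,
                 provenance: str = ""):
        self._entries: dict[ParameterKey, ParameterEntry] = {}
        if entries is None:
            return
        if isinstance(entries, Mapping):
            for key, value in entries.items():
                self.add(key, value, provenance=provenance, warn_override=False)
        else:
            for entry in entries:
                self.add_entry(entry, warn_override=False)

    @staticmethod
    def _as_key(key) -> ParameterKey:
        if isinstance(key, ParameterKey):
            return key
        if isinstance(key, str):
            return ParameterKey(None, None, key)
        if isinstance(key, tuple) and len(key) == 3:
            mech, part, name = key
            return ParameterKey(mech or None, part or None, name)
        raise CRNForgeError(f"cannot interpret parameter key {key!r}")

    def add(self, key, value: float, provenance: str = "",
            warn_override: bool = True) -> ParameterEntry:
        entry = ParameterEntry(self._as_key(key), value, provenance)
        return self.add_entry(entry, warn_override=warn_override)

    def add_entry(self, entry: ParameterEntry, warn_override: bool = True) -> ParameterEntry:
        if warn_override and entry.key in self._entries:
            old = self._entries[entry.key]
            logger.warning(
                "parameter %s overridden: %g -> %g (%s)",
                entry.key, old.value, entry.value, entry.provenance or "unspecified",
            )
        self._entries[entry.key] = entry
        return entry

    def update(self, other: "ParameterDatabase") -> None:
        for entry in other:
            self.add_entry(entry)

    def get(self, key) -> ParameterEntry | None:
        return self._entries.get(self._as_key(key))

    def __contains__(self, key) -> bool:
        return self._as_key(key) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ParameterEntry]:
        return iter(list(self._entries.values()))

    def __repr__(self):
        return f"ParameterDatabase({len(self._entries)} entries)"

    def find(self, name: str, mechanism_name: str | None = None,
             mechanism_type: str | None = None, part_id: str | None = None):
        """Resolve *name* through the defaulting hierarchy.

        Returns ``(value, matched_key)``; raises
        :class:`MissingParameterError` naming every attempted key.
        """
        return find_parameter(self, mechanism_name, mechanism_type, part_id, name)


def search_keys(mechanism_name: str | None, mechanism_type: str | None,
                part_id: str | None, name: str) -> list[ParameterKey]:
    """The attempted key sequence, most specific first.

    Unspecified context fields collapse tiers (e.g. with no mechanism name
    tier 1 *is* tier 3); a collapsed key keeps its least-specific position
    so that genuinely more specific keys are still tried first.
    """
    raw = [
        ParameterKey(mechanism_name, part_id, name),
        ParameterKey(mechanism_type, part_id, name),
        ParameterKey(None, part_id, name),
        ParameterKey(mechanism_name, None, name),
        ParameterKey(mechanism_type, None, name),
        ParameterKey(None, None, name),
    ]
    deduped: list[ParameterKey] = []
    for key in reversed(raw):
        if key not in deduped:
            deduped.append(key)
    return deduped[::-1]


def find_parameter(db: ParameterDatabase, mechanism_name: str | None,
                   mechanism_type: str | None, part_id: str | None,
                   name: str) -> tuple[float, ParameterKey]:
    """First hit in the fixed search order; see module docstring for tiers."""
    if not name:
        raise CRNForgeError("parameter name must be non-empty")
    attempted = search_keys(mechanism_name, mechanism_type, part_id, name)
    for key in attempted:
        entry = db.get(key)
        if entry is not None:
            logger.debug("parameter %s resolved via %s = %g", name, key, entry.value)
            return entry.value, key
    raise MissingParameterError(name, attempted)


# ---------------------------------------------------------------------------
# Delimited-text parameter files
# ---------------------------------------------------------------------------

def _detect_delimiter(text: str) -> str:
    for line in text.splitlines():
        if line.strip() and not line.lstrip().startswith("#"):
            return "\t" if "\t" in line else ","
    return "\t"


def load_parameter_file(path) -> ParameterDatabase:
    """Load a delimited parameter file into a fresh database.

    One entry per data row; later rows override earlier duplicates with a
    warning.  Blank mechanism/part cells become unspecified key fields.
    Malformed or non-numeric rows raise with their row number.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delimiter = _detect_delimiter(text)
    # keep original line numbers by filtering comments but tracking offsets
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append((lineno, line))
    if not rows:
        raise ParameterFileError(f"{path}: no header row found")
    header_line = rows[0][1]
    header = next(csv.reader(io.StringIO(header_line), delimiter=delimiter))
    header = [h.strip() for h in header]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ParameterFileError(
            f"{path}: missing required column(s) {missing}; found {header}"
        )
    idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
    db = ParameterDatabase()
    for lineno, line in rows[1:]:
        cells = next(csv.reader(io.StringIO(line), delimiter=delimiter))
        if len(cells) != len(header):
            raise ParameterFileError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
            )
        cells = [c.strip() for c in cells]
        raw_value = cells[idx["value"]]
        try:
            value = float(raw_value)
        except ValueError:
            raise ParameterFileError(
                f"{path}:{lineno}: non-numeric value {raw_value!r}"
            ) from None
        key = ParameterKey(
            cells[idx["mechanism"]] or None,
            cells[idx["part_id"]] or None,
            cells[idx["param_name"]],
        )
        if not key.name:
            raise ParameterFileError(f"{path}:{lineno}: empty param_name")
        db.add(key, value, provenance=f"{path.name}:{lineno}")
    return db


def write_parameter_file(db: ParameterDatabase, path, delimiter: str = "\t") -> None:
    """Write *db* back out; round-trips with :func:`load_parameter_file`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for entry in db:
            writer.writerow([
                entry.key.mechanism or "",
                entry.key.part_id or "",
                entry.key.name,
                repr(entry.value),
            ])
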