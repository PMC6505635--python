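"""Parsing and expansion of ``sample_attribute`` annotation strings.

SRA stores per-sample annotations (cell line, tissue, strain, treatment...)
as a single semi-structured string of ``" || "``-separated ``"key: value"``
pairs, e.g.::

    source_name: PC3 human prostate cancer cells || cell line: PC3

:func:`parse_attributes` turns such a string into an ordered, normalized
key→value mapping; :func:`expand_table` lifts the mapping into separate
table columns so downstream tools see structured metadata.

Normalization is lossy by design and matches what users expect to grep for:
keys are lowercased with internal whitespace runs collapsed to a single
underscore (``"cell line"`` → ``cell_line``); values are lowercased with
whitespace collapsed to single spaces (``"polyA RNA"`` → ``"polya rna"``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .errors import UsageError
from .table import MetadataTable

logger = logging.getLogger(__name__)

#: pair separator: the two-character token, with optional surrounding space.
#: A lone ``|`` inside a value is preserved.
_PAIR_SPLIT = re.compile(r"\s*\|\|\s*")
_WS = re.compile(r"\s+")

#: suffix applied when an attribute key collides with an existing column name
COLLISION_SUFFIX = "_attr"


@dataclass(frozen=True)
class SampleAttributes:
    """Ordered, normalized key→value pairs parsed from a raw attribute string."""

    pairs: tuple[tuple[str, str], ...]

    def keys(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.pairs)

    def get(self, key: str, default: str = "") -> str:
        for k, v in self.pairs:
            if k == key:
                return v
        return default

    def serialize(self) -> str:
        """Re-serialize as ``"k: v || k: v"`` (a fixed point of parsing)."""
        return " || ".join(f"{k}: {v}" for k, v in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def normalize_key(key: str) -> str:
    return _WS.sub("_", key.strip().lower())


def normalize_value(value: str) -> str:
    return _WS.sub(" ", value.strip().lower())


def parse_attributes(raw: str) -> SampleAttributes:
    """Parse a raw ``sample_attribute`` string; total on any input.

    Each ``||``-separated segment is split on its *first* ``": "``.
    Segments with no separator are skipped with a warning; duplicate
    normalized keys keep the first value.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for segment in _PAIR_SPLIT.split(raw):
        if not segment.strip():
            continue
        key_raw, sep, value_raw = segment.partition(": ")
        if not sep:
            logger.warning("skipping attribute segment without 'key: value' form: %r", segment)
            continue
        key = normalize_key(key_raw)
        if not key:
            logger.warning("skipping attribute segment with empty key: %r", segment)
            continue
        if key in seen:
            logger.warning("duplicate attribute key %r: keeping first value", key)
            continue
        seen.add(key)
        pairs.append((key, normalize_value(value_raw)))
    return SampleAttributes(tuple(pairs))


def expand_table(table: MetadataTable, source_column: str = "sample_attribute") -> MetadataTable:
    """Replace ``source_column`` by one column per attribute key.

    The new columns are the union of normalized keys over all rows, appended
    in alphabetical order after the surviving original columns; rows lacking
    a key get the empty string.  A key colliding with an existing column
    name is suffixed with ``"_attr"``.  Row count is always preserved.
    """
    if source_column not in table.columns:
        raise UsageError(f"column {source_column!r} not found in table")
    src = table.columns.index(source_column)
    kept = [i for i in range(len(table.columns)) if i != src]
    kept_names = [table.columns[i] for i in kept]

    parsed = [parse_attributes(row[src]) for row in table.rows]
    key_union = sorted({k for attrs in parsed for k in attrs.keys()})
    out_names = {
        k: (k + COLLISION_SUFFIX if k in kept_names else k) for k in key_union
    }

    columns = tuple(kept_names) + tuple(out_names[k] for k in key_union)
    rows = tuple(
        tuple(row[i] for i in kept) + tuple(attrs.get(k) for k in key_union)
        for row, attrs in zip(table.rows, parsed)
    )
    return MetadataTable(columns, rows)
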