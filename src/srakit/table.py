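"""Ordered string table — the universal query result.

Every query in the package returns a :class:`MetadataTable`: an ordered list
of column names plus ordered rows of strings.  Keeping everything as strings
mirrors how the archive stores metadata and makes tab-separated output
byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class MetadataTable:
    columns: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"duplicate column names: {self.columns}")
        width = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(
                    f"row {i} has {len(row)} fields, expected {width}"
                )

    @classmethod
    def build(cls, columns, rows) -> "MetadataTable":
        """Construct from any iterables, coercing every cell to ``str``."""
        return cls(
            tuple(columns),
            tuple(tuple("" if v is None else str(v) for v in row) for row in rows),
        )

    def column(self, name: str) -> tuple[str, ...]:
        idx = self.columns.index(name)
        return tuple(row[idx] for row in self.rows)

    def to_pandas(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows), columns=list(self.columns), dtype=str)

    def __len__(self) -> int:
        return len(self.rows)
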