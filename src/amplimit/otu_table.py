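"""Samples-by-taxa count tables.

Thin wrapper around a pandas DataFrame in the classic orientation (taxa as
rows, samples as columns, integer counts) with an optional genus annotation
per taxon and an optional record of the depth every sample was normalized to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OTUTable"]


@dataclass
class OTUTable:
    """Taxa x samples count matrix.

    ``counts`` has taxon ids as the index and sample ids as columns; ``genus``
    maps taxon id -> genus (defaults to the taxon id itself when absent);
    ``normalized_depth`` records a common per-sample depth if the table has
    been rarefied.
    """

    counts: pd.DataFrame
    genus: dict[str, str] = field(default_factory=dict)
    normalized_depth: int | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.normalized_depth is not None:
            sums = self.counts.sum(axis=0)
            if not (sums == self.normalized_depth).all():
                raise ValueError(
                    "normalized_depth set but sample sums differ from it"
                )

    # -- construction ---------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        counts: dict[str, dict[str, int]],
        genus: dict[str, str] | None = None,
    ) -> "OTUTable":
        """Build from {sample_id: {taxon_id: count}}."""
        df = pd.DataFrame(counts).fillna(0).astype(np.int64)
        return cls(counts=df, genus=genus or {})

    # -- accessors ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    def genus_of(self, taxon_id: str) -> str:
        return self.genus.get(taxon_id, taxon_id)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.sample_totals()
        if (totals == 0).any():
            raise ValueError("sample with zero total reads")
        return self.counts / totals

    def collapse_genus(self) -> "OTUTable":
        """Sum counts of taxa sharing a genus; index becomes genus names."""
        g = pd.Index([self.genus_of(t) for t in self.taxon_ids], name="genus")
        collapsed = self.counts.groupby(g).sum()
        return OTUTable(
            counts=collapsed,
            genus={name: name for name in collapsed.index},
            normalized_depth=self.normalized_depth,
        )

    def copy(self) -> "OTUTable":
        return OTUTable(
            counts=self.counts.copy(),
            genus=dict(self.genus),
            normalized_depth=self.normalized_depth,
        )

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column taxon_id, optional genus column, then
        one integer column per sample.  Newline-terminated UTF-8."""
        df = self.counts.copy()
        df.insert(0, "genus", [self.genus_of(t) for t in df.index])
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OTUTable":
        """Read a table written by :meth:`to_tsv` (genus column optional)."""
        try:
            df = pd.read_csv(path, sep="\t", index_col="taxon_id", dtype=str)
        except ValueError as exc:
            raise ValueError(f"{path}: missing taxon_id column ({exc})") from exc
        genus: dict[str, str] = {}
        if "genus" in df.columns:
            genus = df["genus"].to_dict()
            df = df.drop(columns="genus")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"{path}: duplicate taxon id {dup!r}")
        try:
            counts = df.astype(np.int64)
        except ValueError as exc:
            bad = _first_bad_cell(df)
            raise ValueError(
                f"{path}: non-integer count at {bad}" if bad else str(exc)
            ) from exc
        if (counts.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative counts")
        return cls(counts=counts, genus=genus)


def _first_bad_cell(df: pd.DataFrame) -> str | None:
    for col in df.columns:
        for row, value in df[col].items():
            try:
                int(value)
            except (TypeError, ValueError):
                return f"row {row!r}, column {col!r} (value {value!r})"
    return None
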