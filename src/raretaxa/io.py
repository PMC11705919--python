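"""Shared data model and tabular/graph I/O.

The four study tables — OTU counts, taxonomy, sample metadata and soil
environmental indicators — are represented as thin validated wrappers
around :class:`pandas.DataFrame`. All joins across tables are done by
sample/OTU ID, never by row position, so a shuffled input file cannot
silently misalign samples.

Canonical on-disk dialect is TSV (UTF-8, ``.`` decimal); CSV is accepted
via ``sep=","``. Networks are written as 5-column edge lists or GraphML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

_PREFIXES = {"k__", "p__", "c__", "o__", "f__", "g__", "d__", "s__"}


class TableFormatError(ValueError):
    """Raised when an input table violates the data-model contract."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = set()
    dups = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise TableFormatError(f"duplicate {what}: {sorted(set(dups))}")


@dataclasses.dataclass
class OtuTable:
    """Integer count matrix, samples in rows, OTUs in columns."""

    counts: pd.DataFrame  # index = sample IDs, columns = OTU IDs

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample IDs")
        _check_unique(df.columns, "OTU IDs")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # locate the first offending cell for the error message
            for s in df.index:
                for o in df.columns:
                    v = df.at[s, o]
                    if not float(v).is_integer():
                        raise TableFormatError(
                            f"non-integer count at sample {s!r}, OTU {o!r}: {v!r}"
                        )
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise TableFormatError("negative counts are not allowed")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1).astype(float)
        if (totals == 0).any():
            empty = list(self.counts.index[totals == 0])
            raise TableFormatError(f"samples with zero total reads: {empty}")
        return self.counts.div(totals, axis=0)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.columns]
        if missing:
            raise TableFormatError(f"unknown OTU IDs: {missing[:5]}")
        return OtuTable(self.counts.loc[:, list(otu_ids)].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise TableFormatError(f"unknown sample IDs: {missing[:5]}")
        return OtuTable(self.counts.loc[list(sample_ids), :].copy())


@dataclasses.dataclass
class TaxonomyTable:
    """OTU -> six-rank lineage; unknown ranks are ``"unclassified"``."""

    lineages: pd.DataFrame  # index = otu_id, columns = RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise TableFormatError(f"taxonomy missing ranks: {missing}")
        _check_unique(self.lineages.index, "OTU IDs in taxonomy")
        self.lineages = self.lineages[list(RANKS)].fillna(UNCLASSIFIED)

    def lineage_of(self, otu_id: str) -> dict[str, str]:
        if otu_id not in self.lineages.index:
            raise TableFormatError(f"OTU {otu_id!r} missing from taxonomy")
        return dict(self.lineages.loc[otu_id])


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``k__Fungi;p__Ascomycota;...`` or bare ``Fungi;Ascomycota;...``
    into the six ranks; prefixes are stripped, gaps become "unclassified"."""
    parts = [p.strip() for p in lineage.split(";")]
    cleaned = []
    for p in parts:
        if p[:3].lower() in _PREFIXES:
            p = p[3:]
        cleaned.append(p if p else UNCLASSIFIED)
    out = {}
    for i, rank in enumerate(RANKS):
        out[rank] = cleaned[i] if i < len(cleaned) else UNCLASSIFIED
    return out


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample site and health status (H = healthy, M = diseased)."""

    records: pd.DataFrame  # index = sample_id, columns include site, health

    def __post_init__(self) -> None:
        for col in ("site", "health"):
            if col not in self.records.columns:
                raise TableFormatError(f"metadata missing column {col!r}")
        _check_unique(self.records.index, "sample IDs in metadata")
        bad = set(self.records["health"]) - {"H", "M"}
        if bad:
            raise TableFormatError(f"health values must be H or M, got {sorted(bad)}")

    def samples_with_health(self, health: str) -> list[str]:
        return list(self.records.index[self.records["health"] == health])

    def check_covers(self, table: OtuTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.records.index]
        if missing:
            raise TableFormatError(f"samples missing from metadata: {missing}")


@dataclasses.dataclass
class EnvTable:
    """Samples x environmental indicators (pH, EC, OC/SOM, AN, AP, AK ...).

    The indicator set is whatever the header declares; nothing is
    hard-coded to six columns.
    """

    values: pd.DataFrame  # index = sample_id, columns = indicator names

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample IDs in env table")
        _check_unique(self.values.columns, "indicator names")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableFormatError("environmental table contains non-numeric cells")
        if not np.isfinite(arr).all():
            raise TableFormatError("environmental table contains non-finite values")

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    def aligned_to(self, table: OtuTable) -> pd.DataFrame:
        missing = [s for s in table.sample_ids if s not in self.values.index]
        if missing:
            raise TableFormatError(f"samples missing from env table: {missing}")
        return self.values.loc[table.sample_ids]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_indexed(path, sep: str) -> pd.DataFrame:
    """read_csv with duplicate-header detection (pandas silently renames)."""
    if hasattr(path, "read"):
        header = path.readline().rstrip("\n").split(sep)
        path.seek(0)
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "column names")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    df.columns.name = None
    return df


def read_otu_table(path, sep: str = "\t", samples_as_rows: bool = False) -> OtuTable:
    """Read an OTU count table.

    Default file layout is the common amplicon convention: OTUs in rows,
    samples in the header. Set ``samples_as_rows=True`` for transposed files.
    """
    df = _read_indexed(path, sep)
    if not samples_as_rows:
        df = df.T
    for s in df.index:
        for o, v in df.loc[s].items():
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-numeric count at sample {s!r}, OTU {o!r}: {v!r}"
                ) from None
            if not fv.is_integer():
                raise TableFormatError(
                    f"non-integer count at sample {s!r}, OTU {o!r}: {v!r}"
                )
    return OtuTable(df.astype(np.int64))


def write_otu_table(table: OtuTable, path, sep: str = "\t") -> None:
    """Write OTUs as rows, samples as columns (round-trips with the reader)."""
    table.counts.T.to_csv(path, sep=sep, index_label="otu_id")


def read_env_table(path, sep: str = "\t") -> EnvTable:
    df = _read_indexed(path, sep)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric cell in env table: {exc}") from None
    return EnvTable(df)


def write_env_table(env: EnvTable, path, sep: str = "\t") -> None:
    env.values.to_csv(path, sep=sep, index_label="sample_id")


def read_metadata(path, sep: str = "\t") -> SampleMetadata:
    df = _read_indexed(path, sep).astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path, sep: str = "\t") -> None:
    meta.records.to_csv(path, sep=sep, index_label="sample_id")


def read_taxonomy(path, sep: str = "\t") -> TaxonomyTable:
    """Read taxonomy as either a 2-column (otu_id, lineage-string) table or
    a 7-column (otu_id + six ranks) table."""
    df = _read_indexed(path, sep).astype(str)
    if df.shape[1] == 1:
        parsed = pd.DataFrame(
            [parse_lineage(v) for v in df.iloc[:, 0]], index=df.index
        )
        return TaxonomyTable(parsed)
    df.columns = [c.lower() for c in df.columns]
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path, sep: str = "\t") -> None:
    tax.lineages.to_csv(path, sep=sep, index_label="otu_id")


EDGE_COLUMNS = ["source", "target", "spearman_r", "sign", "adjusted_p"]


def write_network(graph: nx.Graph, path, format: str = "edge-list") -> None:
    """Write a co-occurrence network as an edge list or GraphML.

    Edge list columns: source, target, spearman_r, sign, adjusted_p. Node
    attributes (GSP class, taxonomy) survive only in GraphML.
    """
    path = Path(path)
    if format == "edge-list":
        rows = [
            {
                "source": u,
                "target": v,
                "spearman_r": d.get("r", np.nan),
                "sign": d.get("sign", ""),
                "adjusted_p": d.get("adjusted_p", np.nan),
            }
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge-list") -> nx.Graph:
    path = Path(path)
    if format == "edge-list":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(
                row["source"],
                row["target"],
                r=float(row["spearman_r"]),
                sign=str(row["sign"]),
                adjusted_p=float(row["adjusted_p"]),
            )
        return g
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {format!r}")
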