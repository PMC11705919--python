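"""Abundance-class partitioning (abundant / intermediate / rare taxa).

OTUs are classified by relative abundance pooled over all samples:
abundant (AT) above 0.1%, rare (RT) below 0.01%, intermediate (IT) in
between, with the boundary values themselves falling to IT (the class
thresholds are strict). Occupancy is the fraction of samples in a habitat
where an OTU is detected. The module also provides rarefaction, the
low-count filter, abundance-occupancy correlations and the per-rank
taxonomic census.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable, TaxonomyTable, TableFormatError, RANKS, UNCLASSIFIED

GSP_CLASSES = ("AT", "IT", "RT")
ABUNDANT_THRESHOLD = 1e-3  # relative abundance above which an OTU is abundant
RARE_THRESHOLD = 1e-4  # below which it is rare

CENSUS_RANKS = ("phylum", "class", "order", "family", "genus")


@dataclasses.dataclass
class GspPartition:
    """Per-OTU class, mean relative abundance and occupancy."""

    table: pd.DataFrame  # index otu_id; columns gsp_class, mean_relative_abundance, occupancy

    @property
    def classes(self) -> pd.Series:
        return self.table["gsp_class"]

    def otus_in_class(self, gsp_class: str) -> list[str]:
        return list(self.table.index[self.table["gsp_class"] == gsp_class])

    def class_sizes(self) -> pd.Series:
        return self.classes.value_counts().reindex(GSP_CLASSES, fill_value=0)


def filter_low_count(table: OtuTable, min_reads: int = 20) -> OtuTable:
    """Drop OTUs with total reads below ``min_reads`` (strictly fewer).

    An OTU totalling exactly ``min_reads`` is kept.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= min_reads].index
    return OtuTable(table.counts.loc[:, keep].copy())


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to equal depth.

    ``depth`` defaults to the minimum sample total. Uses a multivariate
    hypergeometric draw per sample, so output totals equal ``depth``
    exactly and the same seed reproduces the same table.
    """
    totals = table.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    offending = list(totals.index[totals < depth])
    if offending:
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: {offending}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, sid in enumerate(table.sample_ids):
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        pd.DataFrame(out, index=table.counts.index.copy(), columns=table.counts.columns.copy())
    )


def classify_gsp(table: OtuTable, abundance_mode: str = "pooled") -> GspPartition:
    """Partition OTUs into AT / IT / RT by relative abundance.

    ``abundance_mode="pooled"`` (default) uses OTU total reads over the
    grand total; ``"mean"`` averages per-sample relative abundances. With
    equal sample depths (post-rarefaction) the two coincide.
    """
    if table.counts.size == 0:
        raise ValueError("cannot classify an empty OTU table")
    if abundance_mode == "pooled":
        frac = table.counts.sum(axis=0) / table.counts.to_numpy().sum()
    elif abundance_mode == "mean":
        frac = table.relative_abundance().mean(axis=0)
    else:
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
    cls = pd.Series("IT", index=frac.index, dtype=object)
    cls[frac > ABUNDANT_THRESHOLD] = "AT"
    cls[frac < RARE_THRESHOLD] = "RT"
    occ = occupancy(table)
    return GspPartition(
        pd.DataFrame(
            {
                "gsp_class": cls,
                "mean_relative_abundance": frac.astype(float),
                "occupancy": occ,
            }
        )
    )


def occupancy(table: OtuTable, subset: list[str] | None = None) -> pd.Series:
    """Fraction of samples (optionally a habitat subset) where each OTU occurs."""
    sub = table if subset is None else table.subset_samples(subset)
    n = sub.shape[0]
    if n == 0:
        raise ValueError("occupancy requires a nonempty sample set")
    return (sub.counts > 0).sum(axis=0) / n


def abundance_occupancy(
    partition: GspPartition, by_class: bool = True
) -> pd.DataFrame:
    """Spearman correlation between log10 mean relative abundance and occupancy.

    Returns one row per group ("Whole" plus each abundance class when
    ``by_class``): R, p and n. Groups with fewer than 3 OTUs or zero
    variance are reported with NaN statistics and ``defined=False``.
    """
    rows = {}
    groups = {"Whole": partition.table}
    if by_class:
        for c in GSP_CLASSES:
            groups[c] = partition.table[partition.table["gsp_class"] == c]
    for name, df in groups.items():
        n = len(df)
        x = np.log10(df["mean_relative_abundance"].to_numpy())
        y = df["occupancy"].to_numpy()
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[name] = {"spearman_R": np.nan, "p_value": np.nan, "n": n, "defined": False}
            continue
        r, p = stats.spearmanr(x, y)
        rows[name] = {"spearman_R": float(r), "p_value": float(p), "n": n, "defined": True}
    return pd.DataFrame(rows).T


def taxonomic_census(partition: GspPartition, taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Distinct-name counts per rank for the whole community and each class.

    Rows: Whole, AT, IT, RT. Columns: OTUs plus the five ranks below
    kingdom; "unclassified" never counts as a name.
    """
    missing = [o for o in partition.table.index if o not in taxonomy.lineages.index]
    if missing:
        raise TableFormatError(f"OTUs missing from taxonomy: {missing[:5]}")
    lin = taxonomy.lineages.loc[partition.table.index]

    def census_of(otus: pd.Index) -> dict[str, int]:
        sub = lin.loc[otus]
        row = {"OTUs": len(otus)}
        for rank in CENSUS_RANKS:
            names = set(sub[rank]) - {UNCLASSIFIED}
            row[rank.capitalize()] = len(names)
        return row

    rows = {"Whole": census_of(partition.table.index)}
    for c in GSP_CLASSES:
        rows[c] = census_of(partition.table.index[partition.table["gsp_class"] == c])
    return pd.DataFrame(rows).T[["OTUs"] + [r.capitalize() for r in CENSUS_RANKS]]


def gsp_fractions(census: pd.DataFrame) -> dict[str, float]:
    """Percent of total OTUs per class, rounded to two decimals."""
    from ._utils import round_half_away

    whole = int(census.loc["Whole", "OTUs"])
    if whole == 0:
        raise ValueError("census has zero total OTUs")
    return {
        c: round_half_away(100.0 * int(census.loc[c, "OTUs"]) / whole, 2)
        for c in GSP_CLASSES
    }
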