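"""Ecological-preference trait sets.

Each OTU's preference for each soil indicator is the sign of a
significant Spearman correlation between its relative abundance and that
indicator across samples: +1 (positive preference), -1 (negative), 0
(none). The per-class census aggregates these signs into count rows, a
mean trait score ((#positive - #negative) / class size) and a preference
breadth (fraction of OTU x indicator cells with a nonzero sign).

p-values are deliberately left unadjusted by default: the trait rule is a
per-cell significance call, not a family-wise discovery; a BH option is
provided for the conservative variant.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_away
from .io import EnvTable, OtuTable
from .network import fdr_adjust
from .partition import GspPartition, GSP_CLASSES


@dataclasses.dataclass
class TraitMatrix:
    signs: pd.DataFrame  # OTU x indicator in {-1, 0, +1}
    r: pd.DataFrame | None = None
    p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.signs.to_numpy())) - {-1, 0, 1}
        if bad:
            raise ValueError(f"trait entries must be -1/0/+1, got {sorted(bad)}")


def trait_matrix(
    table: OtuTable, env: EnvTable, alpha: float = 0.05, fdr: bool = False
) -> TraitMatrix:
    """Sign-threshold Spearman correlations of OTU abundance vs indicators."""
    env_vals = env.aligned_to(table)
    if table.shape[0] < 4:
        raise ValueError("trait matrix requires at least 4 samples")
    rel = table.relative_abundance().to_numpy()
    ev = env_vals.to_numpy(dtype=float)
    n_otu, n_ind = rel.shape[1], ev.shape[1]
    r = np.full((n_otu, n_ind), np.nan)
    p = np.full((n_otu, n_ind), np.nan)
    const_env = [j for j in range(n_ind) if np.ptp(ev[:, j]) == 0]
    if const_env:
        warnings.warn(
            f"constant indicators treated as no-preference: "
            f"{[env_vals.columns[j] for j in const_env]}",
            stacklevel=2,
        )
    for j in range(n_ind):
        if j in const_env:
            continue
        for i in range(n_otu):
            if np.ptp(rel[:, i]) == 0:
                continue
            r[i, j], p[i, j] = stats.spearmanr(rel[:, i], ev[:, j])
    p_eff = p
    if fdr:
        p_eff = fdr_adjust(p.ravel()).reshape(p.shape)
    signs = np.zeros((n_otu, n_ind), dtype=int)
    with np.errstate(invalid="ignore"):
        sig = np.isfinite(p_eff) & (p_eff < alpha)
        signs[sig & (r > 0)] = 1
        signs[sig & (r < 0)] = -1
    idx, cols = table.counts.columns, env_vals.columns
    return TraitMatrix(
        signs=pd.DataFrame(signs, index=idx, columns=cols),
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
    )


@dataclasses.dataclass
class PreferenceCensus:
    counts: pd.DataFrame  # MultiIndex rows (class, sign in {+, NA, -}) x indicators
    mean_score: pd.DataFrame  # class x indicator
    breadth: pd.Series  # class -> fraction of nonzero cells
    class_sizes: pd.Series


def preference_census(traits: TraitMatrix, partition: GspPartition) -> PreferenceCensus:
    """Aggregate per-OTU trait signs into the per-class census.

    For each class and indicator: counts of +, NA (0) and -; the mean
    trait score (#+ - #-) / class size; and per class the breadth
    sum over indicators of (#+ + #-) / (class size x #indicators).
    """
    missing = [o for o in traits.signs.index if o not in partition.table.index]
    if missing:
        raise ValueError(f"OTUs missing from partition: {missing[:5]}")
    cls = partition.classes.reindex(traits.signs.index)
    indicators = list(traits.signs.columns)
    count_rows = {}
    scores = {}
    breadth = {}
    sizes = {}
    for c in GSP_CLASSES:
        sub = traits.signs.loc[cls == c]
        n = len(sub)
        sizes[c] = n
        pos = (sub == 1).sum(axis=0)
        neg = (sub == -1).sum(axis=0)
        na = (sub == 0).sum(axis=0)
        count_rows[(c, "+")] = pos
        count_rows[(c, "NA")] = na
        count_rows[(c, "-")] = neg
        scores[c] = (pos - neg) / n if n else pos * np.nan
        breadth[c] = (
            float((pos + neg).sum()) / (n * len(indicators)) if n else np.nan
        )
    counts = pd.DataFrame(count_rows).T
    counts.index = pd.MultiIndex.from_tuples(counts.index, names=["gsp_class", "sign"])
    return PreferenceCensus(
        counts=counts[indicators],
        mean_score=pd.DataFrame(scores).T[indicators],
        breadth=pd.Series(breadth),
        class_sizes=pd.Series(sizes),
    )


def preference_breadth(census: PreferenceCensus) -> pd.Series:
    """Per-class breadth as a percent, two decimals, ties away from zero."""
    out = {}
    for c, frac in census.breadth.items():
        out[c] = round_half_away(100.0 * frac, 2) if np.isfinite(frac) else np.nan
    return pd.Series(out)


def census_table(census: PreferenceCensus, round_scores: int = 4) -> pd.DataFrame:
    """Flat layout of the census: per class the three count rows plus an
    Average row, and a Total row summing + and - over classes."""
    rows = []
    for c in GSP_CLASSES:
        for sign in ("+", "NA", "-"):
            rows.append(
                {"gsp_class": c, "row": sign, **census.counts.loc[(c, sign)].to_dict()}
            )
        rows.append(
            {
                "gsp_class": c,
                "row": "Average",
                **{
                    k: round_half_away(v, round_scores)
                    for k, v in census.mean_score.loc[c].to_dict().items()
                },
            }
        )
    for sign in ("+", "-"):
        total = sum(census.counts.loc[(c, sign)] for c in GSP_CLASSES)
        rows.append({"gsp_class": "Total", "row": sign, **total.to_dict()})
    return pd.DataFrame(rows)
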