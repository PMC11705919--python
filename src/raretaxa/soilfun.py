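"""Diversity indices and their coupling to Z-scored individual soil functions.

Each soil indicator is standardized across plots, Zij = (xij - mean_j) / sd_j,
so that one "individual soil function" per indicator is comparable across
units. Per-class alpha diversity (bias-corrected Chao1 on the class-subset
table) is regressed on each function by ordinary least squares; beta
diversity (Bray-Curtis) is regressed pairwise on |Zi - Zj|. A Wilcoxon
rank-sum test compares alpha diversity between healthy and diseased plots.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .io import EnvTable, OtuTable, SampleMetadata
from .partition import GspPartition, GSP_CLASSES


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    if c.size == 0 or c.sum() == 0:
        return 0.0
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    return float(_skbio_chao1(c.astype(int), bias_corrected=True))


def alpha_by_class(table: OtuTable, partition: GspPartition) -> pd.DataFrame:
    """Per-sample Chao1, computed on each class's OTU subset (and overall)."""
    out = {}
    groups = {"Whole": list(table.otu_ids)}
    for c in GSP_CLASSES:
        groups[c] = [o for o in partition.otus_in_class(c) if o in table.counts.columns]
    for name, otus in groups.items():
        sub = table.counts[otus]
        out[name] = sub.apply(lambda row: chao1(row.to_numpy()), axis=1)
    return pd.DataFrame(out)


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples, on relative abundances."""
    if table.shape[0] < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(
            f"all-zero samples have undefined dissimilarity: "
            f"{list(totals.index[totals == 0])}"
        )
    rel = table.relative_abundance().to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return pd.DataFrame(d, index=table.counts.index, columns=table.counts.index)


@dataclasses.dataclass
class SoilFunctionMatrix:
    z: pd.DataFrame  # samples x indicators, column mean 0 / sample SD 1
    mean: pd.Series
    sd: pd.Series


def zscore_functions(env: EnvTable) -> SoilFunctionMatrix:
    """Column-wise standardization of the environmental table (ddof=1)."""
    df = env.values
    if len(df) < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    const = list(sd.index[sd == 0])
    if const:
        raise ValueError(f"constant indicators cannot be Z-scored: {const}")
    return SoilFunctionMatrix(z=(df - mean) / sd, mean=mean, sd=sd)


def _ols_row(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return {
            "slope": np.nan, "intercept": np.nan, "r2": np.nan,
            "p": np.nan, "n": len(x), "significant": False, "defined": False,
        }
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": len(x),
        "significant": bool(res.pvalue < 0.05),
        "defined": True,
    }


def alpha_function_regression(
    alpha: pd.DataFrame, functions: SoilFunctionMatrix
) -> pd.DataFrame:
    """OLS of per-class alpha diversity on each Z-scored soil function.

    ``alpha``: samples x class columns (from :func:`alpha_by_class`).
    Returns one row per (class, indicator) with slope, intercept, R², p
    and significance flags ("**" p<0.01, "*" p<0.05, "" otherwise).
    """
    z = functions.z
    common = [s for s in alpha.index if s in z.index]
    if not common:
        raise ValueError("no shared samples between alpha table and functions")
    rows = []
    for cls in alpha.columns:
        y = alpha.loc[common, cls].to_numpy(dtype=float)
        for ind in z.columns:
            x = z.loc[common, ind].to_numpy(dtype=float)
            row = {"gsp_class": cls, "indicator": ind, **_ols_row(x, y)}
            p = row["p"]
            row["flag"] = "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append(row)
    return pd.DataFrame(rows)


def beta_function_regression(
    beta: pd.DataFrame,
    functions: SoilFunctionMatrix,
    gsp_class: str = "",
    mantel_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """OLS of pairwise Bray-Curtis distance on pairwise |delta Z|.

    One regression per indicator, over all unordered sample pairs
    (n = N(N-1)/2). Pairs are not independent, so an optional
    Mantel-style permutation p (``mantel_permutations`` > 0) is reported
    alongside the plain OLS p.
    """
    samples = list(beta.index)
    z = functions.z.loc[samples]
    pairs = list(itertools.combinations(range(len(samples)), 2))
    d = np.array([beta.iloc[i, j] for i, j in pairs])
    rows = []
    rng = np.random.default_rng(seed)
    for ind in z.columns:
        zv = z[ind].to_numpy(dtype=float)
        dz = np.array([abs(zv[i] - zv[j]) for i, j in pairs])
        row = {"gsp_class": gsp_class, "indicator": ind, **_ols_row(dz, d)}
        p = row["p"]
        row["flag"] = "**" if p < 0.01 else "*" if p < 0.05 else ""
        if mantel_permutations and row["defined"]:
            obs = abs(np.corrcoef(dz, d)[0, 1])
            hits = 0
            for _ in range(mantel_permutations):
                perm = rng.permutation(len(samples))
                dzp = np.array([abs(zv[perm[i]] - zv[perm[j]]) for i, j in pairs])
                if abs(np.corrcoef(dzp, d)[0, 1]) >= obs:
                    hits += 1
            row["mantel_p"] = (hits + 1) / (mantel_permutations + 1)
        rows.append(row)
    return pd.DataFrame(rows)


def beta_pcoa_axis(beta: pd.DataFrame) -> pd.Series:
    """First principal-coordinate axis of a Bray-Curtis matrix.

    Alternative beta-diversity summary for per-sample (n = N) regressions
    against soil functions.
    """
    d = beta.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    k = int(np.argmax(vals))
    axis = vecs[:, k] * np.sqrt(max(vals[k], 0.0))
    return pd.Series(axis, index=beta.index)


def compare_alpha_by_health(
    alpha: pd.Series, metadata: SampleMetadata
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum of per-sample alpha between H and M."""
    groups = {}
    for health in ("H", "M"):
        ids = [s for s in alpha.index if s in metadata.samples_with_health(health)]
        if len(ids) < 3:
            raise ValueError(f"health group {health!r} has fewer than 3 samples")
        groups[health] = alpha.loc[ids].to_numpy(dtype=float)
    res = stats.mannwhitneyu(groups["H"], groups["M"], alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}
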