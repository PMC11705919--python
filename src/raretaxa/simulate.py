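"""Synthetic community generator with known planted structure.

Every downstream stage of the pipeline is tested against data whose truth
is known by construction: base abundances follow a log-normal species
abundance distribution (few dominant, a long rare tail), environmental
gradients modulate a chosen fraction of OTUs (linearly or as a step at a
known change point), planted modules share a latent per-sample factor so
their members co-occur, and diseased (M) samples receive per-OTU
log-normal fold changes. Counts are drawn multinomially per sample at a
fixed depth, so sample totals are exact.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import EnvTable, OtuTable, SampleMetadata, TaxonomyTable, RANKS, UNCLASSIFIED

DEFAULT_INDICATORS = ("pH", "EC", "OC", "AN", "AP", "AK")

# plausible ranges (location, scale) for each default soil indicator
_INDICATOR_PARAMS = {
    "pH": (4.5, 0.5),
    "EC": (120.0, 30.0),
    "OC": (35.0, 8.0),
    "AN": (110.0, 25.0),
    "AP": (15.0, 5.0),
    "AK": (150.0, 40.0),
}


@dataclasses.dataclass
class EnvResponse:
    otu_id: str
    variable: str
    direction: int  # +1 or -1
    form: str  # "linear" or "threshold"
    threshold: float | None  # gradient value for step responses
    strength: float


@dataclasses.dataclass
class Module:
    otu_ids: list[str]
    sign: int  # +1: all co-increase; -1: two anti-correlated halves
    strength: float


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth planted into a generated dataset."""

    mean_relative_abundance: pd.Series  # per OTU, expected (pooled) fraction
    gsp_class: pd.Series  # per OTU in {"AT", "IT", "RT"}
    modules: list[Module]
    env_responses: list[EnvResponse]
    disease_log_fold: pd.Series  # per-OTU log fold change applied to M samples


def _gsp_class_from_fraction(frac: np.ndarray) -> np.ndarray:
    out = np.full(frac.shape, "IT", dtype=object)
    out[frac > 1e-3] = "AT"
    out[frac < 1e-4] = "RT"
    return out


def generate_dataset(
    n_samples: int = 20,
    n_otus: int = 1000,
    depth: int = 50_000,
    frac_env_responsive: float = 0.15,
    frac_module_members: float = 0.15,
    disease_effect_sd: float = 0.0,
    seed: int = 0,
    sigma: float = 3.0,
    n_indicators: int = 6,
    n_modules: int = 3,
    module_strength: float = 1.0,
    env_strength: float = 1.0,
    decorrelate_modules_in_m: bool = False,
) -> tuple[OtuTable, SampleMetadata, EnvTable, SyntheticTruth]:
    """Generate an OTU table plus metadata, environment and ground truth.

    Parameters mirror the study design being emulated: 20 samples split
    evenly into healthy (H) and diseased (M), ~1000 OTUs, six soil
    indicators, log-normal base abundances with sigma=2 so the abundant
    (>0.1%), intermediate and rare (<0.01%) classes are all populated with
    the rare class largest after the low-count filter (sigma=3 reproduces
    that ordering; sigma=2 inverts it).

    ``decorrelate_modules_in_m`` replaces the shared latent factor with
    independent noise in M samples, weakening co-occurrence there.
    """
    if n_samples < 6 or n_samples % 2:
        raise ValueError("n_samples must be even and >= 6 (H/M split)")
    rng = np.random.default_rng(seed)

    otu_ids = [f"OTU{i + 1:05d}" for i in range(n_otus)]
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    half = n_samples // 2
    health = np.array(["H"] * half + ["M"] * half)
    site = np.where(np.arange(n_samples) % 2 == 0, "QS", "WS")
    meta = SampleMetadata(
        pd.DataFrame({"site": site, "health": health}, index=pd.Index(sample_ids))
    )

    # environmental gradients
    names = list(DEFAULT_INDICATORS[:n_indicators]) + [
        f"X{j}" for j in range(max(0, n_indicators - len(DEFAULT_INDICATORS)))
    ]
    env = np.empty((n_samples, n_indicators))
    for j, name in enumerate(names):
        loc, scale = _INDICATOR_PARAMS.get(name, (0.0, 1.0))
        env[:, j] = loc + scale * rng.uniform(-1.8, 1.8, size=n_samples)
    env_df = pd.DataFrame(env, index=pd.Index(sample_ids), columns=names)
    env_z = (env - env.mean(axis=0)) / env.std(axis=0)

    # log-normal species abundance distribution
    base = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    log_expected = np.tile(np.log(base), (n_samples, 1))  # samples x OTUs

    # planted environmental responses
    responses: list[EnvResponse] = []
    n_resp = int(round(frac_env_responsive * n_otus))
    resp_idx = rng.choice(n_otus, size=n_resp, replace=False)
    for idx in resp_idx:
        j = int(rng.integers(n_indicators))
        direction = int(rng.choice([-1, 1]))
        form = str(rng.choice(["linear", "threshold"]))
        strength = env_strength * rng.uniform(0.5, 1.5)
        grad = env[:, j]
        if form == "linear":
            log_expected[:, idx] += direction * strength * env_z[:, j]
            thr = None
        else:
            lo, hi = np.quantile(grad, [0.25, 0.75])
            thr = float(rng.uniform(lo, hi))
            step = (grad > thr).astype(float) - 0.5
            log_expected[:, idx] += direction * 2.0 * strength * step
        responses.append(
            EnvResponse(otu_ids[idx], names[j], direction, form, thr, strength)
        )

    # planted co-occurrence modules driven by shared latent factors
    modules: list[Module] = []
    n_members_total = int(round(frac_module_members * n_otus))
    pool = [i for i in range(n_otus) if i not in set(resp_idx)]
    rng.shuffle(pool)
    if n_modules > 0 and n_members_total >= 2 * n_modules:
        per = n_members_total // n_modules
        is_m = health == "M"
        for m in range(n_modules):
            members = pool[m * per : (m + 1) * per]
            sign = 1 if m % 2 == 0 else -1
            factor = module_strength * rng.normal(size=n_samples)
            if decorrelate_modules_in_m:
                factor = factor.copy()
                factor[is_m] = 0.0
            for k, idx in enumerate(members):
                s = 1 if (sign == 1 or k < len(members) // 2) else -1
                log_expected[:, idx] += s * factor
                if decorrelate_modules_in_m:
                    noise = module_strength * rng.normal(size=is_m.sum())
                    log_expected[is_m, idx] += noise
            modules.append(Module([otu_ids[i] for i in members], sign, module_strength))

    # disease effect: per-OTU log-normal fold change in M samples only
    disease_lfc = np.zeros(n_otus)
    if disease_effect_sd > 0:
        disease_lfc = rng.normal(0.0, disease_effect_sd, size=n_otus)
        log_expected[health == "M", :] += disease_lfc

    expected = np.exp(log_expected)
    probs = expected / expected.sum(axis=1, keepdims=True)

    counts = np.empty((n_samples, n_otus), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depth, probs[i])
    table = OtuTable(
        pd.DataFrame(counts, index=pd.Index(sample_ids), columns=otu_ids)
    )

    mean_frac = probs.mean(axis=0)
    classes = _gsp_class_from_fraction(mean_frac)
    present = set(classes)
    missing = [c for c in ("AT", "IT", "RT") if c not in present]
    if missing:
        warnings.warn(
            f"synthetic abundance distribution left classes empty: {missing}",
            stacklevel=2,
        )
    truth = SyntheticTruth(
        mean_relative_abundance=pd.Series(mean_frac, index=otu_ids),
        gsp_class=pd.Series(classes, index=otu_ids),
        modules=modules,
        env_responses=responses if n_resp else [],
        disease_log_fold=pd.Series(disease_lfc, index=otu_ids),
    )
    return table, meta, env_df_to_envtable(env_df), truth


def env_df_to_envtable(df: pd.DataFrame) -> EnvTable:
    return EnvTable(df)


def generate_step_taxon(
    gradient: np.ndarray,
    change_point: float,
    direction: str = "+",
    high_mean: float = 50.0,
    low_mean: float = 0.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Abundance vector with a step response along an environmental gradient.

    Expected abundance is ``low_mean`` on one side of ``change_point`` and
    ``high_mean`` on the other; direction "+" puts the high side above the
    change point. Noise is negative-binomial with variance
    ``mu + dispersion * mu**2``; ``dispersion=0`` returns the expected
    values exactly (noiseless limit).
    """
    gradient = np.asarray(gradient, dtype=float)
    if not (gradient.min() < change_point < gradient.max()):
        raise ValueError("change_point must lie strictly inside the gradient range")
    if direction not in {"+", "-"}:
        raise ValueError("direction must be '+' or '-'")
    high_side = gradient > change_point
    if direction == "-":
        high_side = ~high_side
    mu = np.where(high_side, high_mean, low_mean).astype(float)
    if dispersion == 0:
        return mu.copy()
    rng = np.random.default_rng(seed)
    out = np.zeros_like(mu)
    pos = mu > 0
    # NB parameterized by size r = 1/dispersion, p = r/(r+mu)
    r = 1.0 / dispersion
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def random_taxonomy(otu_ids, seed: int = 0, frac_unclassified: float = 0.15) -> TaxonomyTable:
    """Random but internally consistent six-rank lineages for test fixtures.

    Lower ranks nest inside higher ones (each genus belongs to one family,
    and so on), mimicking a real reference-database annotation.
    """
    rng = np.random.default_rng(seed)
    n = len(otu_ids)
    # pool sizes shrink going up the hierarchy
    pools = {"phylum": 8, "class": 16, "order": 30, "family": 50, "genus": 80}
    parent = {"class": "phylum", "order": "class", "family": "order", "genus": "family"}
    assign = {r: rng.integers(pools[r], size=n) for r in pools}
    # force nesting: child label index determines parent label index
    links = {
        r: rng.integers(pools[parent[r]], size=pools[r]) for r in parent
    }
    rows = []
    for i in range(n):
        g = int(assign["genus"][i])
        f = int(links["genus"][g]) if "genus" in links else int(assign["family"][i])
        o = int(links["family"][f])
        c = int(links["order"][o])
        p = int(links["class"][c])
        row = {
            "kingdom": "Fungi",
            "phylum": f"Phylum{p:02d}",
            "class": f"Class{c:02d}",
            "order": f"Order{o:02d}",
            "family": f"Family{f:02d}",
            "genus": f"Genus{g:02d}",
        }
        for rank in RANKS[1:]:
            if rng.random() < frac_unclassified:
                row[rank] = UNCLASSIFIED
        rows.append(row)
    return TaxonomyTable(pd.DataFrame(rows, index=pd.Index(list(otu_ids))))


def write_truth(truth: SyntheticTruth, path) -> None:
    """Persist the per-OTU ground truth as TSV for external harnesses."""
    df = pd.DataFrame(
        {
            "mean_relative_abundance": truth.mean_relative_abundance,
            "gsp_class": truth.gsp_class,
            "disease_log_fold": truth.disease_log_fold,
        }
    )
    module_of = {}
    for m_i, mod in enumerate(truth.modules):
        for o in mod.otu_ids:
            module_of[o] = m_i
    df["module"] = [module_of.get(o, -1) for o in df.index]
    resp = {r.otu_id: f"{r.variable}:{'+' if r.direction > 0 else '-'}:{r.form}" for r in truth.env_responses}
    df["env_response"] = [resp.get(o, "") for o in df.index]
    df.to_csv(path, sep="\t", index_label="otu_id")
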