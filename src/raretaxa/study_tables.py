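"""Published summary tables of the tea-rhizosphere fungal survey.

The pipeline's output layouts follow a published survey of rhizosphere
fungi in karst tea gardens (20 plots, 1091 OTUs after rarefaction and the
<20-read filter, six soil indicators). The survey's printed summary
tables — the per-class OTU census, the network link decomposition and the
ecological-preference count rows — are reproduced here as plain data so
that the corresponding pipeline computations can be exercised against
exact published numbers without access to the raw sequence archive.

Helpers construct in-memory objects (census frame, signed network, trait
sign matrix) that realize the printed counts exactly.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .partition import GSP_CLASSES, GspPartition
from .traits import TraitMatrix

# per-class OTU counts and distinct-name counts per rank
CLASS_CENSUS = {
    "Whole": {"OTUs": 1091, "Phylum": 14, "Class": 34, "Order": 70, "Family": 127, "Genus": 199},
    "AT": {"OTUs": 111, "Phylum": 3, "Class": 8, "Order": 20, "Family": 34, "Genus": 41},
    "IT": {"OTUs": 300, "Phylum": 9, "Class": 20, "Order": 43, "Family": 67, "Genus": 76},
    "RT": {"OTUs": 680, "Phylum": 14, "Class": 34, "Order": 62, "Family": 109, "Genus": 137},
}

# co-occurrence links per class pair: (total, positive, negative)
LINK_COUNTS = {
    "AT-AT": (435, 356, 79),
    "AT-IT": (1372, 1073, 299),
    "AT-RT": (1198, 919, 279),
    "IT-IT": (2121, 1741, 380),
    "IT-RT": (3950, 3255, 695),
    "RT-RT": (4132, 3935, 197),
}

# published positive-correlation percentages for the six class pairs
LINK_POSITIVE_PCT = {
    "AT-AT": 81.84,
    "AT-IT": 78.21,
    "AT-RT": 76.71,
    "IT-IT": 82.08,
    "IT-RT": 82.41,
    "RT-RT": 95.23,
}

ENV_INDICATORS = ("pH", "EC", "OC", "OP", "AP", "AK")

# ecological-preference sign counts per class and indicator: (+, NA, -)
TRAIT_COUNTS = {
    "AT": {
        "pH": (16, 72, 23), "EC": (25, 71, 15), "OC": (5, 83, 23),
        "OP": (21, 71, 19), "AP": (19, 90, 2), "AK": (19, 88, 4),
    },
    "IT": {
        "pH": (46, 167, 87), "EC": (85, 172, 43), "OC": (20, 215, 65),
        "OP": (37, 206, 57), "AP": (43, 252, 5), "AK": (61, 219, 20),
    },
    "RT": {
        "pH": (69, 487, 124), "EC": (121, 513, 46), "OC": (42, 550, 88),
        "OP": (43, 545, 92), "AP": (48, 614, 18), "AK": (78, 565, 37),
    },
}

# published per-class mean trait scores ("Average" rows)
TRAIT_MEAN_SCORES = {
    "AT": {"pH": -0.0631, "EC": 0.0901, "OC": -0.1622, "OP": 0.0180, "AP": 0.1532, "AK": 0.1351},
    # the published IT "OP" value is -0.6667; the count row (37, 206, 57)
    # over 300 OTUs gives -0.0667 by the formula that reproduces every
    # other cell, so the table entry is treated as a misprint
    "IT": {"pH": -0.1367, "EC": 0.14, "OC": -0.15, "OP": -0.0667, "AP": 0.1267, "AK": 0.1367},
    "RT": {"pH": -0.0809, "EC": 0.1103, "OC": -0.0676, "OP": -0.0721, "AP": 0.0441, "AK": 0.0603},
}

# published preference breadths (percent of nonzero OTU x indicator cells)
PREFERENCE_BREADTH_PCT = {"AT": 28.68, "RT": 19.75}

GSP_PERCENTAGES = {"AT": 10.17, "RT": 62.33}


def census_frame() -> pd.DataFrame:
    """The per-class census in the layout taxonomic_census produces."""
    return pd.DataFrame(CLASS_CENSUS).T


def _uniform_partition(otus, classes) -> GspPartition:
    return GspPartition(
        pd.DataFrame(
            {
                "gsp_class": classes,
                "mean_relative_abundance": [1.0 / len(otus)] * len(otus),
                "occupancy": [1.0] * len(otus),
            },
            index=list(otus),
        )
    )


def link_count_network() -> nx.Graph:
    """A signed network realizing the printed per-pair link counts exactly.

    Nodes use the published class sizes; edges are laid out
    deterministically, positives first.
    """
    pools = {
        c: [f"{c}_{i:04d}" for i in range(CLASS_CENSUS[c]["OTUs"])]
        for c in GSP_CLASSES
    }
    g = nx.Graph()
    for c, nodes in pools.items():
        for n in nodes:
            g.add_node(n, gsp_class=c)
    for pair, (total, pos, neg) in LINK_COUNTS.items():
        a, b = pair.split("-")
        if a == b:
            candidates = itertools.combinations(pools[a], 2)
        else:
            candidates = itertools.product(pools[a], pools[b])
        for k, (u, v) in enumerate(itertools.islice(candidates, total)):
            sign = "+" if k < pos else "-"
            g.add_edge(u, v, r=0.9 if sign == "+" else -0.9, sign=sign,
                       adjusted_p=0.01, weight=0.9)
        assert total == pos + neg
    return g


def trait_sign_matrix() -> tuple[TraitMatrix, GspPartition]:
    """A sign matrix and partition realizing the printed trait counts."""
    otus: list[str] = []
    classes: list[str] = []
    rows: list[np.ndarray] = []
    for cls in GSP_CLASSES:
        n_class = CLASS_CENSUS[cls]["OTUs"]
        signs = np.zeros((n_class, len(ENV_INDICATORS)), dtype=int)
        for j, ind in enumerate(ENV_INDICATORS):
            pos, na, neg = TRAIT_COUNTS[cls][ind]
            if pos + na + neg != n_class:
                raise ValueError(f"inconsistent counts for {cls}/{ind}")
            signs[:pos, j] = 1
            signs[pos + na:, j] = -1
        for i in range(n_class):
            otus.append(f"{cls}_{i:04d}")
            classes.append(cls)
            rows.append(signs[i])
    tm = TraitMatrix(
        pd.DataFrame(np.array(rows), index=otus, columns=list(ENV_INDICATORS))
    )
    return tm, _uniform_partition(otus, classes)
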