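"""Hypergeometric gene-set over-representation with Bonferroni control.

Categories (gene classes, GO terms, anatomy/phenotype terms, ...) are
tested for over-representation in a query gene list against a universe
(by default the annotated genes on the censored array).  Categories
with fewer than three genes in the universe, or overlapping the query
in fewer than two genes, are removed before testing; the Bonferroni
multiplier is the number of categories actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnnotationSet:
    category: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"category {self.category!r} has no member genes")


def read_gmt(path) -> list[AnnotationSet]:
    """Read GMT-style annotations: category, source, then gene ids, tab-separated."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or line.startswith("#"):
                continue
            sets.append(AnnotationSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets: Sequence[AnnotationSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.category, s.source, *sorted(s.genes)]) + "\n")


def enrich(
    query: Iterable[str],
    annotations: Sequence[AnnotationSet],
    universe: Iterable[str],
    min_category: int = 3,
    min_overlap: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per category.

    p = P(X ≥ k) for X ~ Hypergeometric(N, K, n) with N the universe
    size, K the category size within the universe, n the query size and
    k the overlap.  Bonferroni-adjusted p divides alpha by the number
    of categories surviving the size/overlap filters.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_q = len(query)
    rows = []
    for ann in annotations:
        members = ann.genes & universe
        k_cat = len(members)
        k_hit = len(members & query)
        if k_cat < min_category or k_hit < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k_hit - 1, len(universe), k_cat, n_q))
        rows.append((ann.category, ann.source, len(universe), k_cat, n_q, k_hit, p))
    out = pd.DataFrame(
        rows, columns=["category", "source", "N", "K", "n", "k", "p"]
    )
    n_tested = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * max(n_tested, 1), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)
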