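"""Broad-sense heritability and transgressive segregation.

Heritability per spot is H² = (V_RIL − V_e)/V_RIL, with V_RIL the
variance among RIL samples and V_e the technical variance pooled (by
degrees of freedom) over the replicated parental and reference strains.
Transgression counts RIL samples beyond 3 pooled-SD boundaries around
the two parental means.  Both statistics get per-spot significance
thresholds from a permutation null: trait values are randomized over
the line designations ``n_perm`` times and the ⌈0.05·n_perm⌉-th highest
permuted value (the 50th for 1000 permutations) is the FDR = 0.05
threshold.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd

from .expression import PARENTAL, REFERENCE, RIL, ExpressionMatrix

StatisticFn = Callable[[np.ndarray], np.ndarray]
"""Maps a (draws × samples) value matrix to one statistic per draw."""


def threshold_from_null(null: np.ndarray, alpha: float = 0.05) -> float:
    """The ⌈alpha·n⌉-th highest value of a permutation null sample."""
    clean = np.where(np.isnan(null), -np.inf, np.asarray(null, dtype=float))
    k = math.ceil(alpha * clean.size)
    return float(np.sort(clean)[::-1][k - 1])


def permutation_threshold(
    statistic_fn: StatisticFn,
    values: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.Series:
    """Per-spot permutation threshold for an arbitrary statistic.

    For each spot (row), the sample values are permuted over the line
    designations ``n_perm`` times and the statistic recomputed on each
    draw; draws where the statistic is undefined count as −inf.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    x = values.to_numpy(dtype=float)
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        perms = rng.permuted(np.broadcast_to(x[i], (n_perm, x.shape[1])).copy(), axis=1)
        out[i] = threshold_from_null(statistic_fn(perms), alpha)
    return pd.Series(out, index=values.index, name="threshold")


def _replicate_groups(mat: ExpressionMatrix) -> list[np.ndarray]:
    """Column indices of each replicated parental/reference strain."""
    meta = mat.samples
    mask = meta["strain_class"].isin([PARENTAL, REFERENCE])
    groups = []
    for _, sub in meta[mask].groupby("line_id", sort=False):
        cols = np.flatnonzero(mat.values.columns.isin(sub.index))
        if len(cols) >= 2:
            groups.append(cols)
    return groups


def _h2_stat(ril_cols: np.ndarray, groups: list[np.ndarray]) -> StatisticFn:
    df_e = sum(len(g) - 1 for g in groups)

    def stat(x: np.ndarray) -> np.ndarray:
        v_ril = x[:, ril_cols].var(axis=1, ddof=1)
        ss = np.zeros(x.shape[0])
        for g in groups:
            sub = x[:, g]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        v_e = ss / df_e
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(v_ril > 0, (v_ril - v_e) / v_ril, np.nan)

    return stat


def heritability(
    mat: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    permute: bool = True,
) -> pd.DataFrame:
    """Broad-sense heritability per spot with permutation significance.

    Returns a DataFrame with ``V_RIL``, ``V_e``, ``H2`` (negative values
    reported as computed, NaN when V_RIL = 0), the permutation
    ``threshold`` and a ``significant`` flag (observed strictly above
    threshold).  With ``permute=False`` only the point estimates are
    returned.
    """
    ril_ids = mat.sample_ids(RIL)
    if len(ril_ids) < 2:
        raise ValueError("need at least two RIL samples")
    groups = _replicate_groups(mat)
    if not groups:
        raise ValueError("need replicated parental/reference strains for V_e")
    cols = mat.values.columns
    ril_cols = np.flatnonzero(cols.isin(ril_ids))
    stat = _h2_stat(ril_cols, groups)

    x = mat.values.to_numpy(dtype=float)
    v_ril = x[:, ril_cols].var(axis=1, ddof=1)
    df_e = sum(len(g) - 1 for g in groups)
    ss = np.zeros(x.shape[0])
    for g in groups:
        sub = x[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    v_e = ss / df_e
    h2 = stat(x)  # rows are spots here; the statistic is rowwise either way
    out = pd.DataFrame({"V_RIL": v_ril, "V_e": v_e, "H2": h2}, index=mat.values.index)
    if permute:
        out["threshold"] = permutation_threshold(stat, mat.values, n_perm, seed, alpha)
        out["significant"] = out["H2"] > out["threshold"]
    return out


def _transgression_stat(
    ril_cols: np.ndarray, parent_groups: list[np.ndarray]
) -> StatisticFn:
    (g1, g2) = parent_groups
    df = len(g1) + len(g2) - 2

    def stat(x: np.ndarray) -> np.ndarray:
        m1 = x[:, g1].mean(axis=1)
        m2 = x[:, g2].mean(axis=1)
        ss1 = ((x[:, g1] - m1[:, None]) ** 2).sum(axis=1)
        ss2 = ((x[:, g2] - m2[:, None]) ** 2).sum(axis=1)
        sigma = np.sqrt((ss1 + ss2) / df)
        low = np.minimum(m1, m2) - 3.0 * sigma
        high = np.maximum(m1, m2) + 3.0 * sigma
        ril = x[:, ril_cols]
        return ((ril < low[:, None]) | (ril > high[:, None])).sum(axis=1).astype(float)

    return stat


def transgression(
    mat: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    permute: bool = True,
) -> pd.DataFrame:
    """Count of transgressive RILs per spot with permutation significance.

    Boundaries are [min parental mean − 3σ, max parental mean + 3σ]
    with σ the pooled standard deviation of the two parental strains;
    the statistic counts RIL samples strictly outside.  Permutations
    shuffle values over RIL and parental samples jointly.
    """
    meta = mat.samples
    parents = meta[meta["strain_class"] == PARENTAL]
    lines = parents["line_id"].unique()
    if len(lines) != 2:
        raise ValueError("exactly two parental strains are required")
    used = list(mat.sample_ids(RIL)) + list(parents.index)
    sub = mat.values[used]
    cols = sub.columns
    ril_cols = np.flatnonzero(cols.isin(mat.sample_ids(RIL)))
    parent_groups = []
    for line in lines:
        g = np.flatnonzero(cols.isin(parents.index[parents["line_id"] == line]))
        if len(g) < 2:
            raise ValueError(f"parental strain {line!r} needs at least two replicates")
        parent_groups.append(g)
    stat = _transgression_stat(ril_cols, parent_groups)

    x = sub.to_numpy(dtype=float)
    m = np.stack([x[:, g].mean(axis=1) for g in parent_groups])
    s = np.stack(
        [((x[:, g] - x[:, g].mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in parent_groups]
    )
    sigma = np.sqrt(s.sum(axis=0) / (sum(len(g) for g in parent_groups) - 2))
    out = pd.DataFrame(
        {
            "mean_low": m.min(axis=0),
            "mean_high": m.max(axis=0),
            "pooled_sd": sigma,
            "lower": m.min(axis=0) - 3.0 * sigma,
            "upper": m.max(axis=0) + 3.0 * sigma,
            "n_transgressive": stat(x).astype(int),
        },
        index=mat.values.index,
    )
    if permute:
        out["threshold"] = permutation_threshold(stat, sub, n_perm, seed, alpha)
        out["significant"] = out["n_transgressive"] > out["threshold"]
    return out
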