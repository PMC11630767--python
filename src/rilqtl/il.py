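"""Introgression-line 2×2 factorial analysis and IL–RIL comparison.

Per spot and per IL set (the four strains descending from one cross),
batch-corrected expression is fitted to y ~ I + A + I·A with 0/1
coding: I is the introgression genotype (0 = N2 background, 1 = CB4856
introgression), A the transgene presence.  With this coding the I
coefficient is the introgression effect in the transgene-absent
background and the interaction coefficient shifts only the (1,1) cell.
Per-term p-values get a Benjamini–Hochberg adjustment across spots
within each set.  Effect sizes are compared with RIL eQTL effects for
genes whose eQTL peak falls inside the set's introgression window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

TERMS = ("I", "A", "IxA")


def fit_factorial(
    mat: ExpressionMatrix,
    design: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-spot, per-set least-squares fit of y ~ I + A + I·A.

    ``design`` is indexed by sample id with columns ``set``, ``I`` and
    ``A``.  Sets missing one of the four (I, A) cells, or with fewer
    than two replicates in a cell, are skipped with a warning.  Returns
    a long DataFrame (spot, set, term, estimate, p, q, significant)
    with BH-adjusted q-values per term within each set.
    """
    missing = set(design.index) - set(mat.values.columns)
    if missing:
        raise ValueError(f"design samples absent from expression matrix: {sorted(missing)[:5]}")
    frames = []
    for set_id, sub in design.groupby("set", sort=False):
        cells = sub.groupby(["I", "A"]).size()
        if len(cells) < 4 or (cells < 2).any():
            warnings.warn(f"set {set_id!r}: incomplete 2x2 design, skipped")
            continue
        y = mat.values[list(sub.index)].to_numpy(dtype=float)
        i_vec = sub["I"].to_numpy(dtype=float)
        a_vec = sub["A"].to_numpy(dtype=float)
        x = np.column_stack([np.ones_like(i_vec), i_vec, a_vec, i_vec * a_vec])
        n, p = x.shape
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = y @ (x @ xtx_inv)  # spots × 4
        resid = y - beta @ x.T
        df = n - p
        sigma2 = (resid**2).sum(axis=1) / df
        se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
        for k, term in enumerate(TERMS, start=1):
            pv = pvals[:, k]
            qv = multipletests(np.nan_to_num(pv, nan=1.0), method="fdr_bh")[1]
            frames.append(
                pd.DataFrame(
                    {
                        "spot": mat.values.index,
                        "set": set_id,
                        "term": term,
                        "estimate": beta[:, k],
                        "p": pv,
                        "q": qv,
                        "significant": qv <= q,
                    }
                )
            )
    if not frames:
        raise ValueError("no set had a complete 2x2 design")
    return pd.concat(frames, ignore_index=True)


def interaction_genes(effects: pd.DataFrame, spot_to_gene: pd.Series) -> list[str]:
    """Genes with a significant interaction in at least one set."""
    hits = effects[(effects["term"] == "IxA") & effects["significant"]]
    genes = spot_to_gene.reindex(hits["spot"]).dropna().unique()
    return sorted(genes)


def compare_il_ril(
    il_effects: pd.DataFrame,
    ril_records: pd.DataFrame,
    window: tuple[str, int, int],
    set_id: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation of IL term estimates with RIL eQTL effects.

    Restricts to spots whose RIL eQTL peak lies inside ``window``
    (chrom, start, end — the set's introgression interval), joins on
    spot id, and reports r with its two-sided test p-value per set and
    term.  Fewer than three overlapping spots yields NaN.
    """
    chrom, start, end = window
    in_window = ril_records[
        (ril_records["chrom"] == chrom)
        & (ril_records["peak_pos"] >= start)
        & (ril_records["peak_pos"] <= end)
    ][["spot", "effect"]].drop_duplicates("spot")
    sub = il_effects if set_id is None else il_effects[il_effects["set"] == set_id]
    rows = []
    for (sid, term), grp in sub.groupby(["set", "term"], sort=False):
        joined = in_window.merge(grp[["spot", "estimate"]], on="spot")
        n = len(joined)
        if n < 3:
            warnings.warn(f"set {sid!r} term {term}: {n} overlapping genes, correlation undefined")
            rows.append((sid, term, n, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(joined["effect"], joined["estimate"])
        rows.append((sid, term, n, float(r), float(p)))
    return pd.DataFrame(rows, columns=["set", "term", "n", "r", "p"])
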