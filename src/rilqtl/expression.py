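"""Expression-matrix preprocessing.

Covers the preprocessing contract of a two-colour microarray pipeline:
spot censoring, within-array loess + between-array quantile
normalization, the log2-ratio-with-mean transform feeding principal
components, additive batch correction, and dual-reference qPCR
quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

#: sample strain classes
RIL = "RIL"
PARENTAL = "parental"
REFERENCE = "reference"
IL = "IL"


@dataclass
class ExpressionMatrix:
    """Spots × samples log2 intensities with spot and sample annotation.

    ``spots`` is indexed by spot id with columns ``gene_id`` (may be
    missing), ``chrom``, ``pos_bp`` and ``is_technical``; ``samples`` is
    indexed by sample id with columns ``line_id``, ``strain_class``
    (one of ``RIL``/``parental``/``reference``/``IL``) and ``batch``.
    """

    values: pd.DataFrame
    spots: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.spots.index):
            raise ValueError("values and spot annotation indices differ")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample metadata differ")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def sample_ids(self, strain_class: str) -> list[str]:
        return list(self.samples.index[self.samples["strain_class"] == strain_class])

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(ids)], self.spots, self.samples.loc[list(ids)])


@dataclass
class CtTable:
    """qPCR cycle-threshold values, samples × genes.

    ``scale`` records the transformed-abundance unit (``2**-ref_ct``) a
    simulator used for its reference genes, so recovered relative
    abundances can be put back on the simulated ratio scale.
    """

    ct: pd.DataFrame
    scale: float = 1.0

    def __post_init__(self) -> None:
        if (self.ct.to_numpy() <= 0).any():
            raise ValueError("Ct values must be positive")


def censor_spots(mat: ExpressionMatrix, censor_list: Iterable[str] = ()) -> ExpressionMatrix:
    """Drop technical spots and spots on the censor list, preserving order."""
    censor = set(censor_list)
    unknown = censor - set(mat.spots.index)
    if unknown:
        warnings.warn(f"{len(unknown)} censor-list spot ids not on the array; skipped")
        censor -= unknown
    keep = ~(mat.spots["is_technical"].astype(bool) | mat.spots.index.isin(censor))
    return ExpressionMatrix(mat.values.loc[keep], mat.spots.loc[keep], mat.samples)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns.

    Each column's values are replaced by the across-column mean of the
    order statistics at their rank; tied values receive the mean of the
    rank means they span (average-rank policy), making the result
    deterministic.
    """
    x = values.to_numpy(dtype=float)
    n = x.shape[0]
    rank_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        sorted_vals = x[order, j]
        assigned = rank_means.copy()
        starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        sizes = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(rank_means, starts) / sizes
        assigned = np.repeat(group_means, sizes)
        out[order, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def loess_ma_correct(red: pd.DataFrame, green: pd.DataFrame, frac: float = 0.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-array intensity-dependent loess correction of log-ratios.

    For each array, M = log2(R/G) is recentred on its loess fit against
    A = 0.5·log2(R·G), removing dye/intensity bias, and the corrected
    log2 channel intensities are reconstructed as A ± M'/2.
    """
    if (red.to_numpy() <= 0).any() or (green.to_numpy() <= 0).any():
        raise ValueError("raw intensities must be strictly positive")
    r = np.log2(red.to_numpy(dtype=float))
    g = np.log2(green.to_numpy(dtype=float))
    m = r - g
    a = 0.5 * (r + g)
    mc = np.empty_like(m)
    for j in range(m.shape[1]):
        if np.allclose(m[:, j], m[0, j]) or np.allclose(a[:, j], a[0, j]):
            fit = np.full(m.shape[0], m[:, j].mean())
        else:
            fit = lowess(m[:, j], a[:, j], frac=frac, return_sorted=False)
        mc[:, j] = m[:, j] - fit
    log_r = a + mc / 2.0
    log_g = a - mc / 2.0
    return (
        pd.DataFrame(log_r, index=red.index, columns=red.columns),
        pd.DataFrame(log_g, index=green.index, columns=green.columns),
    )


def normalize(red: pd.DataFrame, green: pd.DataFrame, frac: float = 0.3) -> pd.DataFrame:
    """Loess within-array, then quantile between-array normalization.

    Returns log2 intensities with one column per array channel
    (``<array>.R`` / ``<array>.G``); after the quantile step every
    column has identical sorted values.
    """
    log_r, log_g = loess_ma_correct(red, green, frac=frac)
    stacked = pd.concat(
        [log_r.rename(columns=lambda c: f"{c}.R"), log_g.rename(columns=lambda c: f"{c}.G")], axis=1
    )
    return quantile_normalize(stacked)


def log_ratio_with_mean(values: pd.DataFrame) -> pd.DataFrame:
    """Per-spot log2 ratio to the mean intensity over samples.

    R_ij = log2( y_ij / mean_j(y_i) ), where y = 2**values is the
    intensity (not log) scale.  Invariant to per-spot multiplicative
    scaling of intensities.
    """
    y = np.exp2(values.to_numpy(dtype=float))
    mean = y.mean(axis=1, keepdims=True)
    if np.any(mean == 0):
        raise ValueError("zero mean intensity for at least one spot")
    return pd.DataFrame(np.log2(y / mean), index=values.index, columns=values.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame      # samples × components
    loadings: pd.DataFrame    # spots × components
    var_frac: pd.Series


def principal_components(transformed: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal components of samples from a spots × samples matrix.

    Singular value decomposition of the sample-by-spot matrix after
    column centering.  Components are signed so the largest-magnitude
    loading is positive; variance fractions sum to 1.
    """
    if transformed.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = transformed.to_numpy(dtype=float).T  # samples × spots
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(xc):
        raise ValueError("degenerate (constant) matrix")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=transformed.columns, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=transformed.index, columns=comps)
    var = s**2
    var_frac = pd.Series((var / var.sum())[:k], index=comps, name="var_frac")
    return PCAResult(scores, loadings, var_frac)


def batch_correct(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Remove additive per-batch offsets per spot.

    Per spot, each batch's mean deviation from the spot's grand mean is
    subtracted from that batch's samples, so per-spot batch means
    coincide afterwards while the grand mean is preserved.  Idempotent;
    a single-batch matrix is returned unchanged with a warning.
    """
    batches = mat.samples["batch"]
    if batches.nunique() < 2:
        warnings.warn("single batch: batch correction is the identity")
        return ExpressionMatrix(mat.values.copy(), mat.spots, mat.samples)
    x = mat.values.to_numpy(dtype=float).copy()
    grand = x.mean(axis=1, keepdims=True)
    for b in batches.unique():
        cols = np.flatnonzero((batches == b).to_numpy())
        x[:, cols] -= x[:, cols].mean(axis=1, keepdims=True) - grand
    return ExpressionMatrix(pd.DataFrame(x, index=mat.values.index, columns=mat.values.columns), mat.spots, mat.samples)


DEFAULT_REFERENCES = ("rpl-6", "Y37E3.8")


def qpcr_relative_abundance(
    table: CtTable,
    targets: Sequence[str],
    references: Sequence[str] = DEFAULT_REFERENCES,
    efficiency: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Relative abundance of target genes against two reference genes.

    Transformed abundance Q = (1+eff)**(-Ct) with eff = 1 by default
    (perfect amplification, Q = 2**-Ct).  For target v,

        E_v = Q_v / ( 0.5 * (Q_ref1/mean(Q_ref1) + Q_ref2/mean(Q_ref2)) )

    where the means run over samples.  With a single sample both
    denominator terms are 1 and E_v = Q_v.
    """
    missing = [g for g in list(targets) + list(references) if g not in table.ct.columns]
    if missing:
        raise ValueError(f"genes absent from Ct table: {missing}")
    if len(references) != 2:
        raise ValueError("exactly two reference genes are required")
    eff = dict(efficiency or {})

    def q(gene: str) -> np.ndarray:
        base = 1.0 + eff.get(gene, 1.0)
        return base ** (-table.ct[gene].to_numpy(dtype=float))

    r1, r2 = (q(g) for g in references)
    denom = 0.5 * (r1 / r1.mean() + r2 / r2.mean())
    out = {t: q(t) / denom for t in targets}
    return pd.DataFrame(out, index=table.ct.index)
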