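"""Single-marker eQTL mapping and downstream genome-level analyses.

The scan regresses each spot's log2 expression on each marker's 0/1
genotype (y ~ x + e); the p-value is the two-sided t test on the slope,
equivalently the 1-df F test.  The genome-wide significance threshold is
empirical: each spot's values are permuted over lines, the permuted
datasets are scanned identically, and the cutoff is the smallest value
whose ratio of mean permuted discoveries (FDS) to real discoveries
(RDS) satisfies the configured inequality.  Downstream: power analysis
by planting QTL at every marker, peak calling with 1.5-drop confidence
intervals and cis/trans classification, ANOVA variance explained,
per-gene representative spots, and Poisson trans-band detection in
0.5 Mb bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import RIL, ExpressionMatrix
from .genotypes import P1, P2, GenotypeMatrix

#: -log10(p) cap for numerically zero p-values
NEGLOGP_CAP = 300.0
_LN10 = math.log(10.0)


@dataclass
class EqtlScan:
    """Spots × markers −log10(p) and signed allelic effects."""

    neglogp: pd.DataFrame
    effect: pd.DataFrame
    markers: pd.DataFrame

    def best_per_spot(self) -> pd.DataFrame:
        """Peak marker, score and effect per spot (genome-wide max)."""
        nlp = self.neglogp.to_numpy()
        safe = np.where(np.isnan(nlp), -np.inf, nlp)
        j = safe.argmax(axis=1)
        rows = np.arange(len(nlp))
        return pd.DataFrame(
            {
                "marker": self.neglogp.columns[j],
                "neglogp": safe[rows, j],
                "effect": self.effect.to_numpy()[rows, j],
            },
            index=self.neglogp.index,
        )


@dataclass
class FdrThreshold:
    """Empirical FDS/RDS threshold bookkeeping."""

    q: float
    m: int
    m0: int
    variant: str
    cutoff: float
    rds: int
    fds: float
    table: pd.DataFrame = field(repr=False)

    @property
    def bound(self) -> float:
        if self.variant == "plain":
            return self.q
        return self.m0 / self.m * self.q * math.log(self.m)


@dataclass
class TransBandResult:
    """Per-bin trans-eQTL counts and merged flagged runs."""

    bands: pd.DataFrame
    merged: pd.DataFrame
    lam: float
    total_bins: int


def _neglogp_from_r2(r2: np.ndarray, df: int | np.ndarray) -> np.ndarray:
    r2c = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = df * r2c / (1.0 - r2c)
        nlp = -stats.f.logsf(f, 1, df) / _LN10
    nlp = np.where(np.isnan(r2), np.nan, nlp)
    return np.minimum(nlp, NEGLOGP_CAP)


def _r2_effect(y: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group R² and signed effect for every spot × marker pair.

    ``y`` is spots × lines, ``g`` markers × lines with entries in {0,1}.
    Marker columns that are monomorphic come back NaN.
    """
    n = y.shape[1]
    n1 = g.sum(axis=1)
    n0 = n - n1
    valid = (n1 > 0) & (n0 > 0)
    s1 = y @ g.T
    sy = y.sum(axis=1, keepdims=True)
    syy = (y**2).sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / n1
        mean0 = (sy - s1) / n0
        ss_t = syy - sy**2 / n
        ss_b = n1 * mean1**2 + n0 * mean0**2 - sy**2 / n
        r2 = np.where(ss_t > 0, ss_b / ss_t, np.nan)
        effect = mean1 - mean0
    r2[:, ~valid] = np.nan
    effect[:, ~valid] = np.nan
    return r2, effect


def _align(mat: ExpressionMatrix | pd.DataFrame, geno: GenotypeMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression rows × mapped lines and the matching genotype codes."""
    if isinstance(mat, ExpressionMatrix):
        ids = mat.sample_ids(RIL)
        lines = mat.samples.loc[ids, "line_id"]
        missing = set(lines) - set(geno.lines)
        if missing:
            raise ValueError(f"samples map to lines absent from the genotype matrix: {sorted(missing)[:5]}")
        y = mat.values[ids]
        g = geno.calls[list(lines)].to_numpy(dtype=np.int8)
    else:
        missing = set(mat.columns) - set(geno.lines)
        if missing:
            raise ValueError(f"expression lines absent from the genotype matrix: {sorted(missing)[:5]}")
        y = mat
        g = geno.calls[list(mat.columns)].to_numpy(dtype=np.int8)
    return y, g


def scan(mat: ExpressionMatrix | pd.DataFrame, geno: GenotypeMatrix) -> EqtlScan:
    """Single-marker scan of every spot against every marker.

    Heterozygous and missing genotype calls are dropped marker-wise;
    markers left monomorphic produce NaN columns.  −log10(p) is capped
    at 300.
    """
    y_df, g = _align(mat, geno)
    y = y_df.to_numpy(dtype=float)
    clean = np.isin(g, (P1, P2)).all()
    if clean:
        r2, effect = _r2_effect(y, g.astype(float))
        nlp = _neglogp_from_r2(r2, y.shape[1] - 2)
    else:
        nlp = np.full((y.shape[0], g.shape[0]), np.nan)
        effect = np.full_like(nlp, np.nan)
        for j in range(g.shape[0]):
            ok = np.isin(g[j], (P1, P2))
            if ok.sum() < 3:
                continue
            r2_j, eff_j = _r2_effect(y[:, ok], g[j : j + 1, ok].astype(float))
            nlp[:, j] = _neglogp_from_r2(r2_j[:, 0], ok.sum() - 2)
            effect[:, j] = eff_j[:, 0]
    idx = y_df.index
    cols = geno.markers.index
    return EqtlScan(
        pd.DataFrame(nlp, index=idx, columns=cols),
        pd.DataFrame(effect, index=idx, columns=cols),
        geno.markers,
    )


def _best_scores_clean(y: np.ndarray, g01: np.ndarray, chunk: int = 8000) -> tuple[np.ndarray, np.ndarray]:
    """Per-spot best marker index and −log10(p) on a clean 0/1 map.

    With a constant residual df across markers, p is monotone in R², so
    the peak is the argmax of R² and the tail probability is evaluated
    only there.
    """
    n = y.shape[1]
    best_idx = np.empty(y.shape[0], dtype=np.int64)
    best_r2 = np.empty(y.shape[0])
    for lo in range(0, y.shape[0], chunk):
        r2, _ = _r2_effect(y[lo : lo + chunk], g01)
        safe = np.where(np.isnan(r2), -np.inf, r2)
        j = safe.argmax(axis=1)
        rows = np.arange(len(j))
        best_idx[lo : lo + chunk] = j
        best_r2[lo : lo + chunk] = safe[rows, j]
    return best_idx, _neglogp_from_r2(best_r2, n - 2)


def best_scores(mat: ExpressionMatrix | pd.DataFrame, geno: GenotypeMatrix) -> pd.DataFrame:
    """Genome-wide peak marker and score per spot (fast path on clean maps)."""
    y_df, g = _align(mat, geno)
    if np.isin(g, (P1, P2)).all():
        idx, nlp = _best_scores_clean(y_df.to_numpy(dtype=float), g.astype(float))
        return pd.DataFrame(
            {"marker": geno.markers.index[idx], "neglogp": nlp}, index=y_df.index
        )
    full = scan(y_df, geno)
    return full.best_per_spot()[["marker", "neglogp"]]


def permuted_best_scores(
    mat: ExpressionMatrix | pd.DataFrame,
    geno: GenotypeMatrix,
    n_datasets: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-spot best scores for permuted datasets (datasets × spots).

    Each dataset permutes every spot's values over lines independently
    and is scanned with the original map.
    """
    if n_datasets < 1:
        raise ValueError("need at least one permuted dataset")
    y_df, _ = _align(mat, geno)
    rng = np.random.default_rng(seed)
    out = np.empty((n_datasets, y_df.shape[0]))
    for d in range(n_datasets):
        perm = pd.DataFrame(
            rng.permuted(y_df.to_numpy(dtype=float), axis=1),
            index=y_df.index,
            columns=y_df.columns,
        )
        out[d] = best_scores(perm, geno)["neglogp"].to_numpy()
    return out


def empirical_fdr(
    best_real: pd.Series | np.ndarray,
    best_permuted: np.ndarray,
    q: float = 0.05,
    variant: str = "plain",
    m: int | None = None,
    m0: int | None = None,
) -> FdrThreshold:
    """Choose the −log10(p) cutoff from real and permuted peak scores.

    At each candidate cutoff c (the observed per-spot peak scores), RDS
    counts real spots with peak ≥ c and FDS the mean of that count over
    the permuted datasets.  The chosen cutoff is the smallest c with
    FDS/RDS ≤ q (variant ``plain``) or ≤ (m0/m)·q·ln(m) (variant
    ``paper``).
    """
    real = np.asarray(best_real, dtype=float)
    real = real[np.isfinite(real)]
    if variant not in ("plain", "paper"):
        raise ValueError("variant must be 'plain' or 'paper'")
    m = int(m if m is not None else real.size)
    m0 = int(m0 if m0 is not None else m)
    bound = q if variant == "plain" else m0 / m * q * math.log(m)

    cand = np.unique(real)  # ascending
    real_sorted = np.sort(real)
    perm_sorted = np.sort(best_permuted[np.isfinite(best_permuted)])
    rds = real.size - np.searchsorted(real_sorted, cand, side="left")
    fds = (perm_sorted.size - np.searchsorted(perm_sorted, cand, side="left")) / best_permuted.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rds > 0, fds / rds, np.inf)
    table = pd.DataFrame({"cutoff": cand, "rds": rds, "fds": fds, "ratio": ratio})
    ok = np.flatnonzero(ratio <= bound)
    if ok.size == 0:
        warnings.warn("no cutoff attains the FDS/RDS bound; threshold undefined")
        return FdrThreshold(q, m, m0, variant, math.nan, 0, math.nan, table)
    i = ok[0]
    return FdrThreshold(q, m, m0, variant, float(cand[i]), int(rds[i]), float(fds[i]), table)


def power_analysis(
    geno: GenotypeMatrix,
    cutoff: float = 4.3,
    ve_grid: np.ndarray | None = None,
    n_per_marker: int = 10,
    seed: int = 0,
    link_r: float = 0.5,
    chunk: int = 5000,
) -> pd.DataFrame:
    """Detection power of the scan for planted QTL at every marker.

    For each variance-explained level, ``n_per_marker`` phenotypes are
    simulated per (polymorphic) marker as its genotype plus Gaussian
    noise scaled to the target VE, then scanned.  A QTL is detected
    when the genome-wide peak exceeds ``cutoff`` and the peak marker is
    the causal one or linked to it (|genotype correlation| ≥
    ``link_r``).  Returns one row per VE level with the detection
    fraction.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if ve_grid is None:
        ve_grid = np.round(np.arange(0.20, 0.801, 0.05), 2)
    ve_grid = np.asarray(ve_grid, dtype=float)
    if np.any((ve_grid <= 0) | (ve_grid >= 1)):
        raise ValueError("variance-explained levels must lie in (0, 1)")
    g = geno.codes().astype(float)
    poly = (g.min(axis=1) != g.max(axis=1)) & np.isin(geno.codes(), (P1, P2)).all(axis=1)
    g01 = g[poly]
    m, n = g01.shape
    if m == 0:
        raise ValueError("no polymorphic markers")
    sd_g = g01.std(axis=1)  # population SD over lines
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(g01)
    rng = np.random.default_rng(seed)
    rows = []
    causal = np.repeat(np.arange(m), n_per_marker)
    for ve in ve_grid:
        noise_sd = sd_g * np.sqrt((1.0 - ve) / ve)
        y = np.repeat(g01, n_per_marker, axis=0)
        y += rng.normal(0.0, 1.0, size=y.shape) * np.repeat(noise_sd, n_per_marker)[:, None]
        best_idx, nlp = _best_scores_clean(y, g01, chunk=chunk)
        linked = np.abs(corr[best_idx, causal]) >= link_r
        detected = (nlp > cutoff) & linked
        rows.append((ve, y.shape[0], int(detected.sum()), detected.mean()))
    return pd.DataFrame(rows, columns=["ve", "n_sim", "n_detected", "power"])


def pooled_power(table: pd.DataFrame, min_ve: float = 0.35) -> float:
    """Detection fraction pooled over VE levels at or above ``min_ve``."""
    sub = table[table["ve"] >= min_ve - 1e-9]
    if sub.empty:
        raise ValueError("no VE levels at or above min_ve")
    return float(sub["n_detected"].sum() / sub["n_sim"].sum())


def call_peaks_and_intervals(
    scan_result: EqtlScan,
    cutoff: float,
    spots: pd.DataFrame | None = None,
    drop: float = 1.5,
) -> pd.DataFrame:
    """Peaks above the cutoff with drop-based confidence intervals.

    Per spot and chromosome, the peak is the marker with the maximum
    −log10(p) when that maximum reaches ``cutoff`` (at most one peak per
    chromosome).  The interval extends contiguously from the peak in
    both directions while markers stay ≥ peak − ``drop``, truncated at
    chromosome ends.  An eQTL is ``cis`` when the annotated gene
    position lies within the interval's physical span (inclusive),
    otherwise ``trans``; spots without gene annotation are ``trans``
    and flagged.
    """
    nlp_all = scan_result.neglogp.to_numpy()
    markers = scan_result.markers
    records = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = np.flatnonzero(markers.index.isin(sub.index))
        nlp = nlp_all[:, idx]
        safe = np.where(np.isnan(nlp), -np.inf, nlp)
        peak_j = safe.argmax(axis=1)
        peak_val = safe[np.arange(len(safe)), peak_j]
        hits = np.flatnonzero(peak_val >= cutoff)
        pos = sub["pos_bp"].to_numpy()
        for i in hits:
            j = peak_j[i]
            floor = peak_val[i] - drop
            lo = j
            while lo > 0 and safe[i, lo - 1] >= floor:
                lo -= 1
            hi = j
            while hi < len(idx) - 1 and safe[i, hi + 1] >= floor:
                hi += 1
            spot = scan_result.neglogp.index[i]
            gene_id, gchrom, gpos = None, None, None
            if spots is not None and spot in spots.index:
                row = spots.loc[spot]
                gene_id = row.get("gene_id")
                gchrom = row.get("chrom")
                gpos = row.get("pos_bp")
            annotated = (
                gene_id is not None
                and not (isinstance(gene_id, float) and math.isnan(gene_id))
                and gpos is not None
                and not (isinstance(gpos, float) and math.isnan(gpos))
            )
            cis = bool(annotated and gchrom == chrom and pos[lo] <= gpos <= pos[hi])
            records.append(
                {
                    "spot": spot,
                    "gene_id": gene_id if annotated else None,
                    "chrom": chrom,
                    "peak_marker": sub.index[j],
                    "peak_pos": int(pos[j]),
                    "neglogp": float(peak_val[i]),
                    "effect": float(scan_result.effect.iloc[i, idx[j]]),
                    "interval_start_marker": sub.index[lo],
                    "interval_end_marker": sub.index[hi],
                    "interval_start": int(pos[lo]),
                    "interval_end": int(pos[hi]),
                    "qtl_class": "cis" if cis else "trans",
                    "unannotated": not annotated,
                }
            )
    cols = [
        "spot", "gene_id", "chrom", "peak_marker", "peak_pos", "neglogp", "effect",
        "interval_start_marker", "interval_end_marker", "interval_start", "interval_end",
        "qtl_class", "unannotated",
    ]
    return pd.DataFrame(records, columns=cols)


def variance_explained(
    mat: ExpressionMatrix | pd.DataFrame,
    geno: GenotypeMatrix,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Single-factor ANOVA R² at each record's peak marker.

    R² = SS_genotype / SS_total, computed per peak even for spots with
    multiple peaks; identical to the squared Pearson correlation of
    expression with the 0/1 genotype.  Degenerate groups give NaN.
    """
    y_df, g = _align(mat, geno)
    y = y_df.to_numpy(dtype=float)
    marker_pos = {mk: i for i, mk in enumerate(geno.markers.index)}
    spot_pos = {s: i for i, s in enumerate(y_df.index)}
    r2 = np.empty(len(records))
    for k, (spot, mk) in enumerate(zip(records["spot"], records["peak_marker"])):
        gj = g[marker_pos[mk]]
        ok = np.isin(gj, (P1, P2))
        yv = y[spot_pos[spot], ok]
        gv = gj[ok].astype(float)
        if gv.min() == gv.max() or yv.std() == 0:
            r2[k] = np.nan
            continue
        r2_k, _ = _r2_effect(yv[None, :], gv[None, :])
        r2[k] = r2_k[0, 0]
    out = records.copy()
    out["r2"] = r2
    return out


def best_spot_per_gene(records: pd.DataFrame) -> pd.DataFrame:
    """One representative record per (gene, peak chromosome).

    The spot with the highest variance explained wins; ties break
    toward the higher peak −log10(p), then the lexicographically
    smaller spot id.
    """
    if records.empty:
        return records.copy()
    annotated = records[records["gene_id"].notna()].copy()
    ranked = annotated.sort_values(
        by=["r2", "neglogp", "spot"], ascending=[False, False, True], kind="stable"
    )
    return (
        ranked.groupby(["gene_id", "chrom"], sort=False, as_index=False)
        .head(1)
        .sort_index()
    )


def detect_trans_bands(
    records: pd.DataFrame,
    geno: GenotypeMatrix,
    bin_bp: int = 500_000,
    p_cut: float = 1e-3,
) -> TransBandResult:
    """Poisson over-representation of trans-eQTL in genomic bins.

    Peak positions of trans records are counted in half-open
    [start, start + bin_bp) bins covering the marker map's extent; the
    expected count λ is uniform (total trans-eQTL / total bins) and a
    bin is flagged when the Poisson upper tail P(X ≥ observed) is below
    ``p_cut``.  Adjacent flagged bins are additionally reported merged.
    """
    trans = records[records["qtl_class"] == "trans"]
    extents = geno.markers.groupby("chrom", sort=False)["pos_bp"].max()
    if trans.empty:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "count", "lam", "p", "flagged"])
        return TransBandResult(empty, empty.copy(), 0.0, int(np.ceil(extents / bin_bp).sum()))
    rows = []
    total_bins = 0
    for chrom, extent in extents.items():
        n_bins = int(np.ceil(extent / bin_bp))
        total_bins += n_bins
        sub = trans[trans["chrom"] == chrom]
        counts = np.bincount(sub["peak_pos"].to_numpy() // bin_bp, minlength=n_bins)
        for b in range(n_bins):
            rows.append((chrom, b * bin_bp, (b + 1) * bin_bp, int(counts[b])))
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    lam = len(trans) / total_bins
    bands["lam"] = lam
    bands["p"] = stats.poisson.sf(bands["count"] - 1, lam)
    bands["flagged"] = bands["p"] < p_cut
    merged_rows = []
    for chrom, sub in bands.groupby("chrom", sort=False):
        flag = sub["flagged"].to_numpy()
        start = None
        for i in range(len(sub) + 1):
            on = i < len(sub) and flag[i]
            if on and start is None:
                start = i
            elif not on and start is not None:
                run = sub.iloc[start:i]
                merged_rows.append(
                    (chrom, int(run["start"].iloc[0]), int(run["end"].iloc[-1]), int(run["count"].sum()))
                )
                start = None
    merged = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "count"])
    return TransBandResult(bands, merged, lam, total_bins)
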