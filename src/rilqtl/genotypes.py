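"""Genotype matrices for inbred-line panels.

A recombinant inbred line (RIL) genome is a mosaic of the two parental
genomes.  Calls are coded ``0`` (parent 1), ``1`` (parent 2), ``HET`` for
residual heterozygosity and ``NA`` for missing.  This module houses the
container, the rules for merging sequencing- and PCR-based call sets,
blank fill-in and nearest-marker prediction, and genetic-map summaries
(crossover breakpoints, allele frequencies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype codes
P1 = 0
P2 = 1
HET = 2
NA = -1

_CODE_STR = {P1: "0", P2: "1", HET: "H", NA: "NA"}
_STR_CODE = {v: k for k, v in _CODE_STR.items()}


@dataclass
class GenotypeMatrix:
    """Markers × lines genotype calls with a physical marker map.

    Parameters
    ----------
    markers
        DataFrame indexed by marker id with columns ``chrom`` and
        ``pos_bp`` (1-based, inclusive).  Positions must be strictly
        increasing within each chromosome.
    calls
        DataFrame of int codes (``0``/``1``/``HET``/``NA``), indexed like
        ``markers``, one column per line.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.markers.index.equals(self.calls.index):
            raise ValueError("markers and calls must share the same marker index")
        if self.calls.columns.duplicated().any():
            raise ValueError("line ids must be unique")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")

    @property
    def lines(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def codes(self) -> np.ndarray:
        """Calls as an int8 array (markers × lines)."""
        return self.calls.to_numpy(dtype=np.int8)

    def chrom_markers(self, chrom: str) -> pd.Index:
        return self.markers.index[self.markers["chrom"] == chrom]


@dataclass
class MapSummary:
    """Genetic-map summary statistics.

    ``breakpoints`` counts adjacent-marker genotype changes per line and
    chromosome (lines × chromosomes); ``allele_freq`` is the per-marker
    fraction of parent-2 calls among non-missing calls;
    ``n_informative`` counts markers at which both parental alleles are
    observed.
    """

    breakpoints: pd.DataFrame
    allele_freq: pd.Series
    n_informative: int


def _runs(values: np.ndarray) -> np.ndarray:
    """Run id of consecutive equal values (NA breaks runs)."""
    change = np.ones(len(values), dtype=bool)
    change[1:] = values[1:] != values[:-1]
    return np.cumsum(change) - 1


def integrate_genotypes(seq: GenotypeMatrix, pcr: GenotypeMatrix) -> GenotypeMatrix:
    """Merge sequencing-based and PCR-based genotype calls.

    Non-conflicting calls pass through (union of markers and lines).  Where
    both platforms call the same marker/line and disagree, the sequencing
    call wins when it is supported by a run of at least two consecutive
    sequencing markers with the same call on that chromosome (strong
    evidence); an isolated single-marker sequencing call is overruled by
    the PCR call.
    """
    common_lines = [l for l in seq.lines if l in set(pcr.lines)]
    if not common_lines:
        raise ValueError("sequencing and PCR call sets share no lines")

    marker_tab = pd.concat([seq.markers, pcr.markers.loc[pcr.markers.index.difference(seq.markers.index)]])
    marker_tab = marker_tab.sort_values(["chrom", "pos_bp"], kind="stable")
    lines = list(dict.fromkeys(seq.lines + pcr.lines))

    out = pd.DataFrame(NA, index=marker_tab.index, columns=lines, dtype=np.int8)
    for src in (pcr, seq):  # seq second: non-conflicting seq calls win by default
        out.loc[src.calls.index, src.lines] = out.loc[src.calls.index, src.lines].where(
            src.calls.to_numpy() == NA, src.calls
        )

    # resolve conflicts at markers present in both platforms
    shared = seq.markers.index.intersection(pcr.markers.index)
    both = [l for l in lines if l in set(seq.lines) and l in set(pcr.lines)]
    for line in both:
        s_all = seq.calls[line]
        for chrom, sub in seq.markers.groupby("chrom", sort=False):
            s = s_all.loc[sub.index].to_numpy()
            run_id = _runs(s)
            run_len = np.bincount(run_id)[run_id]
            for i, mk in enumerate(sub.index):
                if mk not in shared:
                    continue
                p = pcr.calls.at[mk, line]
                if s[i] == NA or p == NA or s[i] == p:
                    continue
                out.at[mk, line] = s[i] if run_len[i] >= 2 else p
    return GenotypeMatrix(marker_tab, out)


def fill_blanks(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls flanked by agreeing non-missing calls.

    For each line and chromosome, an ``NA`` run whose nearest non-missing
    neighbours on both sides carry the same genotype is set to that
    genotype; runs with disagreeing or absent flanks are left missing.
    Idempotent.
    """
    filled = geno.calls.copy()
    for chrom, sub in geno.markers.groupby("chrom", sort=False):
        block = filled.loc[sub.index].astype(float).replace(NA, np.nan)
        fwd = block.ffill()
        bwd = block.bfill()
        agree = block.isna() & (fwd == bwd)
        block = block.where(~agree, fwd)
        filled.loc[sub.index] = block.fillna(NA).astype(np.int8)
    return GenotypeMatrix(geno.markers, filled)


def nearest_marker_impute(geno: GenotypeMatrix, chrom: str, pos_bp: int, line: str) -> int:
    """Predict a genotype at an arbitrary position from the closest called marker.

    Returns the call of the physically closest non-missing marker on the
    chromosome; exact distance ties resolve to the lower coordinate.
    Returns ``NA`` when the chromosome has no non-missing call for the line.
    """
    sub = geno.markers[geno.markers["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    calls = geno.calls.loc[sub.index, line].to_numpy()
    ok = calls != NA
    if not ok.any():
        return NA
    pos = sub["pos_bp"].to_numpy()[ok]
    dist = np.abs(pos - pos_bp)
    # stable argmin on (distance, position) implements the lower-coordinate tie rule
    order = np.lexsort((pos, dist))
    return int(calls[ok][order[0]])


def summarize_map(geno: GenotypeMatrix) -> MapSummary:
    """Breakpoint counts, allele frequencies and informative-marker count.

    A breakpoint is a change between consecutive homozygous calls of a
    line along a chromosome; missing and heterozygous calls are skipped,
    so a change across a gap counts once.
    """
    chroms = geno.chroms
    bp = pd.DataFrame(0, index=geno.lines, columns=chroms, dtype=int)
    for chrom in chroms:
        sub = geno.calls.loc[geno.chrom_markers(chrom)].to_numpy()
        for j, line in enumerate(geno.lines):
            v = sub[:, j]
            hom = v[(v == P1) | (v == P2)]
            bp.at[line, chrom] = int(np.sum(hom[1:] != hom[:-1])) if hom.size else 0
    codes = geno.codes()
    non_na = (codes != NA).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = (codes == P2).sum(axis=1) / non_na
    allele_freq = pd.Series(freq, index=geno.markers.index, name="p2_freq")
    informative = int((((codes == P1).any(axis=1)) & ((codes == P2).any(axis=1))).sum())
    return MapSummary(bp, allele_freq, informative)
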