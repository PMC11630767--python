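"""Synthetic data with the statistical structure of a RIL eQTL study.

Generates genotype maps for a two-parent recombinant inbred panel
(piecewise-constant parental blocks with Poisson-process breakpoints and
an optional fixed single-parent region), spot-level expression matrices
with planted cis-eQTL, trans-eQTL hotspots, transgressive two-locus
architectures and configurable heritability, 2×2 factorial
introgression-line experiments with batch effects, and qPCR Ct tables.
Every generator is bit-reproducible under a fixed seed and returns a
truth table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import IL, PARENTAL, REFERENCE, RIL, CtTable, ExpressionMatrix
from .genotypes import HET, NA, GenotypeMatrix

#: C. elegans-like chromosome lengths (bp)
CELEGANS_CHROMS: dict[str, int] = {
    "I": 15_072_000,
    "II": 15_279_000,
    "III": 13_784_000,
    "IV": 17_494_000,
    "V": 20_924_000,
    "X": 17_719_000,
}

#: transgene insertion region fixed to parent 1 in every line (chrom IV 2.0–12.6 Mb)
DEFAULT_FIXED_REGIONS: list[tuple[str, int, int, int]] = [("IV", 2_000_000, 12_600_000, 0)]


@dataclass
class PanelSpec:
    """Design of a simulated RIL genotype panel."""

    n_lines: int = 70
    n_markers: int = 1927
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(CELEGANS_CHROMS))
    fixed_regions: list[tuple[str, int, int, int]] = field(
        default_factory=lambda: list(DEFAULT_FIXED_REGIONS)
    )
    skew: float | Mapping[str, float] = 0.5
    block_scale: float = 6_000_000.0
    seed: int = 0

    def skew_for(self, chrom: str) -> float:
        return self.skew[chrom] if isinstance(self.skew, Mapping) else float(self.skew)

    def validate(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least two lines")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
        for chrom in self.chrom_lengths:
            s = self.skew_for(chrom)
            if not 0.0 < s < 1.0:
                raise ValueError("skew must lie in (0, 1)")
        for chrom, start, end, allele in self.fixed_regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"fixed region on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError(f"fixed region {chrom}:{start}-{end} outside chromosome")
            if allele not in (0, 1):
                raise ValueError("fixed-region allele must be 0 or 1")
        if self.block_scale <= 0:
            raise ValueError("block_scale must be positive")


@dataclass
class ExpressionArchitecture:
    """Planted genetic architecture of a simulated expression matrix.

    ``cis_fraction`` of spots receive an eQTL at the marker nearest
    their own gene; each hotspot is ``(marker_index, n_targets,
    (effect_mean, effect_sd))`` planting trans effects at one marker;
    ``transgressive_pairs`` spots are driven by two antagonistic loci on
    different chromosomes; remaining spots carry a polygenic line effect
    sized to ``h2_target`` (0 = pure noise).
    """

    n_spots: int = 2000
    cis_fraction: float = 0.10
    trans_hotspots: list[tuple[int, int, tuple[float, float]]] = field(default_factory=list)
    h2_target: float = 0.0
    transgressive_pairs: int = 0
    noise_sd: float = 0.3
    parental_reps: int = 4
    cis_ve_range: tuple[float, float] = (0.2, 0.6)
    transgressive_ve: float = 0.4

    def validate(self, n_markers: int | None = None) -> None:
        if self.n_spots < 1:
            raise ValueError("need at least one spot")
        for frac in (self.cis_fraction, self.h2_target, *self.cis_ve_range, self.transgressive_ve):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for marker, n_targets, (mu, sd) in self.trans_hotspots:
            if not (np.isfinite(mu) and np.isfinite(sd)):
                raise ValueError("hotspot effect sizes must be finite")
            if n_markers is not None and not 0 <= marker < n_markers:
                raise ValueError(f"hotspot marker index {marker} out of range")


@dataclass
class IlDesignSpec:
    """2×2 factorial introgression-line experiment design."""

    n_sets: int = 3
    introgression_windows: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("V", 3_850_000, 9_500_000),
            ("V", 9_500_000, 15_200_000),
            ("V", 15_200_000, 20_900_000),
        ]
    )
    replicates: int = 3
    batch_effects: tuple[float, ...] = (0.0, 0.5, -0.5)
    interaction_spots: int = 25
    effect_size: float = 1.0

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValueError("factorial model needs at least two replicates per strain")
        if len(self.introgression_windows) < self.n_sets:
            raise ValueError("need one introgression window per set")
        if len(self.batch_effects) != self.replicates:
            raise ValueError("one batch offset per replicate batch is required")


def _marker_positions(spec: PanelSpec, rng: np.random.Generator) -> pd.DataFrame:
    lengths = spec.chrom_lengths
    total = sum(lengths.values())
    # largest-remainder apportionment of markers across chromosomes
    quota = {c: spec.n_markers * length / total for c, length in lengths.items()}
    counts = {c: int(np.floor(q)) for c, q in quota.items()}
    rem = spec.n_markers - sum(counts.values())
    for c in sorted(lengths, key=lambda c: quota[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    rows = []
    for chrom, length in lengths.items():
        k = counts[chrom]
        pos = np.sort(rng.uniform(1, length, size=k)).astype(np.int64)
        pos = np.maximum.accumulate(pos + np.arange(k))  # enforce strict increase
        pos = np.minimum(pos, length)
        pos = np.maximum.accumulate(np.minimum(pos, length - (k - 1 - np.arange(k))))
        for p in pos:
            rows.append((f"{chrom}:{p}", chrom, int(p)))
    tab = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"]).set_index("marker_id")
    return tab


def simulate_genotypes(spec: PanelSpec) -> GenotypeMatrix:
    """Simulate a two-parent RIL genotype matrix.

    Each line's genome is piecewise constant in parental blocks whose
    breakpoints follow a Poisson process at rate 1/``block_scale``; the
    first block of each chromosome is parent 2 with probability
    ``skew`` and alleles alternate at breakpoints, so the expected
    parent-2 frequency per marker equals the skew.  Markers inside
    ``fixed_regions`` are forced to the stated allele in every line.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    markers = _marker_positions(spec, rng)
    calls = np.empty((len(markers), spec.n_lines), dtype=np.int8)
    for chrom, length in spec.chrom_lengths.items():
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        pos = markers["pos_bp"].to_numpy()[idx]
        p2 = spec.skew_for(chrom)
        for j in range(spec.n_lines):
            # breakpoint positions: exponential gaps at rate 1/block_scale
            bp = []
            x = rng.exponential(spec.block_scale)
            while x < length:
                bp.append(x)
                x += rng.exponential(spec.block_scale)
            first = int(rng.random() < p2)
            segment = np.searchsorted(np.asarray(bp), pos)
            calls[idx, j] = (first + segment) % 2 if first else segment % 2
    for chrom, start, end, allele in spec.fixed_regions:
        mask = (
            (markers["chrom"] == chrom)
            & (markers["pos_bp"] >= start)
            & (markers["pos_bp"] <= end)
        ).to_numpy()
        calls[mask, :] = allele
    lines = [f"RIL{j + 1:03d}" for j in range(spec.n_lines)]
    return GenotypeMatrix(markers, pd.DataFrame(calls, index=markers.index, columns=lines))


def _genotype_float(geno: GenotypeMatrix) -> np.ndarray:
    """Calls as floats; missing and heterozygous become 0.5."""
    g = geno.codes().astype(float)
    g[(g == NA) | (g == HET)] = 0.5
    return g


def _effect_for_ve(ve: float, sd_g: float, noise_sd: float) -> float:
    """Allelic effect giving the requested variance explained at a marker."""
    if noise_sd == 0 or ve >= 1.0:
        return 1.0
    if sd_g == 0:
        return 0.0
    return float(np.sqrt(ve / (1.0 - ve)) * noise_sd / sd_g)


def simulate_expression(
    geno: GenotypeMatrix,
    arch: ExpressionArchitecture,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate log2 expression for RILs plus parental/reference replicates.

    Returns the expression matrix (one RIL sample per line plus 4
    parental/reference strains × ``parental_reps`` replicates) and a
    truth table with each spot's causal markers, effect sizes, true
    cis/trans label and planted variance explained.
    """
    arch.validate(n_markers=geno.n_markers)
    if geno.n_markers == 0 or not geno.lines:
        raise ValueError("empty genotype matrix")
    rng = np.random.default_rng(seed)
    g_ril = _genotype_float(geno)  # markers × lines
    n_markers, n_lines = g_ril.shape
    mpos = geno.markers["pos_bp"].to_numpy()
    mchrom = geno.markers["chrom"].to_numpy()

    # strain genomes: parents carry the transgene insertion haplotype, references are pure
    p1 = np.zeros(n_markers)
    p2 = np.ones(n_markers)
    strain_genomes = {"parent1": p1, "parent2": p2, "ref1": p1, "ref2": p2}
    strain_class = {"parent1": PARENTAL, "parent2": PARENTAL, "ref1": REFERENCE, "ref2": REFERENCE}

    sample_ids = list(geno.lines)
    meta = [(line, RIL, "b1") for line in geno.lines]
    for strain in strain_genomes:
        for r in range(arch.parental_reps):
            sample_ids.append(f"{strain}_r{r + 1}")
            meta.append((strain, strain_class[strain], "b1"))
    samples = pd.DataFrame(meta, index=sample_ids, columns=["line_id", "strain_class", "batch"])
    n_samples = len(sample_ids)

    # per-sample genotype matrix (markers × samples)
    g_all = np.concatenate(
        [g_ril]
        + [np.repeat(strain_genomes[s][:, None], arch.parental_reps, axis=1) for s in strain_genomes],
        axis=1,
    )
    sd_g = g_ril.std(axis=1)  # population SD over RIL lines

    # spot annotation: genes placed uniformly along the genome
    chroms = list(dict.fromkeys(mchrom))
    lengths = np.array([mpos[mchrom == c].max() for c in chroms], dtype=float)
    gchrom_i = rng.choice(len(chroms), size=arch.n_spots, p=lengths / lengths.sum())
    gpos = (rng.uniform(1, lengths[gchrom_i])).astype(np.int64)
    spot_ids = [f"S{i + 1:05d}" for i in range(arch.n_spots)]
    spots = pd.DataFrame(
        {
            "gene_id": [f"gene_{i + 1:05d}" for i in range(arch.n_spots)],
            "chrom": [chroms[i] for i in gchrom_i],
            "pos_bp": gpos,
            "is_technical": False,
        },
        index=pd.Index(spot_ids, name="spot_id"),
    )

    # assign planted roles to disjoint spot subsets
    order = rng.permutation(arch.n_spots)
    n_cis = int(round(arch.cis_fraction * arch.n_spots))
    n_hot = sum(h[1] for h in arch.trans_hotspots)
    n_tg = arch.transgressive_pairs
    if n_cis + n_hot + n_tg > arch.n_spots:
        raise ValueError("more planted spots requested than spots available")
    cis_spots = order[:n_cis]
    hot_spots = order[n_cis : n_cis + n_hot]
    tg_spots = order[n_cis + n_hot : n_cis + n_hot + n_tg]
    rest = order[n_cis + n_hot + n_tg :]

    genetic = np.zeros((arch.n_spots, n_samples))
    truth_rows: dict[int, dict] = {
        i: {"kind": "null", "markers": "", "effects": "", "ve": 0.0, "h2": arch.h2_target}
        for i in range(arch.n_spots)
    }

    def plant(spot: int, marker_idx: Sequence[int], effects: Sequence[float], kind: str) -> None:
        ve_num = 0.0
        for m, a in zip(marker_idx, effects):
            genetic[spot] += a * g_all[m]
            ve_num += (a * sd_g[m]) ** 2
        tot = ve_num + arch.noise_sd**2
        truth_rows[spot] = {
            "kind": kind,
            "markers": ";".join(geno.markers.index[list(marker_idx)]),
            "effects": ";".join(f"{a:.6g}" for a in effects),
            "ve": ve_num / tot if tot > 0 else 1.0,
            "h2": arch.h2_target,
        }

    # cis: eQTL at the marker nearest the spot's own gene
    for spot in cis_spots:
        on_chrom = np.flatnonzero(mchrom == spots["chrom"].iloc[spot])
        m = on_chrom[np.argmin(np.abs(mpos[on_chrom] - spots["pos_bp"].iloc[spot]))]
        ve = rng.uniform(*arch.cis_ve_range)
        a = _effect_for_ve(ve, sd_g[m], arch.noise_sd) * rng.choice([-1.0, 1.0])
        plant(spot, [m], [a], "cis")

    # trans hotspots: one master marker regulating many targets
    cursor = 0
    for marker, n_targets, (mu, sd) in arch.trans_hotspots:
        for spot in hot_spots[cursor : cursor + n_targets]:
            a = rng.normal(mu, sd) * rng.choice([-1.0, 1.0])
            plant(spot, [marker], [a], "hotspot")
        cursor += n_targets

    # transgressive spots: antagonistic loci on two chromosomes
    for spot in tg_spots:
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        m1 = rng.choice(np.flatnonzero(mchrom == chroms[c1]))
        m2 = rng.choice(np.flatnonzero(mchrom == chroms[c2]))
        denom = np.sqrt(sd_g[m1] ** 2 + sd_g[m2] ** 2)
        ve = arch.transgressive_ve
        a = _effect_for_ve(ve, denom, arch.noise_sd) if denom > 0 else 0.0
        plant(spot, [m1, m2], [a, -a], "transgressive")

    # background polygenic line effect sized to h2_target
    if arch.h2_target > 0 and arch.noise_sd > 0:
        sd_line = arch.noise_sd * np.sqrt(arch.h2_target / (1.0 - arch.h2_target))
        line_ids = samples["line_id"].to_numpy()
        uniq = list(dict.fromkeys(line_ids))
        col_of = np.array([uniq.index(l) for l in line_ids])
        eff = rng.normal(0.0, sd_line, size=(len(rest), len(uniq)))
        genetic[rest] += eff[:, col_of]
        for spot in rest:
            truth_rows[spot]["kind"] = "polygenic"

    baseline = rng.normal(10.0, 1.5, size=arch.n_spots)
    noise = rng.normal(0.0, arch.noise_sd, size=(arch.n_spots, n_samples)) if arch.noise_sd > 0 else 0.0
    values = pd.DataFrame(
        baseline[:, None] + genetic + noise, index=spots.index, columns=sample_ids
    )
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth.index = spots.index
    truth.insert(0, "gene_id", spots["gene_id"].to_numpy())
    return ExpressionMatrix(values, spots, samples), truth


def simulate_il_experiment(
    spec: IlDesignSpec,
    arch: ExpressionArchitecture,
    seed: int = 0,
    introgression_effects: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a 2×2 factorial introgression-line experiment.

    Per set, all four (introgression I × transgene A) genotype classes
    are produced with ``replicates`` replicates, replicate r assigned to
    batch r with the configured additive offset.  ``interaction_spots``
    spots carry a pure I×A effect of size ``effect_size`` (random sign);
    ``introgression_effects`` optionally plants per-spot I main effects.
    Returns (expression, design, truth).
    """
    spec.validate()
    arch.validate()
    rng = np.random.default_rng(seed)

    rows = []
    for s in range(spec.n_sets):
        for i_allele in (0, 1):
            for a_allele in (0, 1):
                for r in range(spec.replicates):
                    rows.append(
                        (
                            f"set{s + 1}_I{i_allele}A{a_allele}_r{r + 1}",
                            f"set{s + 1}",
                            i_allele,
                            a_allele,
                            f"b{r + 1}",
                            r + 1,
                        )
                    )
    design = pd.DataFrame(
        rows, columns=["sample_id", "set", "I", "A", "batch", "replicate"]
    ).set_index("sample_id")

    spot_ids = [f"S{i + 1:05d}" for i in range(arch.n_spots)]
    spots = pd.DataFrame(
        {
            "gene_id": [f"gene_{i + 1:05d}" for i in range(arch.n_spots)],
            "chrom": "V",
            "pos_bp": np.linspace(1, 20_900_000, arch.n_spots).astype(np.int64),
            "is_technical": False,
        },
        index=pd.Index(spot_ids, name="spot_id"),
    )

    if spec.interaction_spots > arch.n_spots:
        raise ValueError("more interaction spots requested than spots available")
    beta = pd.DataFrame(0.0, index=spots.index, columns=["I", "A", "IxA"])
    picks = rng.choice(arch.n_spots, size=spec.interaction_spots, replace=False)
    beta.iloc[picks, beta.columns.get_loc("IxA")] = spec.effect_size * rng.choice(
        [-1.0, 1.0], size=spec.interaction_spots
    )
    for spot, eff in (introgression_effects or {}).items():
        beta.loc[spot, "I"] = eff

    i_vec = design["I"].to_numpy()
    a_vec = design["A"].to_numpy()
    batch_of = design["replicate"].to_numpy() - 1
    offsets = np.asarray(spec.batch_effects)[batch_of]

    baseline = rng.normal(10.0, 1.5, size=arch.n_spots)
    signal = (
        np.outer(beta["I"], i_vec)
        + np.outer(beta["A"], a_vec)
        + np.outer(beta["IxA"], i_vec * a_vec)
    )
    noise = (
        rng.normal(0.0, arch.noise_sd, size=(arch.n_spots, len(design)))
        if arch.noise_sd > 0
        else 0.0
    )
    values = pd.DataFrame(
        baseline[:, None] + signal + offsets[None, :] + noise,
        index=spots.index,
        columns=design.index,
    )
    samples = pd.DataFrame(
        {
            "line_id": [f"{s}_{i}_{a}" for s, i, a in zip(design["set"], design["I"], design["A"])],
            "strain_class": IL,
            "batch": design["batch"],
        },
        index=design.index,
    )
    truth = beta.copy()
    truth.insert(0, "gene_id", spots["gene_id"].to_numpy())
    return ExpressionMatrix(values, spots, samples), design, truth


def simulate_qpcr(
    n_samples: int,
    true_ratios: Mapping[str, float | Sequence[float]],
    seed: int = 0,
    noise_sd: float = 0.0,
    ref_ct: float = 20.0,
    references: Sequence[str] = ("rpl-6", "Y37E3.8"),
) -> CtTable:
    """Simulate Ct values for target genes against two reference genes.

    Reference genes are emitted at Ct = ``ref_ct`` and each target v at
    Ct = ref_ct − log2(ratio_v), so the dual-reference quantification
    recovers ``true_ratios`` exactly (times the table's ``scale``,
    2**−ref_ct) in the noiseless limit.  Gaussian noise of SD
    ``noise_sd`` is added to every Ct.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for ref in references:
        cols[ref] = np.full(n_samples, float(ref_ct))
    for gene, ratio in true_ratios.items():
        r = np.broadcast_to(np.asarray(ratio, dtype=float), (n_samples,)).copy()
        if (r <= 0).any():
            raise ValueError("true ratios must be positive")
        cols[gene] = ref_ct - np.log2(r)
    ct = pd.DataFrame(cols, index=[f"sample{j + 1}" for j in range(n_samples)])
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
    return CtTable(ct, scale=2.0 ** (-ref_ct))
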