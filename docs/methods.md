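# Methods

This note documents the statistical models, the synthetic-data
generators, the defaults and the numerical conventions used throughout
`rilqtl`, and what the test suite does and does not demonstrate.

## The panel model

The package analyses a two-parent recombinant inbred line (RIL) panel:
each line is homozygous at (nearly) every locus, its genome a mosaic of
the two parental haplotypes. Genotypes are coded 0 (parent 1, an
N2-derived background) and 1 (parent 2, a CB4856-derived background),
with representable heterozygous and missing codes; heterozygous calls are
treated as missing at mapping time, since residual heterozygosity in an
inbred panel is noise for a two-group contrast. Coordinates are 1-based
inclusive base pairs. Both parents carry the same transgene insertion,
so the insertion region is monomorphic in the panel — on the default map
that is chromosome IV from 2.0 to 12.6 Mb, forced to the parent-1 allele
in every simulated line. Markers inside it are monomorphic and yield no
mapping signal, exactly as in the real design.

## Synthetic data

The generators reproduce the *statistical structure* the estimators
assume, not *C. elegans* biology:

- **Genotypes** (`simulate_genotypes`). Marker positions are drawn
  uniformly within chromosomes (six, 13.8–20.9 Mb, apportioned ~1927
  markers by length); dimensions and marker density are what the
  downstream statistics react to, not the actual coordinates. Each
  line's genome is piecewise constant with breakpoints from a Poisson
  process at rate 1/`block_scale` (default 6 Mb, giving the 2–3 blocks
  per chromosome typical of a selfed RIL); the first block is parent 2
  with probability `skew` (default 0.5) and alleles alternate at
  breakpoints, so the per-marker parent-2 frequency equals the skew.
  The real panel shows allelic skews of unreported magnitude, so skew is
  a free per-chromosome parameter.
- **Expression** (`simulate_expression`). Spots get a baseline
  ~N(10, 1.5²) log₂ units and Gaussian residual noise (`noise_sd`,
  default 0.3 log₂ units — a typical spot-level microarray residual).
  A `cis_fraction` of spots receives an eQTL at the marker nearest its
  own gene with variance explained drawn from `cis_ve_range`; hotspot
  spots load on one designated marker with N(mean, sd) effects;
  transgressive spots are driven by two antagonistic loci on different
  chromosomes (equal and opposite effects), which leaves the parental
  means equal while recombinant lines escape the parental range.
  Remaining spots optionally carry a polygenic line effect sized to
  `h2_target`. Samples are one per RIL plus four replicates each of the
  two parents and two reference backgrounds, mirroring the technical-
  variance estimator. Allelic effects are scaled from the requested
  variance explained via a² = VE/(1−VE) · σ²_noise/σ²_marker using the
  population genotype variance over the lines.
- **IL experiment** (`simulate_il_experiment`). Per set, all four
  introgression × transgene classes with 3 replicates; replicate r is
  batch r with an additive offset (defaults 0, +0.5, −0.5 log₂ units, a
  visible but realistic array batch effect). A configurable number of
  spots carries a pure interaction effect (default |I×A| = 1 log₂ unit).
- **qPCR** (`simulate_qpcr`). Reference genes at fixed Ct (default 20),
  targets at Ct = 20 − log₂(ratio), optional Gaussian Ct noise, so the
  dual-reference quantification recovers the planted ratios exactly in
  the noiseless limit.

What the generators do *not* emulate: the actual two-phase crossing
scheme and meiotic interference, genotyping error, probe cross-
hybridisation, intensity-dependent variance, correlated expression
modules, or mitochondrial inheritance. Passing tests therefore show the
estimators are correct under their own assumptions (exchangeable
Gaussian noise, additive effects), not that real arrays meet those
assumptions.

## Heritability and transgression

Broad-sense heritability per spot is H² = (V_RIL − V_e)/V_RIL, with
V_RIL the sample variance over the RIL samples and V_e the technical
variance pooled (degrees-of-freedom weighted) over the replicated
parental *and* reference strains — all four strains contribute, since
replicate scatter within any isogenic strain measures the same technical
noise. Negative H² is reported as computed, not clipped; significance
comes from the permutation threshold, so clipping is unnecessary. H² is
undefined (NaN) when V_RIL = 0.

Transgression counts RIL samples strictly outside
[min parental mean − 3σ, max parental mean + 3σ], σ the pooled SD of the
two parental strains (n = 4 each, 6 df).

Both statistics get per-spot thresholds by randomizing the trait values
over the line designations (all samples jointly — the most literal
reading; shuffling only RILs is a defensible alternative) 1000 times and
taking the ⌈0.05·n⌉-th highest permuted value (the 50th for 1000) as the
FDR = 0.05 cutoff; a spot is significant when its observed statistic
strictly exceeds its threshold. Under exchangeability this exceeds with
probability k/(n+1) ≈ 0.05 for a continuous statistic; the transgression
count is discrete, so ties make it mildly conservative (measured ~0.03–
0.05 under a global null). Permutation draws with an undefined statistic
count as −∞.

## eQTL mapping

The scan is ordinary least squares of each spot on each marker's 0/1
genotype; the p-value is the two-sided t test on the slope, identically
the 1-df F test, and the signed effect is mean(allele 1) − mean(allele 0).
−log10(p) is capped at 300 so numerically zero p-values stay finite in
files. Markers monomorphic after dropping missing/heterozygous lines
give NaN columns. On maps without missing calls the residual df is
constant across markers, so the genome-wide peak is located as the
argmax of R² and the tail probability is evaluated only there — this
fast path is what makes the permutation and power loops cheap; a masked
per-marker path handles maps with missing data and is verified identical
against an independent regression oracle.

**Threshold.** Ten datasets are built by permuting each spot's values
over lines and scanned identically. At a candidate cutoff c, RDS = real
spots whose peak ≥ c and FDS = mean permuted count; the chosen cutoff is
the smallest c with FDS/RDS ≤ q (default q = 0.05). A more liberal
variant with bound (m₀/m)·q·ln(m) is available behind
`variant="paper"`; the default is the plain bound because it is the one
that actually delivers FDR ≤ q (measured false-discovery proportion
≈ 0.04–0.05 on planted panels).

**Power.** For each polymorphic marker and each variance-explained level
(default grid 0.20–0.80, step 0.05), 10 phenotypes are simulated as
genotype plus Gaussian noise scaled to the level; a QTL is detected when
the genome-wide peak exceeds the cutoff and the peak marker is the
causal one or linked to it (|genotype correlation| ≥ 0.5). Pooled over
levels ≥ 0.35 on a balanced 70 × 1927 map at cutoff 4.3, detection is
~99.6%; a balanced map is the best case, and panels with allele-
frequency skew or fixed regions can only do worse.

**Peaks, intervals, classes.** At most one peak per chromosome per spot
(prevents double-counting shoulders of one signal). The confidence
interval extends contiguously from the peak while markers stay within
1.5 −log10(p) units of it, truncated at chromosome ends; extension stops
at the first marker below the floor rather than jumping dips, matching
the standard LOD-drop convention. An eQTL is *cis* when its gene's
annotated position lies inside the interval's physical span (inclusive),
else *trans*; unannotated spots are trans and flagged. Variance
explained is the one-factor ANOVA R² at the peak (numerically the
squared Pearson correlation with the genotype), computed per peak even
for multi-peak spots, and gene-level lists keep the spot with the
highest R² (ties: higher peak, then lexicographic spot id).

**Trans-bands.** Trans-eQTL peak positions are counted in half-open
0.5 Mb bins covering the marker map; under a uniform expectation
λ = total/bins, a bin is flagged when the Poisson upper tail
P(X ≥ observed) falls below `p_cut` (default 0.001, with 0.0001 exposed
as the stricter documented alternative — both cutoffs are in reasonable
use and the choice is left to the caller). Adjacent flagged bins are
reported both individually and merged.

## IL factorial analysis

Expression is first batch-corrected per spot: each batch's mean
deviation from the spot's grand mean is subtracted, which equalizes
batch means, preserves the grand mean, and is idempotent. (An additive
batch offset is thereby removed entirely up to the per-spot constant the
correction deliberately preserves; every downstream fit has an
intercept, so this constant is inert. With batches balanced over the
design, factorial estimates are identical before and after correction.)

Per strain set, y ~ I + A + I·A is fitted by least squares with 0/1
coding — the reference cell is the N2 background without the transgene,
so I is the introgression effect in the transgene-absent background and
I×A shifts only the doubly-positive cell; the coding is stated because
interaction estimates depend on it. Per-coefficient t tests are
Benjamini–Hochberg adjusted across spots within each set and term
(per-model testing; a pooled option exists). Sets missing one of the
four cells are rejected. IL–RIL comparison restricts to spots whose RIL
eQTL peak falls inside the set's introgression window and reports the
Pearson correlation (with its two-sided test) between RIL signed effects
and each IL term's estimates; fewer than three overlapping genes yields
NaN with a warning.

## Enrichment

Hypergeometric upper-tail test per category with the filters applied
before testing: at least three category members in the universe and at
least two in the query. The Bonferroni multiplier is the number of
categories actually tested (after filters), and the default universe is
the annotated genes on the censored expression matrix — the hypothesis
space of the array — rather than the whole genome.

## Preprocessing conventions

Quantile normalization replaces each column's values by the
across-column means of the order statistics at their rank; tied values
receive the mean of the rank means they span (deterministic
average-tie policy; the column-distribution identity is exact only on
tie-free data, which log-intensity data is in practice). Within-array
loess recentres M = log₂(R/G) on its loess fit against
A = ½·log₂(R·G) and reconstructs channel intensities as A ± M′/2; a
constant M is removed as dye bias, so only arrays with M equal to its
intensity trend are fixed points. qPCR transformed abundance is
Q = 2^(−Ct) (perfect-efficiency two-fold amplification; per-gene
efficiencies are accepted as an optional argument), and relative
abundance divides the target's Q by the mean of the two reference
genes' sample-normalized Q values. The log₂-ratio-with-mean transform
divides intensities (not log intensities) by the spot's mean intensity
before taking log₂, making principal components invariant to per-spot
scaling; components come from the SVD of the column-centred
sample-by-spot matrix with the sign convention that the
largest-magnitude loading is positive. The selection of a single
developmental timepoint for sampling is treated as a fixed design input.

## Genotype-map conventions

When merging sequencing- and PCR-based calls, a conflict resolves to the
sequencing call when at least two consecutive sequencing markers agree
against the PCR call (strong evidence), and to the PCR call when the
conflicting sequencing run is a single marker; the two-marker rule is
this package's operationalization of "strong evidence". Blanks flanked
by agreeing calls are filled with that call; disagreeing flanks leave
the blank. A breakpoint is a change between consecutive homozygous
calls along a line, counted once across missing-data gaps whose flanks
disagree — an unbiased convention where the change must have happened
somewhere in the gap.

## Problem sizes and runtime

The permutation and simulation scales used by the tests and the
acceptance script are the design's own: 70 lines, 1927 markers for power
(10 QTL per marker per level, levels 0.35–0.80 for the pooled figure),
500 transcripts × 1000 permutations for the null calibrations, and 20
replicate panels of 2000 spots × 500 markers with 10 permuted datasets
each for false-discovery control. On one CPU the whole acceptance run
takes well under two minutes thanks to the closed-form group-mean scan.

## Known limitations

No interval mapping between markers, no multi-QTL or forward-selection
models, no kinship/relatedness correction (RILs are treated as
exchangeable), no mixed-effects batch modelling, no GO-graph
propagation in enrichment, and no variant calling or HMM genotype
smoothing — genotype matrices are consumed, not called. Trans-band
detection assumes a uniform null over bins; clustering of genes or
markers along the genome is not modelled.
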