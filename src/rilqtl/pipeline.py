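"""End-to-end orchestration of the synthetic-panel analysis.

Stages run in dependency order (simulate → heritability/transgression →
eQTL scan, FDR threshold, classification, trans-bands → IL factorial →
enrichment → report).  Every stage draws from its own seed stream
(stage-name salted), so toggling one stage off does not shift another
stage's random draws, and output files are stamped with version, seed
and a parameter hash; a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import eqtl, il, io, quantgen, simulate
from .expression import batch_correct

#: defaults: 1000 permutations, 10 permuted datasets, q = 0.05, 0.5 Mb bins,
#: 1.5 drop, 3σ boundaries, Bonferroni 0.05
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": {
        "simulate": True,
        "heritability": True,
        "transgression": True,
        "eqtl": True,
        "power": False,
        "il": True,
        "enrich": True,
        "report": True,
    },
    "panel": {},
    "architecture": {},
    "il": {},
    "quantgen": {"n_perm": 1000, "alpha": 0.05},
    "eqtl": {
        "q": 0.05,
        "fdr_variant": "plain",
        "n_perm_datasets": 10,
        "cutoff": None,
        "bin_kb": 500,
        "p_cut": 0.001,
        "drop": 1.5,
    },
    "power": {"n_per_marker": 10, "cutoff": None},
    "enrich": {"alpha": 0.05, "n_random_categories": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


@dataclass
class RunConfig:
    """Pipeline configuration; unspecified tunables keep their defaults."""

    data: dict = field(default_factory=lambda: _merge(DEFAULT_CONFIG, {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(_merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {}))

    @classmethod
    def from_dict(cls, override: dict | None = None) -> "RunConfig":
        return cls(_merge(DEFAULT_CONFIG, override or {}))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed, salted by stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _arch_from_cfg(cfg: dict) -> simulate.ExpressionArchitecture:
    kw = dict(cfg)
    if "trans_hotspots" in kw:
        kw["trans_hotspots"] = [(int(m), int(n), (float(mu), float(sd))) for m, n, (mu, sd) in kw["trans_hotspots"]]
    if "cis_ve_range" in kw:
        kw["cis_ve_range"] = tuple(kw["cis_ve_range"])
    return simulate.ExpressionArchitecture(**kw)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured stages into ``outdir``; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    stages = config["stages"]
    params = config.data

    def stamp(df, name, index=True):
        io.write_table(df, out / name, seed=seed, params=params, index=index)

    def require(name: str):
        if not (out / name).exists():
            raise FileNotFoundError(
                f"missing upstream output {name!r}; enable the stage that produces it"
            )

    if stages.get("simulate"):
        spec = simulate.PanelSpec(**config["panel"], seed=stage_seed(seed, "simulate"))
        geno = simulate.simulate_genotypes(spec)
        arch = _arch_from_cfg(config["architecture"])
        expr, truth = simulate.simulate_expression(geno, arch, seed=stage_seed(seed, "expression"))
        io.write_genotypes(geno, out / "genotypes.tsv", seed=seed, params=params)
        io.write_expression(expr, out / "expression", seed=seed, params=params)
        stamp(truth, "truth.tsv")
        il_spec = simulate.IlDesignSpec(**config["il"])
        il_mat, il_design, il_truth = simulate.simulate_il_experiment(
            il_spec, arch, seed=stage_seed(seed, "il")
        )
        io.write_expression(il_mat, out / "il_expression", seed=seed, params=params)
        stamp(il_design, "il_design.tsv")
        stamp(il_truth, "il_truth.tsv")

    require("genotypes.tsv")
    geno = io.read_genotypes(out / "genotypes.tsv")
    expr = io.read_expression(out / "expression")
    qg = config["quantgen"]

    if stages.get("heritability"):
        h2 = quantgen.heritability(
            expr, n_perm=qg["n_perm"], seed=stage_seed(seed, "heritability"), alpha=qg["alpha"]
        )
        stamp(h2, "heritability.tsv")
    if stages.get("transgression"):
        tg = quantgen.transgression(
            expr, n_perm=qg["n_perm"], seed=stage_seed(seed, "transgression"), alpha=qg["alpha"]
        )
        stamp(tg, "transgression.tsv")

    cutoff = None
    if stages.get("eqtl"):
        ecfg = config["eqtl"]
        scan_res = eqtl.scan(expr, geno)
        best = eqtl.best_scores(expr, geno)
        perm = eqtl.permuted_best_scores(
            expr, geno, n_datasets=ecfg["n_perm_datasets"], seed=stage_seed(seed, "eqtl-perm")
        )
        thr = eqtl.empirical_fdr(
            best["neglogp"], perm, q=ecfg["q"], variant=ecfg["fdr_variant"]
        )
        cutoff = ecfg["cutoff"] if ecfg["cutoff"] is not None else thr.cutoff
        with open(out / "fdr_threshold.json", "w") as fh:
            json.dump(
                {
                    "cutoff": cutoff,
                    "rds": thr.rds,
                    "fds": thr.fds,
                    "q": thr.q,
                    "variant": thr.variant,
                    "m": thr.m,
                    "m0": thr.m0,
                },
                fh,
                indent=1,
            )
        records = eqtl.call_peaks_and_intervals(scan_res, cutoff, expr.spots, drop=ecfg["drop"])
        records = eqtl.variance_explained(expr, geno, records)
        stamp(records, "eqtl_records.tsv", index=False)
        stamp(eqtl.best_spot_per_gene(records), "eqtl_per_gene.tsv", index=False)
        bands = eqtl.detect_trans_bands(
            records, geno, bin_bp=int(ecfg["bin_kb"]) * 1000, p_cut=ecfg["p_cut"]
        )
        stamp(bands.bands, "transbands.tsv", index=False)
        stamp(bands.merged, "transbands_merged.tsv", index=False)

    if stages.get("power"):
        pcfg = config["power"]
        pc = pcfg["cutoff"] if pcfg["cutoff"] is not None else (cutoff if cutoff else 4.3)
        ptab = eqtl.power_analysis(
            geno, cutoff=pc, n_per_marker=pcfg["n_per_marker"], seed=stage_seed(seed, "power")
        )
        stamp(ptab, "power.tsv", index=False)

    if stages.get("il"):
        require("il_design.tsv")
        il_mat = io.read_expression(out / "il_expression")
        design = io.read_table(out / "il_design.tsv")
        corrected = batch_correct(il_mat)
        effects = il.fit_factorial(corrected, design)
        stamp(effects, "il_effects.tsv", index=False)
        if stages.get("eqtl"):
            require("eqtl_records.tsv")
            records = io.read_table(out / "eqtl_records.tsv", index_col=None)
            windows = simulate.IlDesignSpec(**config["il"]).introgression_windows
            reports = []
            for set_id, window in zip(sorted(design["set"].unique()), windows):
                reports.append(
                    il.compare_il_ril(effects, records, tuple(window), set_id=set_id)
                )
            stamp(pd.concat(reports, ignore_index=True), "il_ril_correlation.tsv", index=False)

    if stages.get("enrich"):
        require("eqtl_records.tsv")
        require("truth.tsv")
        truth = io.read_table(out / "truth.tsv")
        records = io.read_table(out / "eqtl_records.tsv", index_col=None)
        bands = io.read_table(out / "transbands.tsv", index_col=None)
        universe = expr.spots["gene_id"].dropna().unique()
        sets = _synthetic_annotations(
            truth, universe, config["enrich"]["n_random_categories"], stage_seed(seed, "enrich")
        )
        enrich_mod.write_gmt(sets, out / "annotations.gmt")
        query = _hotspot_query(records, bands)
        if query:
            result = enrich_mod.enrich(query, sets, universe, alpha=config["enrich"]["alpha"])
        else:
            result = pd.DataFrame(
                columns=["category", "source", "N", "K", "n", "k", "p", "p_bonferroni", "significant"]
            )
        stamp(result, "enrichment.tsv", index=False)

    if stages.get("report"):
        report(out)
    return out


def _hotspot_query(records: pd.DataFrame, bands: pd.DataFrame) -> list[str]:
    """Genes whose trans-eQTL peak falls in a flagged trans-band bin."""
    flagged = bands[bands["flagged"]]
    genes: set[str] = set()
    trans = records[(records["qtl_class"] == "trans") & records["gene_id"].notna()]
    for _, b in flagged.iterrows():
        hit = trans[
            (trans["chrom"] == b["chrom"])
            & (trans["peak_pos"] >= b["start"])
            & (trans["peak_pos"] < b["end"])
        ]
        genes.update(hit["gene_id"])
    return sorted(genes)


def _synthetic_annotations(truth: pd.DataFrame, universe, n_random: int, seed: int):
    """Annotation categories for the synthetic panel: planted-architecture
    classes plus random categories (labelled synthetic; they stand in for
    curated gene-set databases, which are inputs in a real analysis)."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets = []
    for kind, sub in truth.groupby("kind"):
        genes = frozenset(sub["gene_id"].dropna())
        if len(genes) >= 3 and kind != "null":
            sets.append(enrich_mod.AnnotationSet(f"planted_{kind}", "synthetic", genes))
    for i in range(n_random):
        size = int(rng.integers(3, max(4, len(universe) // 10)))
        members = frozenset(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets.append(enrich_mod.AnnotationSet(f"random_{i + 1:02d}", "synthetic", members))
    return sets


def report(rundir) -> dict:
    """Summary counts, a cis/trans dot plot and a trans-eQTL density histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rundir = Path(rundir)
    counts: dict[str, int] = {}
    records = None
    if (rundir / "eqtl_records.tsv").exists():
        records = io.read_table(rundir / "eqtl_records.tsv", index_col=None)
        counts["n_eqtl"] = len(records)
        counts["n_cis"] = int((records["qtl_class"] == "cis").sum())
        counts["n_trans"] = int((records["qtl_class"] == "trans").sum())
    if (rundir / "transbands_merged.tsv").exists():
        counts["n_trans_bands"] = len(io.read_table(rundir / "transbands_merged.tsv", index_col=None))
    if (rundir / "heritability.tsv").exists():
        h2 = io.read_table(rundir / "heritability.tsv")
        counts["n_heritable"] = int(h2["significant"].sum())
    if (rundir / "transgression.tsv").exists():
        tg = io.read_table(rundir / "transgression.tsv")
        counts["n_transgressive"] = int(tg["significant"].sum())

    if records is not None and not records.empty:
        # trans-eQTL density per 0.5 Mb bin with the flagging threshold
        if (rundir / "transbands.tsv").exists():
            from scipy import stats as sps

            bands = io.read_table(rundir / "transbands.tsv", index_col=None)
            fig2, ax2 = plt.subplots(figsize=(7, 3))
            ax2.bar(range(len(bands)), bands["count"], width=1.0)
            if len(bands):
                lam = float(bands["lam"].iloc[0])
                k_star = 0
                while sps.poisson.sf(k_star - 1, lam) >= 1e-3:
                    k_star += 1
                ax2.axhline(k_star, linestyle="--", color="k")
            ax2.set_xlabel("0.5 Mb bin")
            ax2.set_ylabel("trans-eQTL")
            fig2.savefig(rundir / "trans_density.png", dpi=100)
            plt.close(fig2)
        # eQTL-position vs gene-position dot plot (concatenated coordinates)
        spots = None
        if (rundir / "expression.spots.tsv").exists():
            spots = io.read_table(rundir / "expression.spots.tsv")
        offs, off = {}, 0
        for c in dict.fromkeys(records["chrom"]):
            offs[c] = off
            off += int(records.loc[records["chrom"] == c, "peak_pos"].max()) + 1
        sub = records[records["spot"].isin(spots.index)] if spots is not None else records.iloc[:0]
        if not sub.empty:
            fig, ax = plt.subplots(figsize=(6, 6))
            x = [offs[c] + p for c, p in zip(sub["chrom"], sub["peak_pos"])]
            y = [
                offs.get(spots.at[s, "chrom"], 0) + spots.at[s, "pos_bp"] for s in sub["spot"]
            ]
            colors = sub["qtl_class"].map({"cis": "tab:blue", "trans": "tab:red"})
            ax.scatter(x, y, s=6, c=colors)
            ax.set_xlabel("eQTL position (concatenated bp)")
            ax.set_ylabel("gene position (concatenated bp)")
            fig.savefig(rundir / "cis_trans_dotplot.png", dpi=100)
            plt.close(fig)
    elif records is not None:
        import warnings

        warnings.warn("no eQTL records; report plots are empty")

    with open(rundir / "report.txt", "w") as fh:
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
    return counts
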