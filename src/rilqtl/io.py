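"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with ``#``-prefixed header lines carrying
the package version, the seed and a parameter hash, so a rerun with the
same configuration is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .expression import CtTable, ExpressionMatrix
from .genotypes import _CODE_STR, _STR_CODE, GenotypeMatrix


def params_hash(params: Mapping | None) -> str:
    blob = json.dumps(params or {}, sort_keys=True, default=str).encode()
    return hashlib.md5(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path,
    seed: int | None = None,
    params: Mapping | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# rilqtl {__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if params is not None:
            fh.write(f"# params={params_hash(params)}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_genotypes(geno: GenotypeMatrix, path, seed: int | None = None, params=None) -> None:
    """Genotype TSV: marker_id, chrom, pos_bp, then one column per line."""
    coded = geno.calls.apply(lambda s: s.map(_CODE_STR))
    out = pd.concat([geno.markers, coded], axis=1)
    out.index.name = "marker_id"
    write_table(out, path, seed=seed, params=params)


def read_genotypes(path) -> GenotypeMatrix:
    tab = read_table(path)
    markers = tab[["chrom", "pos_bp"]]
    calls = tab.drop(columns=["chrom", "pos_bp"]).astype(str).apply(lambda s: s.map(_STR_CODE)).astype("int8")
    return GenotypeMatrix(markers, calls)


def write_expression(mat: ExpressionMatrix, prefix, seed: int | None = None, params=None) -> None:
    """Expression as three TSVs: values, spot annotation, sample metadata."""
    prefix = Path(prefix)
    write_table(mat.values, prefix.with_suffix(".values.tsv"), seed=seed, params=params)
    write_table(mat.spots, prefix.with_suffix(".spots.tsv"), seed=seed, params=params)
    write_table(mat.samples, prefix.with_suffix(".samples.tsv"), seed=seed, params=params)


def read_expression(prefix) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = read_table(prefix.with_suffix(".values.tsv"))
    spots = read_table(prefix.with_suffix(".spots.tsv"))
    samples = read_table(prefix.with_suffix(".samples.tsv"))
    return ExpressionMatrix(values, spots, samples)


def read_censor_list(path) -> list[str]:
    """Plain-text censor list, one spot id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_ct_table(table: CtTable, path) -> None:
    """qPCR CSV in long form: sample, gene, Ct."""
    long = table.ct.stack().rename("ct").reset_index()
    long.columns = ["sample", "gene", "ct"]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    long.to_csv(path, index=False)


def read_ct_table(path, scale: float = 1.0) -> CtTable:
    long = pd.read_csv(path)
    wide = long.pivot(index="sample", columns="gene", values="ct")
    wide.columns.name = None
    return CtTable(wide, scale=scale)


def read_vcf_matrix(path) -> GenotypeMatrix:
    """Genotypes from a (plain-text) VCF: per-sample GT collapsed to codes.

    0/0 → parent 1, 1/1 → parent 2, mixed → heterozygous, ``./.`` →
    missing.  Intended for simple biallelic genotype-matrix VCFs.
    """
    from cyvcf2 import VCF  # optional dependency, present where VCF input is used

    rows, calls = [], []
    vcf = VCF(str(path))
    for var in vcf:
        rows.append((f"{var.CHROM}:{var.POS}", var.CHROM, var.POS))
        codes = []
        for gt in var.genotypes:
            a = [x for x in gt[:-1] if x is not None and x >= 0]
            if not a:
                codes.append(_STR_CODE["NA"])
            elif all(x == 0 for x in a):
                codes.append(_STR_CODE["0"])
            elif all(x > 0 for x in a):
                codes.append(_STR_CODE["1"])
            else:
                codes.append(_STR_CODE["H"])
        calls.append(codes)
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"]).set_index("marker_id")
    df = pd.DataFrame(calls, index=markers.index, columns=list(vcf.samples), dtype="int8")
    return GenotypeMatrix(markers, df)
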