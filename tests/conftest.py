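import numpy as np
import pandas as pd
import pytest

from rilqtl.expression import ExpressionMatrix
from rilqtl.genotypes import NA, GenotypeMatrix
from rilqtl.simulate import ExpressionArchitecture, PanelSpec, simulate_expression, simulate_genotypes


def make_geno(calls: dict[str, list[int]], chrom: str = "I", spacing: int = 100_000) -> GenotypeMatrix:
    """GenotypeMatrix from {line: calls} with evenly spaced markers."""
    df = pd.DataFrame(calls, dtype="int8")
    pos = (np.arange(len(df)) + 1) * spacing
    markers = pd.DataFrame(
        {"chrom": chrom, "pos_bp": pos}, index=[f"{chrom}:{p}" for p in pos]
    )
    df.index = markers.index
    return GenotypeMatrix(markers, df)


def make_expr(
    values: np.ndarray,
    ril_ids: list[str],
    rep_groups: dict[str, tuple[str, int]] | None = None,
    spots: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """ExpressionMatrix with RIL columns plus replicated strain groups.

    ``rep_groups`` maps strain line id → (strain class, n replicates);
    columns are appended in that order after the RILs.
    """
    cols = list(ril_ids)
    meta = [(l, "RIL", "b1") for l in ril_ids]
    for line, (cls, n) in (rep_groups or {}).items():
        for r in range(n):
            cols.append(f"{line}_r{r + 1}")
            meta.append((line, cls, "b1"))
    values = np.asarray(values, dtype=float)
    assert values.shape[1] == len(cols)
    vals = pd.DataFrame(values, columns=cols)
    vals.index = [f"S{i + 1:04d}" for i in range(len(vals))]
    if spots is None:
        spots = pd.DataFrame(
            {"gene_id": [f"g{i + 1}" for i in range(len(vals))], "chrom": "I",
             "pos_bp": 1000, "is_technical": False},
            index=vals.index,
        )
    else:
        spots = spots.set_axis(vals.index)
    samples = pd.DataFrame(meta, index=cols, columns=["line_id", "strain_class", "batch"])
    return ExpressionMatrix(vals, spots, samples)


@pytest.fixture(scope="session")
def dense_panel():
    """70-line panel at full marker density with planted cis effects and a hotspot."""
    spec = PanelSpec(n_lines=70, n_markers=800, seed=11)
    geno = simulate_genotypes(spec)
    arch = ExpressionArchitecture(
        n_spots=400,
        cis_fraction=0.15,
        trans_hotspots=[(200, 40, (0.6, 0.1))],
        noise_sd=0.3,
        cis_ve_range=(0.3, 0.7),
    )
    expr, truth = simulate_expression(geno, arch, seed=12)
    return geno, expr, truth
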