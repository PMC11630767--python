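"""Single-marker scan, empirical FDR, peaks/intervals, power, trans-bands."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilqtl.eqtl import (
    EqtlScan,
    best_scores,
    best_spot_per_gene,
    call_peaks_and_intervals,
    detect_trans_bands,
    empirical_fdr,
    permuted_best_scores,
    pooled_power,
    power_analysis,
    scan,
    variance_explained,
)
from rilqtl.genotypes import NA
from rilqtl.simulate import ExpressionArchitecture, PanelSpec, simulate_expression, simulate_genotypes

from conftest import make_expr, make_geno


def _expr_for(geno, values):
    return make_expr(values, list(geno.lines))


class TestScan:
    def test_matches_brute_force_regression_oracle(self):
        # independent oracle: scipy.stats.linregress per spot x marker
        rng = np.random.default_rng(0)
        for n_lines in (8, 12, 20):
            lines = {f"L{i}": rng.integers(0, 2, size=6) for i in range(n_lines)}
            geno = make_geno({k: v.tolist() for k, v in lines.items()})
            y = rng.normal(0, 1, (4, n_lines))
            res = scan(_expr_for(geno, y), geno)
            for si in range(4):
                for mi, mk in enumerate(geno.markers.index):
                    g = geno.calls.loc[mk].to_numpy().astype(float)
                    if g.min() == g.max():
                        assert np.isnan(res.neglogp.iloc[si, mi])
                        continue
                    lr = stats.linregress(g, y[si])
                    assert abs(res.neglogp.iloc[si, mi] - (-math.log10(lr.pvalue))) < 1e-10
                    assert abs(res.effect.iloc[si, mi] - lr.slope) < 1e-10

    def test_equals_pooled_t_test(self):
        rng = np.random.default_rng(1)
        geno = make_geno({f"L{i}": [int(i < 5)] for i in range(10)})
        y = rng.normal(0, 1, (3, 10))
        res = scan(_expr_for(geno, y), geno)
        for si in range(3):
            t = stats.ttest_ind(y[si, 5:], y[si, :5], equal_var=True)
            assert np.isclose(res.neglogp.iloc[si, 0], -math.log10(t.pvalue), atol=1e-10)

    def test_noiseless_capped(self):
        geno = make_geno({f"L{i}": [int(i % 2)] for i in range(70)})
        y = geno.calls.to_numpy(dtype=float)  # expression identical to genotype
        res = scan(_expr_for(geno, y), geno)
        assert res.neglogp.iloc[0, 0] == 300.0
        assert np.isclose(res.effect.iloc[0, 0], 1.0)

    def test_het_and_missing_dropped(self):
        from rilqtl.genotypes import HET

        rng = np.random.default_rng(2)
        calls = {f"L{i}": [rng.integers(0, 2)] for i in range(12)}
        calls["L0"], calls["L1"] = [HET], [NA]
        geno = make_geno(calls)
        y = rng.normal(0, 1, (2, 12))
        res = scan(_expr_for(geno, y), geno)
        keep = [i for i in range(12) if i > 1]
        g = np.array([calls[f"L{i}"][0] for i in keep], dtype=float)
        lr = stats.linregress(g, y[0, keep])
        assert np.isclose(res.neglogp.iloc[0, 0], -math.log10(lr.pvalue), atol=1e-10)

    def test_monomorphic_marker_is_nan(self):
        geno = make_geno({"L1": [0, 0], "L2": [1, 0], "L3": [0, 0], "L4": [1, 0]})
        y = np.random.default_rng(3).normal(0, 1, (2, 4))
        res = scan(_expr_for(geno, y), geno)
        assert res.neglogp.iloc[:, 1].isna().all()

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(4)
        geno = make_geno({f"L{i}": [int(i % 2)] for i in range(70)})
        y = rng.normal(0, 1, (800, 70))
        res = scan(_expr_for(geno, y), geno)
        p = 10 ** (-res.neglogp.to_numpy()[:, 0])
        assert stats.kstest(p, "uniform").pvalue > 1e-3


class TestEmpiricalFdr:
    def _oracle(self, real, perm, bound):
        # brute force over all observed score values
        best = None
        for c in sorted(set(real)):
            rds = sum(r >= c for r in real)
            fds = np.mean([sum(x >= c for x in row) for row in perm])
            if rds > 0 and fds / rds <= bound and best is None:
                best = c
        return best

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            real = rng.exponential(2, 40).round(2)
            perm = rng.exponential(1, (5, 40)).round(2)
            res = empirical_fdr(real, perm, q=0.2)
            assert res.cutoff == self._oracle(real.tolist(), perm, 0.2)

    def test_paper_variant_bound(self):
        real = np.array([1.0, 2.0, 3.0])
        perm = np.array([[0.5, 2.5, 0.1]])
        res = empirical_fdr(real, perm, q=0.05, variant="paper", m=45220)
        assert np.isclose(res.bound, 0.05 * math.log(45220))
        assert res.cutoff == self._oracle(real.tolist(), perm, res.bound)

    def test_clean_separation(self):
        # permuted scans all below 3, real has scores above: cutoff at most 3.5
        real = np.array([1.0, 3.5, 6.0])
        perm = np.full((4, 3), 2.0)
        res = empirical_fdr(real, perm, q=0.05)
        assert res.cutoff == 3.5 and res.fds == 0.0

    def test_no_attainable_threshold_warns(self):
        real = np.array([1.0, 1.5])
        perm = np.full((2, 2), 5.0)
        with pytest.warns(UserWarning, match="undefined"):
            res = empirical_fdr(real, perm, q=0.05)
        assert math.isnan(res.cutoff)


class TestPeaksAndIntervals:
    def _scan(self, profiles, chrom="I"):
        markers = pd.DataFrame(
            {"chrom": chrom, "pos_bp": (np.arange(profiles.shape[1]) + 1) * 1000},
            index=[f"{chrom}:{(i + 1) * 1000}" for i in range(profiles.shape[1])],
        )
        idx = [f"S{i + 1:04d}" for i in range(profiles.shape[0])]
        nlp = pd.DataFrame(profiles, index=idx, columns=markers.index)
        return EqtlScan(nlp, nlp * 0 + 0.5, markers)

    def _spots(self, chrom, pos, n=1):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "chrom": chrom, "pos_bp": pos,
             "is_technical": False},
            index=[f"S{i + 1:04d}" for i in range(n)],
        )

    def test_hand_evaluated_drop_rule(self):
        # peak 6 at marker 2; floor 4.5 keeps markers 2-3 (5.1), excludes 4.4 and 2
        sc = self._scan(np.array([[2.0, 6.0, 5.1, 4.4, 2.0]]))
        rec = call_peaks_and_intervals(sc, 4.3, self._spots("I", 2500)).iloc[0]
        assert rec["peak_marker"] == "I:2000"
        assert rec["interval_start_marker"] == "I:2000"
        assert rec["interval_end_marker"] == "I:3000"
        assert rec["qtl_class"] == "cis"  # gene at 2.5 kb inside [2000, 3000]

    def test_monotone_profile_truncates_at_chromosome_end(self):
        sc = self._scan(np.array([[5.2, 5.5, 5.8, 6.1, 6.5]]))
        rec = call_peaks_and_intervals(sc, 4.3, self._spots("I", 1)).iloc[0]
        assert rec["interval_end_marker"] == "I:5000"
        assert rec["interval_start_marker"] == "I:1000"  # no drop attained

    def test_gene_on_other_chromosome_is_trans(self):
        sc = self._scan(np.array([[2.0, 6.0, 5.1, 4.4, 2.0]]))
        rec = call_peaks_and_intervals(sc, 4.3, self._spots("II", 2500)).iloc[0]
        assert rec["qtl_class"] == "trans"

    def test_unannotated_gene_flagged_trans(self):
        spots = self._spots("I", 2500)
        spots["gene_id"] = np.nan
        rec = call_peaks_and_intervals(
            self._scan(np.array([[2.0, 6.0, 5.1, 4.4, 2.0]])), 4.3, spots
        ).iloc[0]
        assert rec["qtl_class"] == "trans" and rec["unannotated"]

    def test_below_cutoff_yields_no_record(self):
        recs = call_peaks_and_intervals(self._scan(np.array([[1.0, 2.0, 1.0]])), 4.3)
        assert recs.empty

    def test_cis_trans_partition(self, dense_panel):
        geno, expr, truth = dense_panel
        sc = scan(expr, geno)
        recs = call_peaks_and_intervals(sc, 4.3, expr.spots)
        assert set(recs["qtl_class"]) <= {"cis", "trans"}
        assert (recs["qtl_class"] == "cis").sum() + (recs["qtl_class"] == "trans").sum() == len(recs)


class TestVarianceExplained:
    def test_noiseless_exact_and_identity_with_pearson(self):
        spec = PanelSpec(n_lines=40, n_markers=60, seed=5, fixed_regions=[])
        geno = simulate_genotypes(spec)
        arch = ExpressionArchitecture(n_spots=20, cis_fraction=1.0, noise_sd=0.25)
        expr, truth = simulate_expression(geno, arch, seed=6)
        sc = scan(expr, geno)
        recs = call_peaks_and_intervals(sc, 2.0, expr.spots)
        recs = variance_explained(expr, geno, recs)
        assert recs["r2"].between(0, 1).all()
        for _, rec in recs.iterrows():
            g = geno.calls.loc[rec["peak_marker"]].to_numpy().astype(float)
            y = expr.values.loc[rec["spot"], geno.lines].to_numpy()
            assert np.isclose(rec["r2"], np.corrcoef(g, y)[0, 1] ** 2, atol=1e-9)

    def test_noiseless_planted_ve_exact(self):
        spec = PanelSpec(n_lines=30, n_markers=40, seed=7, fixed_regions=[])
        geno = simulate_genotypes(spec)
        arch = ExpressionArchitecture(n_spots=10, cis_fraction=1.0, noise_sd=0.0)
        expr, truth = simulate_expression(geno, arch, seed=8)
        sc = scan(expr, geno)
        recs = variance_explained(expr, geno, call_peaks_and_intervals(sc, 100.0, expr.spots))
        assert np.allclose(recs["r2"], 1.0)


class TestBestSpotPerGene:
    def _recs(self, rows):
        return pd.DataFrame(
            rows, columns=["spot", "gene_id", "chrom", "peak_pos", "neglogp", "r2", "effect"]
        )

    def test_highest_r2_kept(self):
        recs = self._recs([("s1", "g1", "I", 5, 6.0, 0.4, 1.0), ("s2", "g1", "I", 5, 5.0, 0.6, 1.0)])
        out = best_spot_per_gene(recs)
        assert out["spot"].tolist() == ["s2"]

    def test_tie_breaks_on_peak_then_spot(self):
        recs = self._recs([
            ("s2", "g1", "I", 5, 5.0, 0.5, 1.0),
            ("s1", "g1", "I", 5, 7.0, 0.5, 1.0),
            ("b", "g2", "I", 5, 7.0, 0.5, 1.0),
            ("a", "g2", "I", 5, 7.0, 0.5, 1.0),
        ])
        out = best_spot_per_gene(recs)
        assert sorted(out["spot"]) == ["a", "s1"]

    def test_single_and_multichrom_kept(self):
        recs = self._recs([("s1", "g1", "I", 5, 6.0, 0.4, 1.0), ("s1", "g1", "II", 9, 5.0, 0.3, 1.0)])
        assert len(best_spot_per_gene(recs)) == 2


class TestTransBands:
    def _records(self, positions, chrom="I"):
        return pd.DataFrame(
            {"spot": [f"s{i}" for i in range(len(positions))], "gene_id": "g",
             "chrom": chrom, "peak_pos": positions, "qtl_class": "trans"}
        )

    def _geno(self, length=10_000_000):
        return make_geno({"L1": [0, 1], "L2": [1, 0]}, spacing=length // 2)

    def test_zero_trans_eqtl_no_bands(self):
        geno = self._geno()
        recs = self._records([])
        res = detect_trans_bands(recs, geno)
        assert res.bands.empty and res.merged.empty

    def test_poisson_tail_oracle(self):
        # lambda = 1.5 over 200 bins; flag iff P(X >= k) < 1e-3 by cumulative oracle
        geno = self._geno(length=100_000_000)  # 200 bins of 0.5 Mb
        rng = np.random.default_rng(9)
        positions = rng.integers(0, 100_000_000, 300)
        recs = self._records(positions.tolist())
        res = detect_trans_bands(recs, geno, p_cut=1e-3)
        lam = 300 / 200
        assert np.isclose(res.lam, lam)

        def tail(k):  # exact Poisson upper tail by summation
            return 1.0 - sum(math.exp(-lam) * lam**j / math.factorial(j) for j in range(k))

        for _, band in res.bands.iterrows():
            assert band["flagged"] == (tail(int(band["count"])) < 1e-3)
            assert np.isclose(band["p"], tail(int(band["count"])), atol=1e-12)

    def test_planted_hotspot_recovered_and_null_clean(self, dense_panel):
        geno, expr, truth = dense_panel
        sc = scan(expr, geno)
        recs = call_peaks_and_intervals(sc, 4.3, expr.spots)
        res = detect_trans_bands(recs, geno, p_cut=1e-3)
        hot_marker = geno.markers.iloc[200]
        hit = res.bands[res.bands["flagged"]]
        assert any(
            (hit["chrom"] == hot_marker["chrom"])
            & (hit["start"] <= hot_marker["pos_bp"])
            & (hit["end"] > hot_marker["pos_bp"])
        )
        # matched null panel: no planted hotspot, few spurious flags
        arch = ExpressionArchitecture(n_spots=400, cis_fraction=0.0, noise_sd=0.3)
        null_expr, _ = simulate_expression(geno, arch, seed=77)
        null_recs = call_peaks_and_intervals(scan(null_expr, geno), 4.3, null_expr.spots)
        null_res = detect_trans_bands(null_recs, geno, p_cut=1e-3)
        if not null_res.bands.empty:
            assert null_res.bands["flagged"].sum() <= max(1, 1e-3 * res.total_bins * 5)

    def test_adjacent_flagged_bins_merge(self):
        geno = self._geno(length=10_000_000)  # 20 bins
        positions = [100] * 10 + [600_000] * 10 + [5_000_000]
        res = detect_trans_bands(self._records(positions), geno, p_cut=1e-3)
        assert res.bands["flagged"].sum() == 2
        assert len(res.merged) == 1
        assert res.merged.iloc[0]["end"] - res.merged.iloc[0]["start"] == 1_000_000


@pytest.fixture(scope="module")
def balanced_geno():
    return simulate_genotypes(
        PanelSpec(n_lines=70, n_markers=120, fixed_regions=[], skew=0.5, seed=21)
    )


class TestPower:

    def test_high_ve_matches_noncentral_f_oracle(self, balanced_geno):
        tab = power_analysis(balanced_geno, cutoff=4.3, ve_grid=[0.8], n_per_marker=20, seed=1)
        # oracle: detection at the causal marker alone is a noncentral-F tail with
        # lambda = n*VE/(1-VE); the genome-wide peak can only beat it via linked markers
        n, ve = 70, 0.8
        crit = stats.f.isf(10**-4.3, 1, n - 2)
        oracle = stats.ncf.sf(crit, 1, n - 2, n * ve / (1 - ve))
        assert tab["power"].iloc[0] >= oracle - 0.02
        assert tab["power"].iloc[0] > 0.99

    def test_detection_monotone_in_ve(self, balanced_geno):
        tab = power_analysis(
            balanced_geno, cutoff=4.3, ve_grid=[0.2, 0.4, 0.6], n_per_marker=10, seed=2
        )
        p = tab["power"].to_numpy()
        assert p[0] <= p[1] + 0.05 and p[1] <= p[2] + 0.05

    def test_vanishing_ve_approaches_type_one_level(self, balanced_geno):
        tab = power_analysis(balanced_geno, cutoff=1.0, ve_grid=[0.01], n_per_marker=10, seed=3)
        # at cutoff 1.0 a null peak among 120 correlated markers passes often, but
        # the linkage requirement keeps detection near the per-test level
        assert tab["power"].iloc[0] < 0.5

    def test_pooled_power(self):
        tab = pd.DataFrame({"ve": [0.3, 0.35, 0.4], "n_sim": [10, 10, 10], "n_detected": [1, 8, 10]})
        assert pooled_power(tab, 0.35) == 18 / 20
        with pytest.raises(ValueError):
            pooled_power(tab, 0.9)


class TestPermutedScores:
    def test_reproducible_and_shaped(self, dense_panel):
        geno, expr, _ = dense_panel
        a = permuted_best_scores(expr, geno, n_datasets=2, seed=3)
        b = permuted_best_scores(expr, geno, n_datasets=2, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (2, len(expr.values))

    def test_best_scores_agree_with_full_scan(self, dense_panel):
        geno, expr, _ = dense_panel
        fast = best_scores(expr, geno)
        full = scan(expr, geno).best_per_spot()
        np.testing.assert_allclose(fast["neglogp"], full["neglogp"], atol=1e-9)
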