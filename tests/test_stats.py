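"""Paired statistics: Wilcoxon oracles, effect sizes, FDR, success rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon

import fewpick as fp


def enumerate_exact_p(diffs):
    """Full 2^n sign-pattern enumeration oracle for the two-sided p."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestWilcoxonSignedRank:
    def test_five_positive_differences_exact(self):
        res = fp.wilcoxon_signed_rank(np.array([0.3, 1.2, 0.7, 2.0, 0.1]))
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 32)
        assert res.w == 15.0 and res.z > 0

    def test_antisymmetric_differences_null_centered(self):
        res = fp.wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0]))
        assert res.w == pytest.approx(10.5)
        assert res.p == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_enumeration_n10(self, seed):
        d = np.random.default_rng(seed).normal(size=10)
        res = fp.wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(enumerate_exact_p(d), abs=1e-12)

    @pytest.mark.parametrize("n", [8, 12, 15])
    def test_matches_scipy_exact(self, n):
        d = np.random.default_rng(n).normal(size=n)
        res = fp.wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(scipy_wilcoxon(d, method="exact").pvalue)

    def test_all_zero_differences_is_no_information(self):
        res = fp.wilcoxon_signed_rank(np.zeros(6))
        assert not res.informative
        assert np.isnan(res.p) and res.n_zero == 6

    def test_zero_differences_dropped_and_counted(self):
        res = fp.wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, -0.5]))
        assert res.n_zero == 2 and res.n_used == 3

    @pytest.mark.parametrize("n", range(10, 16))
    def test_exact_and_normal_paths_agree(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(30):
            d = rng.normal(size=n)
            res = fp.wilcoxon_signed_rank(d)
            assert res.method == "exact"
            from scipy.special import ndtr

            p_norm = min(1.0, 2 * ndtr(-abs(res.z)))
            assert abs(res.p - p_norm) < 0.02

    def test_type_one_error_calibrated_under_null(self):
        """Rejection rate at alpha=0.05 over 2000 null repetitions, N=30."""
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            if fp.wilcoxon_signed_rank(x, y).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestEffectSize:
    def test_arithmetic(self):
        r_paper, r_conv = fp.effect_size(2.0, 16)
        assert r_paper == pytest.approx(0.125)
        assert r_conv == pytest.approx(0.5)

    def test_zero_z(self):
        assert fp.effect_size(0.0, 9) == (0.0, 0.0)

    def test_all_positive_differences_maximal_for_n(self):
        n = 8
        rng = np.random.default_rng(0)
        base = np.abs(rng.normal(size=n)) + 0.1
        z_all_pos = fp.wilcoxon_signed_rank(base).z
        for signs in itertools.product([-1, 1], repeat=n):
            z = fp.wilcoxon_signed_rank(base * np.array(signs)).z
            assert z <= z_all_pos + 1e-12


class TestBhAdjust:
    def test_hand_executed_step_up(self):
        assert np.allclose(fp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fp.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25)
        adj = fp.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fp.bh_adjust([0.1, 1.5])

    def test_family_wise_false_discovery_controlled_under_null(self):
        """Fraction of null families with any adjusted p < 0.05 stays near
        alpha (<= 0.07 at these simulation sizes)."""
        rng = np.random.default_rng(11)
        n_families, tests_per_family = 800, 5
        hits = 0
        for _ in range(n_families):
            ps = [
                fp.wilcoxon_signed_rank(rng.normal(size=30), rng.normal(size=30)).p
                for _ in range(tests_per_family)
            ]
            if (fp.bh_adjust(ps) < 0.05).any():
                hits += 1
        assert hits / n_families <= 0.07


class TestThresholdSuccessRate:
    def test_basic_fraction(self):
        assert fp.threshold_success_rate([0.7, 0.5, 0.9], [0.6])[0] == pytest.approx(
            2 / 3
        )

    def test_zero_threshold_full_success(self):
        assert fp.threshold_success_rate([0.1, 0.2], [0.0])[0] == 1.0

    def test_matches_direct_counting(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(size=40)
        taus = [0.2, 0.5, 0.8]
        got = fp.threshold_success_rate(v, taus)
        assert np.allclose(got, [(v >= t).sum() / 40 for t in taus])


def make_metric_table(n_methods=5, n_datasets=6, n_micros=8, seed=0, clone_ref=False):
    rng = np.random.default_rng(seed)
    rows = []
    ref_vals = {}
    for ds in range(n_datasets):
        for mic in range(n_micros):
            v = rng.uniform(0.4, 0.9)
            ref_vals[(ds, mic)] = v
            rows.append(
                dict(method="ref", dataset=f"d{ds}", micrograph=f"m{mic}",
                     precision=v, recall=min(1.0, v + 0.05))
            )
    for k in range(n_methods):
        for ds in range(n_datasets):
            for mic in range(n_micros):
                v = (
                    ref_vals[(ds, mic)]
                    if clone_ref
                    else np.clip(ref_vals[(ds, mic)] - rng.uniform(0, 0.3), 0, 1)
                )
                rows.append(
                    dict(method=f"comp{k}", dataset=f"d{ds}", micrograph=f"m{mic}",
                         precision=v, recall=v)
                )
    return pd.DataFrame(rows)


class TestCompareMethods:
    def test_five_by_six_gives_thirty_tests_per_metric(self):
        report = fp.compare_methods(make_metric_table(), "ref")
        per_metric = report.groupby("metric").size()
        assert (per_metric == 30).all()

    def test_single_pair_bh_is_identity(self):
        table = make_metric_table(n_methods=1, n_datasets=1)
        report = fp.compare_methods(table, "ref", metrics=("precision",))
        assert len(report) == 1
        assert report.p_adj.iloc[0] == pytest.approx(report.p_raw.iloc[0])

    def test_competitor_identical_to_reference_is_no_information(self):
        table = make_metric_table(n_methods=2, clone_ref=True)
        report = fp.compare_methods(table, "ref", metrics=("precision",))
        assert (report["test"] == "none").all()
        assert report.p_raw.isna().all()

    def test_misaligned_micrographs_rejected_naming_dataset(self):
        table = make_metric_table()
        table = table[
            ~((table.method == "comp0") & (table.dataset == "d2")
              & (table.micrograph == "m0"))
        ]
        with pytest.raises(ValueError, match="d2"):
            fp.compare_methods(table, "ref")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            fp.compare_methods(make_metric_table(), "nope")
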