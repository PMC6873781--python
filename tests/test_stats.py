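"""Statistical layer: rank tests, FDR, correlations, variance checks, band power."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from msdyn import (
    EEGRecording,
    ParameterError,
    UndefinedStatisticError,
    alpha_band_power,
    bh_fdr,
    compare_groups,
    correlate_clinical,
    levene_test,
    mann_whitney_z,
    spearman_rho,
    students_t,
)


def brute_force_u(x, y):
    """U by direct pair counting: #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    x, y = np.asarray(x), np.asarray(y)
    gt = np.sum(x[:, None] > y[None, :])
    eq = np.sum(x[:, None] == y[None, :])
    return gt + 0.5 * eq


def brute_force_bh(p, m=None):
    p = np.asarray(p, dtype=float)
    m = m or p.size
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(
            min(p[j] * m / rank_j for rank_j, j in enumerate(order, start=1) if rank_j >= rank_i),
            1.0,
        )
    return q


class TestMannWhitney:
    def test_separated_samples(self):
        u, z, p = mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert z < 0

    def test_exact_enumeration_oracle(self):
        """Two-sided exact p for fully separated n=3 samples is 0.1 (2 of 20 splits)."""
        values = [1, 2, 3, 4, 5, 6]
        observed = brute_force_u(values[:3], values[3:])
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [values[i] for i in combo]
            ys = [values[i] for i in range(6) if i not in combo]
            u = brute_force_u(xs, ys)
            mu = 4.5
            if abs(u - mu) >= abs(observed - mu):
                count += 1
            total += 1
        assert total == 20
        assert count / total == pytest.approx(0.1)

    def test_identical_samples(self):
        x = [1.0, 2.0, 2.0, 5.0]
        u, z, p = mann_whitney_z(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert z == 0.0
        assert p == 1.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(0.5, size=6)
        u1, z1, p1 = mann_whitney_z(x, y)
        u2, z2, p2 = mann_whitney_z(y, x)
        assert u1 + u2 == pytest.approx(len(x) * len(y))
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=10),
        st.lists(st.integers(0, 5), min_size=1, max_size=10),
    )
    def test_u_equals_pair_counting(self, x, y):
        u, _, _ = mann_whitney_z(x, y)
        assert u == brute_force_u(x, y)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
            u, z, p = mann_whitney_z(x, y)
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert u == pytest.approx(ref.statistic)
            if not np.all(np.concatenate([x, y]) == x[0]):
                assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestBhFdr:
    def test_published_coverage_family(self):
        """BH on a five-test family (0.009, 0.005, 0.09, 0.86, 0.84)."""
        q = bh_fdr([0.009, 0.005, 0.09, 0.86, 0.84])
        np.testing.assert_allclose(q, [0.0225, 0.0225, 0.15, 0.86, 0.86])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_stepup_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.1, 1.5])

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 12))
            q = bh_fdr(p)
            np.testing.assert_allclose(q, brute_force_bh(p), rtol=0, atol=0)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)
        assert np.all(bh_fdr(p) >= p)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=10)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= 0)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1).rho == pytest.approx(1.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_equals_pearson_on_midranks(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 6, size=12).astype(float)
            y = rng.integers(0, 6, size=12).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho = spearman_rho(x, y).rho
            ref = scipy.stats.pearsonr(
                scipy.stats.rankdata(x), scipy.stats.rankdata(y)
            ).statistic
            assert rho == pytest.approx(ref, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestLevene:
    def test_identical_dispersion_gives_zero(self):
        w, p = levene_test([1.0, 3.0], [5.0, 7.0])
        assert w == pytest.approx(0.0)

    def test_extreme_dispersion_difference(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            w, p = levene_test([0.0, 0.0, 0.0, 0.0], [-10.0, 10.0, -10.0, 10.0])
        assert w > 100 or np.isinf(w)
        assert p < 0.01

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(scale=3.0, size=8)
        w1, _ = levene_test(a, b)
        w2, _ = levene_test(rng.permutation(a), rng.permutation(b))
        assert w1 == pytest.approx(w2)


class TestStudentsT:
    def test_identical_samples(self):
        t, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            students_t([0.0, 0.0], [1.0, 1.0])

    def test_hand_arithmetic(self):
        t, _ = students_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.0 / np.sqrt(2 / 3), abs=1e-4)  # -1.2247


class TestAlphaPower:
    def _sine_rec(self, freq, amplitude=1.0, fs=125.0, seconds=8.0):
        t = np.arange(int(fs * seconds)) / fs
        wave = amplitude * np.sin(2 * np.pi * freq * t)
        return EEGRecording(
            data=np.vstack([wave, -wave]), fs=fs, channel_names=("a", "b"),
            reference="average",
        )

    def test_in_band_sinusoid_parseval(self):
        rec = self._sine_rec(10.0, amplitude=2.0)
        power = alpha_band_power(rec)
        assert power == pytest.approx(2.0**2 / 2, rel=0.05)

    def test_out_of_band_sinusoid(self):
        rec = self._sine_rec(20.0)
        in_band = alpha_band_power(rec, band=(8.0, 14.0))
        total = alpha_band_power(rec, band=(1.0, 40.0))
        assert in_band < 0.01 * total

    def test_quadratic_amplitude_scaling(self):
        p1 = alpha_band_power(self._sine_rec(10.0, amplitude=1.0))
        p2 = alpha_band_power(self._sine_rec(10.0, amplitude=2.0))
        assert p2 == pytest.approx(4 * p1, rel=1e-6)

    def test_short_recording_rejected(self):
        rec = self._sine_rec(10.0, seconds=1.0)
        with pytest.raises(ParameterError):
            alpha_band_power(rec, window_sec=2.0)

    def test_low_fs_rejected(self):
        rec = self._sine_rec(5.0, fs=20.0)
        with pytest.raises(ParameterError):
            alpha_band_power(rec, band=(8.0, 14.0))


def _toy_table(rng, n=8, k=3, shift=None):
    rows = []
    for g, prefix in (("patient", "p"), ("control", "c")):
        for i in range(n):
            for cls in range(k):
                occ = rng.normal(3.0, 0.3)
                if shift and g == "patient" and cls == shift[0]:
                    occ *= 1 + shift[1]
                rows.append({
                    "subject": f"{prefix}{i}", "group": g, "class": cls,
                    "occurrence": occ, "coverage": rng.normal(33.0, 3.0),
                    "duration": rng.normal(80.0, 8.0),
                })
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_table_shape_and_fdr_monotonicity(self):
        table = _toy_table(np.random.default_rng(6))
        out = compare_groups(table)
        assert len(out) == 3 * 3  # parameters x classes
        assert np.all(out["p_fdr"] >= out["p"] - 1e-12)
        assert np.all((out["p"] >= 0) & (out["p_fdr"] <= 1))

    def test_strong_planted_shift_detected(self):
        table = _toy_table(np.random.default_rng(7), n=15, shift=(1, 0.5))
        out = compare_groups(table)
        row = out[(out["parameter"] == "occurrence") & (out["class"] == 1)].iloc[0]
        assert row["p_fdr"] < 0.05
        assert row["mean_patient"] > row["mean_control"]

    def test_missing_class_treated_as_zero(self):
        table = _toy_table(np.random.default_rng(8))
        table = table[~((table["subject"] == "p0") & (table["class"] == 2))]
        out = compare_groups(table)
        assert len(out) == 9  # still a full parameters x classes grid

    def test_single_subject_group_rejected(self):
        table = _toy_table(np.random.default_rng(9), n=4)
        table = table[(table["group"] == "control") | (table["subject"] == "p0")]
        with pytest.raises(ParameterError):
            compare_groups(table)


class TestCorrelateClinical:
    def _scores(self, table, link=None, rng=None):
        subs = table[["subject", "group"]].drop_duplicates()
        cov = table[table["class"] == 1].set_index("subject")["coverage"]
        rows = []
        for _, r in subs.iterrows():
            base = cov[r["subject"]]
            rows.append({
                "subject": r["subject"], "group": r["group"],
                "MADRS": 2, "YMRS": 1,
                "STAI_state": float(np.clip(base, 20, 80)),
                "STAI_trait": float(np.clip(
                    base + (rng.normal(0, 0.5) if rng is not None else 0), 20, 80)),
            })
        return pd.DataFrame(rows)

    def test_identical_column_perfect_rho(self):
        table = _toy_table(np.random.default_rng(10))
        scores = self._scores(table)
        res = correlate_clinical(table, scores, [("coverage", 1)],
                                 score_columns=("STAI_state",))
        assert res[0].rho == pytest.approx(1.0)

    def test_planted_monotone_link(self):
        rng = np.random.default_rng(11)
        table = _toy_table(rng, n=17)
        scores = self._scores(table, rng=rng)
        res = correlate_clinical(table, scores, [("coverage", 1)],
                                 score_columns=("STAI_trait",))
        assert res[0].rho > 0.8

    def test_constant_score_reported_missing(self):
        table = _toy_table(np.random.default_rng(12))
        scores = self._scores(table)
        res = correlate_clinical(table, scores, [("coverage", 1)],
                                 score_columns=("MADRS",))
        assert res == []
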