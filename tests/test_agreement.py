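"""Agreement statistics: ICC(C,1), Bland–Altman, paired regression."""

import numpy as np
import pytest
from scipy import stats

import adipoquant as aq


def _paired(a, b, name="v"):
    a = np.asarray(a, dtype=float)
    return aq.PairedMeasurements(list(range(len(a))), a, np.asarray(b, dtype=float), name)


def icc_oracle(matrix: np.ndarray, alpha: float = 0.05):
    """Independent ICC(C,1) via explicit loop-based sums of squares and the
    Shrout–Fleiss closed-form confidence interval."""
    n, k = matrix.shape
    grand = sum(matrix[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(matrix[i, :]) / k for i in range(n)]
    col_means = [sum(matrix[:, j]) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((matrix[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse)
    f = msr / mse
    fl = f / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
    fu = f * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
    low = (fl - 1) / (fl + k - 1)
    high = (fu - 1) / (fu + k - 1)
    p = stats.f.sf(f, n - 1, (n - 1) * (k - 1))
    return icc, low, high, f, p


class TestICCConsistency:
    def test_perfect_agreement(self):
        r = aq.icc_consistency(_paired([1, 2, 3], [1, 2, 3]))
        assert r.icc == pytest.approx(1.0)

    def test_constant_offset_is_ignored(self):
        # Consistency ICC is insensitive to a fixed shift between methods.
        r = aq.icc_consistency(_paired([1, 2, 3], [2, 3, 4]))
        assert r.icc == pytest.approx(1.0)
        assert r.f_pvalue == 0.0

    def test_matches_anova_oracle_on_seeded_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            subj = rng.normal(0, 1, size=50)
            mat = subj[:, None] + rng.normal(0, 0.5, size=(50, 2))
            r = aq.icc_consistency(_paired(mat[:, 0], mat[:, 1]))
            icc, low, high, f, p = icc_oracle(mat)
            assert r.icc == pytest.approx(icc, abs=1e-10)
            assert r.ci_low == pytest.approx(low, abs=1e-10)
            assert r.ci_high == pytest.approx(high, abs=1e-10)
            assert r.f_stat == pytest.approx(f, abs=1e-10)
            assert r.f_pvalue == pytest.approx(p, abs=1e-12)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        subj = rng.normal(0, 1, size=40)
        mat = subj[:, None] + rng.normal(0, 0.4, size=(40, 2))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["a", "b"], 40),
                "value": mat.ravel(),
            }
        )
        out = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="value")
        icc3 = out.set_index("Type").loc["ICC(C,1)"]
        r = aq.icc_consistency(_paired(mat[:, 0], mat[:, 1]))
        assert r.icc == pytest.approx(icc3["ICC"], abs=1e-8)
        assert r.f_stat == pytest.approx(icc3["F"], abs=1e-8)
        assert r.f_pvalue == pytest.approx(icc3["pval"], rel=1e-6)
        lo, hi = icc3["CI95"]  # pingouin rounds its CI to 2 decimals
        assert r.ci_low == pytest.approx(lo, abs=0.006)
        assert r.ci_high == pytest.approx(hi, abs=0.006)

    def test_shift_invariance_is_exact(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 30)
        b = a + rng.normal(0, 0.5, 30)
        r1 = aq.icc_consistency(_paired(a, b))
        r2 = aq.icc_consistency(_paired(a, b + 1234.5))
        assert r1.icc == pytest.approx(r2.icc, abs=1e-9)

    def test_symmetric_under_column_swap(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 25)
        b = a + rng.normal(0, 0.3, 25)
        assert aq.icc_consistency(_paired(a, b)).icc == pytest.approx(
            aq.icc_consistency(_paired(b, a)).icc, abs=1e-12
        )

    def test_degenerate_identical_values(self):
        with pytest.raises(aq.DegenerateDataError):
            aq.icc_consistency(_paired([5, 5, 5], [5, 5, 5]))

    def test_ci_is_proper_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            subj = rng.normal(0, 1, size=20)
            mat = subj[:, None] + rng.normal(0, 0.8, size=(20, 2))
            r = aq.icc_consistency(_paired(mat[:, 0], mat[:, 1]))
            assert r.ci_low <= r.icc <= r.ci_high

    def test_estimate_converges_to_variance_ratio(self):
        # With subject variance 1 and noise variance 0.25 the population
        # consistency ICC is 1/(1+0.25) = 0.8.
        rng = np.random.default_rng(11)
        subj = rng.normal(0, 1.0, size=2000)
        mat = subj[:, None] + rng.normal(0, 0.5, size=(2000, 2))
        r = aq.icc_consistency(_paired(mat[:, 0], mat[:, 1]))
        assert r.icc == pytest.approx(0.8, abs=0.03)

    def test_reliability_labels(self):
        from adipoquant.agreement import reliability_label

        assert reliability_label(0.95) == "excellent"
        assert reliability_label(0.80) == "good"
        assert reliability_label(0.60) == "moderate"
        assert reliability_label(0.10) == "poor"


class TestBlandAltman:
    def test_identical_columns(self):
        r = aq.bland_altman(_paired([1, 2, 3], [1, 2, 3]))
        assert r.mean_diff == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset_sign_convention(self):
        # d = A − B: if B reads 13.7 units higher everywhere, the mean
        # difference is −13.7 with zero spread.
        a = np.array([100.0, 200.0, 300.0])
        r = aq.bland_altman(_paired(a, a + 13.7))
        assert r.mean_diff == pytest.approx(-13.7)
        assert r.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_limits_cover_95_percent(self):
        rng = np.random.default_rng(13)
        a = rng.normal(50, 10, 10_000)
        b = a + rng.normal(0, 2, 10_000)
        r = aq.bland_altman(_paired(a, b))
        d = a - b
        coverage = np.mean((d >= r.loa_low) & (d <= r.loa_high))
        assert 0.94 <= coverage <= 0.96

    def test_points_table(self):
        r = aq.bland_altman(_paired([1.0, 3.0], [2.0, 5.0]))
        assert list(r.ba_points["mean"]) == [1.5, 4.0]
        assert list(r.ba_points["difference"]) == [-1.0, -2.0]


class TestPairedRegression:
    def test_identity(self):
        s, i, r = aq.paired_regression(_paired([1, 2, 3], [1, 2, 3]))
        assert (s, i, r) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(1.0))

    def test_anticorrelation(self):
        *_, r = aq.paired_regression(_paired([1, 2, 3], [-1, -2, -3]))
        assert r == pytest.approx(-1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 3, 60)
        b = 1.7 * a + 0.4 + rng.normal(0, 1, 60)
        s, i, _ = aq.paired_regression(_paired(a, b))
        X = np.column_stack([np.ones_like(a), a])
        beta = np.linalg.solve(X.T @ X, X.T @ b)
        assert i == pytest.approx(beta[0], abs=1e-12)
        assert s == pytest.approx(beta[1], abs=1e-12)

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            aq.paired_regression(_paired([2, 2, 2], [1, 2, 3]))


class TestIO:
    def test_wide_csv(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("subject_id,a_value,b_value\n1,10,11\n2,20,21\n3,30,29\n")
        d = aq.read_paired_csv(p)
        assert d.n == 3 and d.method_a[1] == 20

    def test_long_csv_with_variable(self, tmp_path):
        p = tmp_path / "long.csv"
        rows = ["subject_id,method,variable,value"]
        for s in (1, 2, 3):
            rows.append(f"{s},x,area,{s*10}")
            rows.append(f"{s},y,area,{s*10+1}")
            rows.append(f"{s},x,count,{s}")
            rows.append(f"{s},y,count,{s}")
        p.write_text("\n".join(rows) + "\n")
        d = aq.read_paired_csv(p, variable="area")
        assert d.n == 3 and list(d.method_b - d.method_a) == [1.0, 1.0, 1.0]

    def test_listwise_deletion(self, tmp_path):
        p = tmp_path / "missing.csv"
        p.write_text("subject_id,a_value,b_value\n1,10,11\n2,,21\n3,30,29\n")
        d = aq.read_paired_csv(p)
        assert d.n == 2

    def test_missing_values_rejected_in_constructor(self):
        with pytest.raises(ValueError):
            _paired([1, np.nan], [1, 2])


def test_analyze_agreement_combines_all(tmp_path):
    rng = np.random.default_rng(19)
    a = rng.normal(300, 60, 52)
    b = a + rng.normal(-13.7, 10, 52)
    r = aq.analyze_agreement(_paired(a, b, "count"))
    assert r.ci_low <= r.icc <= r.ci_high
    assert r.loa_low <= r.mean_diff <= r.loa_high
    assert np.isfinite(r.slope) and np.isfinite(r.r)
    assert r.reliability in {"excellent", "good", "moderate", "poor"}
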