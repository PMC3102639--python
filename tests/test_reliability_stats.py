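"""ICC estimation against brute-force ANOVA and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from spinetorsion import (
    DegenerateDataError,
    IncompleteDesignError,
    MeasurementTable,
    ParameterError,
    icc_single,
    interobserver_icc,
    intraobserver_icc,
)


def icc2_bruteforce(x):
    """Independent oracle: ICC(2,1) from sums of squares computed by definition."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIccSingle:
    def test_identical_columns_give_perfect_agreement(self):
        x = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        res = icc_single(x)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_worked_four_by_two_example(self):
        # MSR = 40/3, MSC = 2, MSE = 0 -> ICC = (40/3)/(40/3 + 1) = 40/43
        res = icc_single(np.array([[1, 2], [3, 4], [5, 6], [7, 8]], float))
        assert res.estimate == pytest.approx(40 / 43, abs=1e-12)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert "two-way random" in res.model_label

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            icc_single(np.full((4, 2), 3.0))

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            x = rng.normal(0, 5, size=(10, 3)) + rng.normal(0, 2, size=(10, 1))
            assert icc_single(x).estimate == pytest.approx(
                icc2_bruteforce(x), abs=1e-10
            )

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(0, 6, size=(30, 1)) + rng.normal(0, 2, size=(30, 3))
        x = x + np.array([0.0, 0.5, 1.0])
        mine = icc_single(x)
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(30), 3),
                "r": np.tile(np.arange(3), 30),
                "y": x.ravel(),
            }
        )
        row = pg.intraclass_corr(df, "s", "r", "y").set_index("Type").loc["ICC(A,1)"]
        assert mine.estimate == pytest.approx(float(row["ICC"]), abs=1e-9)
        lo, hi = row["CI95"]
        assert mine.ci_low == pytest.approx(float(lo), abs=0.01)
        assert mine.ci_high == pytest.approx(float(hi), abs=0.01)

    def test_scale_shift_equivariance(self, rng):
        x = rng.normal(10, 4, size=(12, 3))
        base = icc_single(x).estimate
        assert icc_single(2.5 * x - 7.0).estimate == pytest.approx(base, abs=1e-12)
        assert icc_single(-1.0 * x + 3.0).estimate == pytest.approx(base, abs=1e-12)

    def test_too_few_subjects_or_columns(self):
        with pytest.raises(IncompleteDesignError):
            icc_single(np.ones((2, 2)))
        with pytest.raises(IncompleteDesignError):
            icc_single(np.ones((5, 1)))

    def test_negative_estimate_warns_not_truncated(self):
        # anti-correlated columns: MSR < MSE forces a negative estimate
        x = np.array([[1.0, -1.0], [-1.0, 1.0], [2.0, -2.0], [-2.0, 2.0], [0.5, -0.5]])
        with pytest.warns(UserWarning, match="negative ICC"):
            res = icc_single(x)
        assert res.estimate < 0

    def test_closed_form_recovery_one_way_model(self):
        """sigma_s = 6, sigma_e = 2, n = 500, k = 3: population ICC = 36/40."""
        rng = np.random.default_rng(77)
        x = rng.normal(0, 6, size=(500, 1)) + rng.normal(0, 2, size=(500, 3))
        assert icc_single(x).estimate == pytest.approx(0.9, abs=0.02)


class TestTableIcc:
    def test_noiseless_table_gives_unit_icc(self, noiseless_table):
        for method in ("ho", "new"):
            intra = intraobserver_icc(noiseless_table, method)
            assert all(
                r.estimate == pytest.approx(1.0, abs=1e-9) for r in intra.values()
            )
            inter = interobserver_icc(noiseless_table, method)
            assert inter.estimate == pytest.approx(1.0, abs=1e-9)

    def test_paper_scale_noisy_table_structure(self, noisy_table):
        for method in ("ho", "new"):
            intra = intraobserver_icc(noisy_table, method)
            assert len(intra) == 3
            for res in intra.values():
                assert res.ci_low <= res.estimate <= res.ci_high
                assert res.n_subjects == 25 and res.n_raters_or_occasions == 2

    def test_landmark_noise_hits_study_reliability_band(self, noisy_table):
        """At 0.4 mm landmark noise the simulated ICCs fall in the observed
        0.90-0.99 band, with Ho's bisector no more reliable than the chord."""
        for method in ("ho", "new"):
            for res in intraobserver_icc(noisy_table, method).values():
                assert 0.90 <= res.estimate <= 0.999
            assert 0.90 <= interobserver_icc(noisy_table, method).estimate <= 0.999

    def test_single_occasion_is_incomplete(self, small_cohort):
        from spinetorsion import simulate_observers

        table = simulate_observers(small_cohort, 3, 1, 0.4, seed=1)
        with pytest.raises(IncompleteDesignError):
            intraobserver_icc(table, "new")

    def test_unbalanced_coverage_is_incomplete(self, noisy_table):
        df = noisy_table.data
        df = df[~((df["subject_id"] == df["subject_id"].iloc[0]) & (df["observer"] == 2))]
        with pytest.raises(IncompleteDesignError):
            interobserver_icc(MeasurementTable(df), "new")

    def test_occasion_policy_validated(self, noisy_table):
        with pytest.raises(ParameterError):
            interobserver_icc(noisy_table, "new", occasion_policy="median")

    def test_mean_policy_at_least_as_reliable_as_first(self, noisy_table):
        # averaging occasions shrinks within-cell noise
        for method in ("ho", "new"):
            first = interobserver_icc(noisy_table, method, "first").estimate
            mean = interobserver_icc(noisy_table, method, "mean").estimate
            assert mean >= first - 0.02
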