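"""Clock representation, transforms, prediction, error summaries,
extreme-deviation overlap, and replicate ICC."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockdissect.clocks import (AgePrediction, ClockModel, clock_concordance,
                                 extreme_deviation_overlap,
                                 horvath_forward_transform,
                                 horvath_inverse_transform,
                                 icc_2way_mean_rating, icc_absolute_agreement,
                                 predict_age, prediction_error_summary,
                                 read_clock_model, write_clock_model,
                                 zhang_standardize)


def toy_clock(transform="identity", **kw):
    return ClockModel(name="toy", intercept=10.0,
                      coefficients={"cg1": 2.0, "cg2": -1.0},
                      transform=transform, **kw)


class TestClockIO:
    def test_three_row_file_parses(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("#transform=identity\nid,coef\n(Intercept),10\ncg1,2.0\ncg2,-1.0\n")
        m = read_clock_model(p)
        assert m.intercept == 10 and m.coefficients == {"cg1": 2.0, "cg2": -1.0}

    def test_duplicate_cpg_named_in_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,coef\n(Intercept),1\ncg1,2.0\ncg1,3.0\n")
        with pytest.raises(ValueError, match="cg1"):
            read_clock_model(p)

    def test_missing_intercept_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,coef\ncg1,2.0\n")
        with pytest.raises(ValueError, match="Intercept"):
            read_clock_model(p)

    def test_non_numeric_weight_reports_row(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,coef\n(Intercept),1\ncg1,abc\n")
        with pytest.raises(ValueError, match="row 3"):
            read_clock_model(p)

    def test_roundtrip_preserves_model(self, tmp_path):
        m = ClockModel(name="rt", intercept=-3.25,
                       coefficients={"cg1": 0.1234567890123, "cg2": -9.5},
                       transform="horvath", adult_age=20.0,
                       training_means={"cg1": 0.5, "cg2": 0.25})
        p = tmp_path / "m.csv"
        write_clock_model(m, p)
        back = read_clock_model(p)
        assert back.intercept == m.intercept
        assert back.coefficients == m.coefficients
        assert back.training_means == m.training_means
        assert back.transform == "horvath" and back.adult_age == 20.0


class TestTransforms:
    def test_horvath_fixed_points(self):
        assert horvath_inverse_transform(0.0) == pytest.approx(20.0)
        assert horvath_inverse_transform(1.0) == pytest.approx(41.0)

    def test_horvath_monotone_and_continuous(self):
        x = np.linspace(-3, 4, 2001)
        y = horvath_inverse_transform(x)
        assert (np.diff(y) > 0).all()

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=120.0))
    def test_horvath_inverse_of_forward_is_identity(self, age):
        back = horvath_inverse_transform(horvath_forward_transform(age))
        assert abs(back - age) < 1e-9

    def test_zhang_rows_standardized(self):
        b = pd.DataFrame([[0.2, 0.4, 0.6]], index=["s1"], columns=["a", "b", "c"])
        z = zhang_standardize(b)
        assert abs(z.values.mean()) < 1e-10
        assert abs(z.values.std(ddof=0) - 1) < 1e-10

    def test_zhang_idempotent(self):
        b = pd.DataFrame(np.random.default_rng(0).random((4, 20)))
        once = zhang_standardize(b)
        twice = zhang_standardize(once)
        assert np.abs(once.values - twice.values).max() < 1e-10

    def test_zhang_constant_row_names_sample(self):
        b = pd.DataFrame([[0.5, 0.5]], index=["badguy"], columns=["a", "b"])
        with pytest.raises(ValueError, match="badguy"):
            zhang_standardize(b)


class TestPredictAge:
    def test_hand_arithmetic_identity(self):
        beta = pd.DataFrame([[0.5, 0.5]], index=["s1"], columns=["cg1", "cg2"])
        pred = predict_age(toy_clock(), beta)
        assert pred.predicted["s1"] == pytest.approx(10.5)
        assert pred.n_missing_cpgs["s1"] == 0

    def test_horvath_zero_score_gives_adult_age(self):
        clock = ClockModel(name="h", intercept=0.0,
                           coefficients={"cg1": 1.0, "cg2": -1.0},
                           transform="horvath")
        beta = pd.DataFrame([[0.3, 0.3]], index=["s1"], columns=["cg1", "cg2"])
        assert predict_age(clock, beta).predicted["s1"] == pytest.approx(20.0)

    def test_missing_cpg_imputed_from_training_mean(self):
        clock = toy_clock(training_means={"cg1": 0.5, "cg2": 0.25})
        beta = pd.DataFrame([[0.5]], index=["s1"], columns=["cg1"])
        # cg2 missing entirely: 50% missing needs a raised threshold
        pred = predict_age(clock, beta, max_missing_frac=0.6)
        assert pred.predicted["s1"] == pytest.approx(10 + 2 * 0.5 - 1 * 0.25)
        assert pred.n_missing_cpgs["s1"] == 1

    def test_nan_cells_imputed_from_cohort_mean(self):
        clock = toy_clock()
        beta = pd.DataFrame({"cg1": [0.4, 0.6, np.nan], "cg2": [0.2, 0.2, 0.2]},
                            index=["a", "b", "c"])
        pred = predict_age(clock, beta, max_missing_frac=0.6)
        assert pred.predicted["c"] == pytest.approx(10 + 2 * 0.5 - 1 * 0.2)
        assert list(pred.n_missing_cpgs) == [0, 0, 1]

    def test_excess_missing_rejected(self):
        clock = toy_clock(training_means={"cg1": 0.5, "cg2": 0.25})
        beta = pd.DataFrame([[0.5]], index=["s1"], columns=["cg1"])
        with pytest.raises(ValueError, match="missing"):
            predict_age(clock, beta, max_missing_frac=0.2)

    def test_all_missing_rejected(self):
        beta = pd.DataFrame([[0.5]], index=["s1"], columns=["cgX"])
        with pytest.raises(ValueError, match="all clock CpGs"):
            predict_age(toy_clock(), beta, max_missing_frac=1.0)

    def test_identity_clock_is_linear_in_samples(self):
        rng = np.random.default_rng(3)
        beta = pd.DataFrame(rng.random((2, 2)), index=["a", "b"],
                            columns=["cg1", "cg2"])
        lam = 0.3
        mix = pd.DataFrame([lam * beta.loc["a"] + (1 - lam) * beta.loc["b"]],
                           index=["mix"])
        clock = toy_clock()
        pa, pb = predict_age(clock, beta).predicted
        pm = predict_age(clock, mix).predicted["mix"]
        assert abs(pm - (lam * pa + (1 - lam) * pb)) < 1e-10

    def test_zhang_prediction_invariant_to_row_shift(self):
        rng = np.random.default_rng(4)
        beta = pd.DataFrame(rng.random((3, 50)) * 0.5,
                            columns=[f"cg{i}" for i in range(50)])
        clock = ClockModel(name="z", intercept=40.0,
                           coefficients={"cg0": 1.0, "cg1": -2.0, "cg2": 0.5},
                           transform="zhang")
        base = predict_age(clock, beta).predicted
        shifted = predict_age(clock, beta + 0.17).predicted
        assert np.abs(base - shifted).max() < 1e-10


class TestErrorSummaries:
    def test_mae_hand_example(self):
        pred = AgePrediction("c", pd.Series([30.0, 40.0], index=["a", "b"]),
                             pd.Series([0, 0], index=["a", "b"]))
        ages = pd.Series([28.0, 44.0, 50.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            prediction_error_summary(pred, ages)  # misaligned
        pred3 = AgePrediction("c", pd.Series([30.0, 40.0, 52.0], index=["a", "b", "c"]),
                              pd.Series(0, index=["a", "b", "c"]))
        s = prediction_error_summary(pred3, ages)
        assert s.mae == pytest.approx((2 + 4 + 2) / 3)
        assert s.mae == pytest.approx(np.abs(s.errors).mean())

    def test_perfect_prediction(self):
        ages = pd.Series([30.0, 40.0, 50.0], index=list("abc"))
        pred = AgePrediction("c", ages.copy(), pd.Series(0, index=ages.index))
        s = prediction_error_summary(pred, ages)
        assert s.mae == 0 and s.pearson_r == pytest.approx(1.0)

    def test_identical_error_vectors_have_unit_concordance(self):
        errs = pd.Series([1.0, -2.0, 3.0], index=list("abc"))
        s1 = type("S", (), {"clock_name": "x", "errors": errs})()
        s2 = type("S", (), {"clock_name": "y", "errors": errs.copy()})()
        conc = clock_concordance([s1, s2])
        assert conc.loc["x", "y"] == pytest.approx(1.0)
        assert (conc.values == conc.values.T).all()


class TestExtremeOverlap:
    def test_identical_vectors_full_overlap(self):
        e = pd.Series([12.0, -3.0, 15.0, 2.0])
        out = extreme_deviation_overlap({"a": e, "b": e.copy()})
        assert out.loc["a", "b"] == 100.0

    def test_disjoint_extremes(self):
        a = pd.Series([12.0, 0.0, 0.0])
        b = pd.Series([0.0, 12.0, 0.0])
        out = extreme_deviation_overlap({"a": a, "b": b})
        assert out.loc["a", "b"] == 0.0

    def test_no_extreme_row_flagged_nan(self):
        a = pd.Series([1.0, 2.0])
        b = pd.Series([12.0, 1.0])
        out = extreme_deviation_overlap({"a": a, "b": b})
        assert np.isnan(out.loc["a", "b"])
        assert out.loc["b", "a"] == 0.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(8)
        errs = {c: pd.Series(rng.normal(0, 8, 300)) for c in "abc"}
        out = extreme_deviation_overlap(errs, threshold=10)
        for x in "abc":
            ex = np.flatnonzero(errs[x] >= 10)
            for y in "abc":
                expect = 100.0 * np.mean(errs[y].values[ex] >= 10) if len(ex) else np.nan
                got = out.loc[x, y]
                assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            extreme_deviation_overlap({"a": pd.Series([1.0]), "b": pd.Series([1.0])},
                                      threshold=0)


class TestICC:
    def test_identical_replicates_give_unity(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_2way_mean_rating(x) == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(200, 2))
        assert abs(icc_2way_mean_rating(x)) < 0.15

    def test_small_table_matches_anova_closed_form(self):
        x = np.array([[9.0, 2.0], [7.5, 8.0], [6.0, 4.0], [4.0, 3.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand) ** 2
               ).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (msc - mse) / n)
        assert icc_2way_mean_rating(x) == pytest.approx(expected, abs=1e-12)

    def test_per_cpg_series(self):
        rng = np.random.default_rng(10)
        base = rng.random((30, 3))
        first = pd.DataFrame(base, columns=list("xyz"))
        second = pd.DataFrame(base + rng.normal(0, 0.01, base.shape),
                              columns=list("xyz"))
        icc = icc_absolute_agreement(first, second)
        assert list(icc.index) == list("xyz")
        assert (icc > 0.9).all()

    def test_incomplete_pairs_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError, match="incomplete"):
            icc_2way_mean_rating(x)
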