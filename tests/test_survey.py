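import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from proxnet import codebook
from proxnet.survey import (CorrelationTable, composite_score, correlate,
                            cronbach_alpha, describe, mcdonald_omega,
                            pca_first_loadings, retain_items, score_scales,
                            significance_flag)


def equicorrelated_items(n, k, rho, rng):
    """Rows from a k-variate normal with equal correlation rho."""
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    return pd.DataFrame(rng.multivariate_normal(np.zeros(k), cov, size=n),
                        columns=[f"item{i}" for i in range(k)])


class TestPcaFirstLoadings:
    def test_perfectly_correlated_items_equal(self, rng):
        x = rng.normal(size=200)
        items = pd.DataFrame({"a": x, "b": 2 * x + 3})
        lo = pca_first_loadings(items)
        assert lo["a"] == pytest.approx(lo["b"], abs=1e-10)
        assert lo["a"] == pytest.approx(1.0, abs=1e-10)

    def test_uncorrelated_item_smallest_loading(self, rng):
        n = 5000
        f = rng.normal(size=n)
        items = pd.DataFrame({
            "a": f + 0.3 * rng.normal(size=n),
            "b": f + 0.3 * rng.normal(size=n),
            "c": rng.normal(size=n),
        })
        lo = pca_first_loadings(items)
        # oracle: dense eigendecomposition of the correlation matrix
        R = np.corrcoef(items.to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(R)
        ref = v[:, -1] * math.sqrt(w[-1])
        if ref.sum() < 0:
            ref = -ref
        np.testing.assert_allclose(lo.to_numpy(), ref, atol=1e-10)
        assert abs(lo["c"]) == min(abs(lo))

    def test_sign_reversed_item(self, rng):
        x = rng.normal(size=300)
        items = pd.DataFrame({"a": x, "b": -x + rng.normal(size=300) * 1e-6})
        lo = pca_first_loadings(items)
        assert abs(lo["a"]) == pytest.approx(abs(lo["b"]), abs=1e-6)
        assert lo["a"] * lo["b"] < 0

    def test_zero_variance_item_named(self):
        items = pd.DataFrame({"a": [1, 2, 3, 4], "flat": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="flat"):
            pca_first_loadings(items)

    def test_too_few_respondents(self):
        items = pd.DataFrame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            pca_first_loadings(items)


class TestRetainItems:
    def test_threshold_excludes_low_loading(self):
        lo = pd.Series({"good": 0.85, "bad": 0.39})
        assert retain_items(lo, threshold=0.45) == ["good"]

    def test_zero_threshold_keeps_all_nonnegative(self):
        lo = pd.Series({"a": 0.85, "b": 0.39, "c": 0.01})
        assert retain_items(lo, threshold=0.0) == ["a", "b", "c"]

    def test_all_below_threshold_errors(self):
        lo = pd.Series({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError):
            retain_items(lo, threshold=0.45)

    def test_manual_exclusion(self):
        lo = pd.Series({"a": 0.85, "b": 0.56})
        assert retain_items(lo, threshold=0.45, manual_exclusions=["b"]) == ["a"]


class TestCronbachAlpha:
    def test_spearman_brown_two_items(self, rng):
        # alpha for k=2 parallel items with rho=0.5 is 2*0.5/1.5 = 0.6667
        items = equicorrelated_items(200_000, 2, 0.5, rng)
        assert cronbach_alpha(items) == pytest.approx(2 * 0.5 / 1.5, abs=0.01)

    def test_identical_items_alpha_one(self, rng):
        x = rng.normal(size=50)
        items = pd.DataFrame({"a": x, "b": x, "c": x})
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_hand_table_against_brute_force(self):
        items = pd.DataFrame({"a": [1, 2, 3, 4, 5],
                              "b": [2, 2, 3, 5, 4],
                              "c": [1, 3, 3, 4, 4]})
        data = items.to_numpy(float)
        k = 3

        def var(x):  # n-1 denominator, by hand
            m = sum(x) / len(x)
            return sum((v - m) ** 2 for v in x) / (len(x) - 1)

        item_vars = sum(var(data[:, j]) for j in range(k))
        total_var = var(data.sum(axis=1))
        expected = k / (k - 1) * (1 - item_vars / total_var)
        assert cronbach_alpha(items) == pytest.approx(expected, rel=1e-12)

    def test_rescaling_invariance(self, rng):
        items = equicorrelated_items(500, 4, 0.4, rng)
        scaled = items * [2.0, 5.0, 1.5, 10.0] + [1, 2, 3, 4]
        assert cronbach_alpha(items) != pytest.approx(cronbach_alpha(scaled))  # raw alpha moves
        # but standardizing each item restores it
        std = (items - items.mean()) / items.std()
        std_s = (scaled - scaled.mean()) / scaled.std()
        assert cronbach_alpha(std) == pytest.approx(cronbach_alpha(std_s), rel=1e-10)

    def test_too_few_rows(self):
        items = pd.DataFrame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            cronbach_alpha(items)


class TestMcdonaldOmega:
    def test_closed_form_two_items(self, rng):
        # tau-equivalent closed form: omega = 4*0.5 / (4*0.5 + 2*0.5)
        items = equicorrelated_items(200_000, 2, 0.5, rng)
        assert mcdonald_omega(items) == pytest.approx(2 / 3, abs=0.01)

    @pytest.mark.parametrize("k,rho", [(3, 0.4), (5, 0.3)])
    def test_closed_form_equicorrelated(self, k, rho, rng):
        items = equicorrelated_items(100_000, k, rho, rng)
        expected = k * k * rho / (k * k * rho + k * (1 - rho))
        assert mcdonald_omega(items) == pytest.approx(expected, abs=0.015)

    def test_recovers_generating_omega(self, rng):
        lam = np.array([0.8, 0.7, 0.6, 0.75, 0.65, 0.7])
        n = 500
        f = rng.normal(size=n)
        data = np.column_stack([
            l * f + math.sqrt(1 - l * l) * rng.normal(size=n) for l in lam
        ])
        items = pd.DataFrame(data, columns=[f"i{j}" for j in range(6)])
        s = lam.sum()
        true_omega = s * s / (s * s + (1 - lam ** 2).sum())
        assert mcdonald_omega(items) == pytest.approx(true_omega, abs=0.05)

    def test_heywood_case_raises(self, rng):
        # just-identified 3-item solution implies lambda_a = sqrt(1.5) > 1
        cov = np.array([[1.0, 0.9, 0.5],
                        [0.9, 1.0, 0.3],
                        [0.5, 0.3, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=20_000)
        items = pd.DataFrame(data, columns=list("abc"))
        with pytest.raises(ValueError, match="Heywood"):
            mcdonald_omega(items)


class TestAlphaOmegaInequality:
    def test_alpha_at_most_omega_congeneric_trend(self, rng):
        # classical inequality under unequal loadings, asserted as a trend
        lam = np.array([0.9, 0.8, 0.5, 0.3])
        wins = 0
        n_sims = 40
        for _ in range(n_sims):
            n = 1000
            f = rng.normal(size=n)
            data = np.column_stack([
                l * f + math.sqrt(1 - l * l) * rng.normal(size=n) for l in lam
            ])
            items = pd.DataFrame(data, columns=list("abcd"))
            std = (items - items.mean()) / items.std()
            if cronbach_alpha(std) <= mcdonald_omega(items) + 1e-6:
                wins += 1
        assert wins >= 0.9 * n_sims


class TestCompositeScore:
    def test_all_fives(self):
        items = pd.DataFrame({"a": [5, 5], "b": [5, 5]})
        out = composite_score(items, ["a", "b"])
        assert (out == 5.0).all()

    def test_simple_mean(self):
        items = pd.DataFrame({"a": [3], "b": [4], "c": [5]})
        assert composite_score(items, ["a", "b", "c"]).iloc[0] == pytest.approx(4.0)

    def test_three_of_seven_missing(self):
        row = {f"i{j}": [float(j % 5 + 1)] for j in range(7)}
        items = pd.DataFrame(row)
        items.loc[0, ["i0", "i1", "i2", "i3"]] = np.nan  # 3 of 7 answered
        out = composite_score(items, list(items.columns))
        assert np.isnan(out.iloc[0])

    def test_four_of_seven_present(self):
        row = {f"i{j}": [2.0] for j in range(7)}
        items = pd.DataFrame(row)
        items.loc[0, ["i0", "i1", "i2"]] = np.nan  # 4 of 7 answered
        out = composite_score(items, list(items.columns))
        assert out.iloc[0] == pytest.approx(2.0)


class TestDescribe:
    def test_basic(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        row = describe(df).loc["x"]
        assert row["N"] == 3
        assert row["mean"] == pytest.approx(2.0)
        assert row["median"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_single_value_sd_missing(self):
        df = pd.DataFrame({"x": [4.0]})
        assert np.isnan(describe(df).loc["x", "sd"])

    def test_random_vector_brute_force(self, rng):
        x = rng.normal(size=37)
        row = describe(pd.DataFrame({"x": x})).loc["x"]
        m = sum(x) / len(x)
        sd = math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))
        assert row["mean"] == pytest.approx(m, rel=1e-12)
        assert row["sd"] == pytest.approx(sd, rel=1e-12)


class TestCorrelate:
    def test_identical_vectors(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        ct = correlate(df)
        assert ct.r.loc["x", "y"] == pytest.approx(1.0)

    def test_exact_negatives(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        assert correlate(df).r.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_sample_against_brute_force(self):
        x = [2.0, 4.0, 5.0, 7.0, 8.0, 9.0]
        y = [1.0, 3.0, 2.0, 6.0, 8.0, 7.0]
        df = pd.DataFrame({"x": x, "y": y})
        ct = correlate(df)
        n = 6
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        r = sxy / math.sqrt(sxx * syy)
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
        assert ct.r.loc["x", "y"] == pytest.approx(r, rel=1e-12)
        assert ct.p.loc["x", "y"] == pytest.approx(p, rel=1e-10)
        assert ct.n.loc["x", "y"] == 6

    def test_symmetry_and_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        ct = correlate(df)
        assert np.allclose(ct.r.to_numpy(), ct.r.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(ct.r.to_numpy()), 1.0)

    def test_pairwise_deletion(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan],
                           "y": [2.0, 1, 4, 3, 5],
                           "z": [1.0, np.nan, 2, 5, 4]})
        ct = correlate(df)
        assert ct.n.loc["x", "y"] == 4
        assert ct.n.loc["x", "z"] == 3
        assert ct.n.loc["y", "z"] == 4

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        assert np.isnan(correlate(df).r.loc["x", "y"])

    def test_flags(self):
        assert significance_flag(0.005) == "**"
        assert significance_flag(0.03) == "*"
        assert significance_flag(0.08) == "†"
        assert significance_flag(0.5) == ""


class TestScoreScales:
    def synthetic_survey(self, rng, n=300):
        data = {}
        f1 = rng.normal(size=n)
        for it in codebook.SCALES["pro_community"]["items"]:
            noise = 1.2 if it in ("pc_participate", "pc_no_refuse") else 0.6
            data[it] = np.clip(np.rint(3 + f1 + noise * rng.normal(size=n)), 1, 5)
        f2 = rng.normal(size=n)
        for it in codebook.SCALES["openness"]["items"]:
            sign = -0.1 if it == "op_problems" else 1.0
            data[it] = np.clip(np.rint(3 + sign * f2 + 0.8 * rng.normal(size=n)), 1, 5)
        data["happiness"] = np.clip(np.rint(7 + rng.normal(size=n)), 0, 10)
        data["subjective_health"] = np.clip(np.rint(7 + rng.normal(size=n)), 0, 10)
        return pd.DataFrame(data)

    def test_published_retained_sets_score_without_error(self, rng):
        survey = self.synthetic_survey(rng)
        results = score_scales(survey, use_published_retained=True)
        assert results["pro_community"].retained == \
            codebook.SCALES["pro_community"]["retained"]
        assert results["openness"].retained == \
            codebook.SCALES["openness"]["retained"]
        for res in results.values():
            assert 0 < res.alpha <= 1
            assert 0 < res.omega <= 1
            assert res.composite.notna().all()

    def test_threshold_retention_drops_weak_items(self, rng):
        survey = self.synthetic_survey(rng, n=2000)
        results = score_scales(survey, use_published_retained=False)
        assert "op_problems" not in results["openness"].retained
        assert "pc_participate" not in results["pro_community"].retained

    def test_composite_is_mean_of_retained(self, rng):
        survey = self.synthetic_survey(rng, n=50)
        results = score_scales(survey, use_published_retained=True)
        res = results["pro_community"]
        expected = survey[res.retained].mean(axis=1)
        pd.testing.assert_series_equal(res.composite, expected)
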