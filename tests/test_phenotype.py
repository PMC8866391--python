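"""Adjusted-means model, backward elimination, closed-form qPCR helpers."""

import math

import numpy as np
import pandas as pd
import pytest

from allelemine.phenotype import (
    FrostScoreModel,
    PhenotypeError,
    backward_elimination,
    cn_latitude_summary,
    ddct_fold_change,
    genotype_adjusted_means,
    pearson_correlation,
    qpcr_efficiency,
)


def scores_frame(rows):
    return pd.DataFrame(rows, columns=["genotype_id", "box_id", "score"])


class TestAdjustedMeans:
    def test_balanced_design_equals_arithmetic_means(self, rng):
        rows = []
        genos = [f"g{i}" for i in range(6)]
        boxes = [f"b{j}" for j in range(4)]
        for g in genos:
            for b in boxes:
                rows.append((g, b, float(rng.integers(0, 11)) / 2))
        df = scores_frame(rows)
        res = genotype_adjusted_means(df)
        arithmetic = df.groupby("genotype_id")["score"].mean()
        for g in genos:
            assert res.adjusted_means[g] == pytest.approx(arithmetic[g], abs=1e-12)

    def test_zero_box_effects_recover_true_genotype_means(self, rng):
        true = {"g0": 1.0, "g1": 2.5, "g2": 4.0}
        sd, reps = 0.5, 30
        rows = []
        for g, mu in true.items():
            for r in range(reps):
                b = f"b{r % 3}"
                rows.append((g, b, mu + rng.normal(0, sd)))
        res = genotype_adjusted_means(scores_frame(rows))
        se = sd / math.sqrt(reps)
        for g, mu in true.items():
            assert abs(res.adjusted_means[g] - mu) < 3 * se

    def test_unbalanced_toy_matches_normal_equations_oracle(self):
        """3 genotypes × 2 boxes with one empty cell, solved by hand-built
        normal equations."""
        rows = [
            ("g0", "b0", 2.0), ("g0", "b1", 3.0),
            ("g1", "b0", 1.0), ("g1", "b1", 2.5),
            ("g2", "b0", 4.0),  # (g2, b1) missing
        ]
        res = genotype_adjusted_means(scores_frame(rows))
        # oracle: X = [1, I(g1), I(g2), I(b1)], beta = (X'X)^-1 X'y
        X = np.array(
            [
                [1, 0, 0, 0],
                [1, 0, 0, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 1],
                [1, 0, 1, 0],
            ],
            dtype=float,
        )
        y = np.array([2.0, 3.0, 1.0, 2.5, 4.0])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        mean_box = beta[3] / 2  # boxes contribute (0 + beta_b1)/2
        expected = {
            "g0": beta[0] + mean_box,
            "g1": beta[0] + beta[1] + mean_box,
            "g2": beta[0] + beta[2] + mean_box,
        }
        for g, v in expected.items():
            assert res.adjusted_means[g] == pytest.approx(v, abs=1e-10)

    def test_matches_statsmodels_on_sparse_design(self, rng):
        import statsmodels.formula.api as smf

        rows = []
        for i in range(8):
            for j in range(5):
                if rng.random() < 0.6:
                    rows.append((f"g{i}", f"b{j}", float(rng.normal(2.5, 1.0))))
        df = scores_frame(rows)
        res = genotype_adjusted_means(df)
        fit = smf.ols("score ~ C(genotype_id) + C(box_id)", data=df).fit()
        boxes = sorted(df["box_id"].unique())
        for g in sorted(df["genotype_id"].unique()):
            grid = pd.DataFrame({"genotype_id": g, "box_id": boxes})
            expected = fit.predict(grid).mean()
            assert res.adjusted_means[g] == pytest.approx(expected, abs=1e-8)

    def test_disconnected_design_rejected(self):
        rows = [
            ("g0", "b0", 2.0), ("g1", "b0", 3.0),
            ("g2", "b1", 1.0), ("g3", "b1", 2.0),
        ]
        with pytest.raises(PhenotypeError, match="disconnected"):
            genotype_adjusted_means(scores_frame(rows))


class TestBackwardElimination:
    def test_perfect_predictor_retained_with_recovered_slope(self, rng):
        n = 40
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({"y": 2.0 + 3.0 * x, "x": x, "noise": rng.normal(0, 1, n)})
        res = backward_elimination(df, "y", ["x", "noise"])
        assert "x" in res.retained
        assert res.coefficients["x"][0] == pytest.approx(3.0, abs=1e-8)
        assert res.p_values["x"] < 1e-10

    def test_pure_noise_type_one_rate_near_alpha(self, rng):
        """Each noise term should survive elimination about 5% of the time."""
        retained = 0
        n_runs, n, n_terms = 400, 45, 3
        for _ in range(n_runs):
            df = pd.DataFrame(
                {"y": rng.normal(0, 1, n)}
                | {f"x{k}": rng.normal(0, 1, n) for k in range(n_terms)}
            )
            res = backward_elimination(df, "y", [f"x{k}" for k in range(n_terms)])
            retained += len(res.retained)
        rate = retained / (n_runs * n_terms)
        assert 0.02 <= rate <= 0.09

    def test_categorical_factor_removed_as_whole_term(self, rng):
        n = 45
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, n),
                "hap": rng.choice(["h1", "h2", "h3"], n),
                "cn": rng.normal(1, 0.5, n),
            }
        )
        res = backward_elimination(df, "y", ["hap", "cn"], alpha=1e-9)
        assert res.retained == ()
        removed = [s.removed for s in res.trace]
        assert sorted(removed) == ["cn", "hap"]

    def test_retained_set_stable_under_predictor_reordering(self, rng):
        n = 60
        hap = rng.choice(["h1", "h2", "h3"], n)
        y = (hap == "h3") * 1.0 + rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"y": y, "hap": hap, "cn": rng.normal(1, 0.5, n), "z": rng.normal(0, 1, n)}
        )
        a = backward_elimination(df, "y", ["hap", "cn", "z"])
        b = backward_elimination(df, "y", ["z", "cn", "hap"])
        assert a.retained == b.retained
        assert [s.removed for s in a.trace] == [s.removed for s in b.trace]

    def test_partial_f_pvalues_match_statsmodels_anova(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        n = 50
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, n),
                "hap": rng.choice(["h1", "h2", "h3"], n),
                "cn": rng.normal(1, 0.5, n),
            }
        )
        res = backward_elimination(df, "y", ["hap", "cn"], alpha=1.1)
        # alpha > 1 keeps everything; compare the full-model partial F tests
        fit = smf.ols("y ~ C(hap) + cn", data=df).fit()
        table = anova_lm(fit, typ=2)
        assert res.p_values["hap"] == pytest.approx(table.loc["C(hap)", "PR(>F)"], rel=1e-6)
        assert res.p_values["cn"] == pytest.approx(table.loc["cn", "PR(>F)"], rel=1e-6)

    def test_too_few_observations_rejected(self, rng):
        df = pd.DataFrame({"y": rng.normal(0, 1, 3), "x": rng.normal(0, 1, 3),
                           "w": rng.normal(0, 1, 3), "z": rng.normal(0, 1, 3)})
        with pytest.raises(PhenotypeError):
            backward_elimination(df, "y", ["x", "w", "z"])


class TestClosedFormHelpers:
    def test_perfect_doubling_slope_gives_unit_efficiency(self):
        assert qpcr_efficiency(-1.0 / math.log10(2.0)) == pytest.approx(1.0, abs=1e-9)

    def test_slope_minus_one(self):
        assert qpcr_efficiency(-1.0) == pytest.approx(9.0)

    def test_slope_minus_ten(self):
        assert qpcr_efficiency(-10.0) == pytest.approx(10**0.1 - 1, abs=1e-9)

    def test_positive_slope_rejected(self):
        with pytest.raises(PhenotypeError, match="invalid standard curve"):
            qpcr_efficiency(3.3)

    def test_fold_change_identity(self):
        assert ddct_fold_change(20, 18, 22, 20) == 1.0

    def test_fold_change_doubles_per_negative_ddct_unit(self):
        assert ddct_fold_change(19, 18, 22, 20) == 2.0

    def test_fold_change_calculator_value(self):
        # ddct = 3.3219 -> 2^-3.3219 ~ 0.1
        assert ddct_fold_change(23.3219, 20, 22, 22) == pytest.approx(0.1, abs=1e-4)

    def test_pearson_perfect_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v for v in x])[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v + 7 for v in x])[0] == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        r, _ = pearson_correlation(x, y)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(PhenotypeError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestLatitudeSummary:
    def _tables(self):
        cn = pd.DataFrame(
            {
                "sample_id": ["a", "a", "b", "b", "c", "c"],
                "gene_id": ["HvCBF2a", "HvCBF4b"] * 3,
                "cn_ratio": [1.0, 1.2, 3.0, 2.8, 2.0, 2.0],
            }
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "latitude": [42.0, 43.0, np.nan],
            }
        )
        return cn, meta

    def test_single_band_holds_all_located_samples(self):
        cn, meta = self._tables()
        bands, unlocated = cn_latitude_summary(cn, meta, band_width_deg=5)
        assert len(bands) == 1
        assert bands.iloc[0]["n"] == 2
        assert bands.iloc[0]["band"] == 40.0

    def test_unlocated_sample_reported_separately(self):
        cn, meta = self._tables()
        _, unlocated = cn_latitude_summary(cn, meta)
        assert list(unlocated["sample_id"]) == ["c"]
        assert unlocated.iloc[0]["cn_sum"] == pytest.approx(4.0)

    def test_band_medians_equal_brute_force_group_by(self, rng):
        n = 50
        samples = [f"s{i}" for i in range(n)]
        lat = rng.uniform(20, 60, n)
        sums = rng.uniform(1, 10, n)
        cn = pd.DataFrame(
            {
                "sample_id": samples * 2,
                "gene_id": ["HvCBF2a"] * n + ["HvCBF4b"] * n,
                "cn_ratio": np.concatenate([sums / 2, sums / 2]),
            }
        )
        meta = pd.DataFrame({"sample_id": samples, "latitude": lat})
        bands, _ = cn_latitude_summary(cn, meta, band_width_deg=10)
        for row in bands.itertuples():
            members = [
                s for s, l in zip(sums, lat) if row.band <= l < row.band + 10
            ]
            assert row.n == len(members)
            assert row.median == pytest.approx(float(np.median(members)))
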