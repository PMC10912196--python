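"""Correlation series, regressions, repeatability, bins and confusion."""

import numpy as np
import pandas as pd
import pytest

from phenoyield.evaluation import (
    BIN_LABELS,
    bin_genotypes,
    bin_sizes,
    confusion_matrix,
    perflight_correlations,
    regress_estimated_vs_measured,
    repeatability,
)


def _trial_tables(trait_fn, n=12):
    yields = pd.DataFrame(
        {"plot_id": [f"p{i}" for i in range(n)], "yield": np.linspace(2, 6, n)}
    )
    traits = pd.DataFrame(
        {
            "plot_id": yields["plot_id"],
            "year": "2021",
            "dap": 50,
            "CC": trait_fn(yields["yield"].to_numpy()),
        }
    )
    return traits, yields


class TestPerflightCorrelations:
    def test_perfect_linear_trait(self):
        traits, yields = _trial_tables(lambda y: 2 * y + 1)
        out = perflight_correlations(traits, yields, trait_cols=("CC",))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negative_trait(self):
        traits, yields = _trial_tables(lambda y: -y)
        out = perflight_correlations(traits, yields, trait_cols=("CC",))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        traits, yields = _trial_tables(lambda y: rng.normal(size=len(y)))
        out = perflight_correlations(traits, yields, trait_cols=("CC",))
        x = traits["CC"].to_numpy()
        y = yields["yield"].to_numpy()
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["r"].iloc[0] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_trait_reported_missing(self):
        traits, yields = _trial_tables(lambda y: np.full(len(y), 0.5))
        out = perflight_correlations(traits, yields, trait_cols=("CC",))
        assert np.isnan(out["r"].iloc[0])


class TestRegression:
    def test_identity_prediction(self):
        preds = pd.DataFrame(
            {"plot_id": list("abcde"), "measured": [1, 2, 3, 4, 5.0], "estimated": [1, 2, 3, 4, 5.0]}
        )
        out = regress_estimated_vs_measured(preds)
        assert out.loc[0, ["slope", "intercept", "r2"]].to_numpy() == pytest.approx([1, 0, 1])

    def test_shuffled_prediction_near_zero(self, rng):
        measured = rng.normal(4, 1, 200)
        preds = pd.DataFrame(
            {
                "plot_id": np.arange(200),
                "measured": measured,
                "estimated": rng.permutation(measured),
            }
        )
        assert regress_estimated_vs_measured(preds).loc[0, "r2"] < 0.05

    def test_two_distant_clusters_inflate_pooled_r2(self, rng):
        # within each year the fit is mediocre; pooling two separated
        # clusters anchors the line and inflates R2
        n = 60
        rows = []
        for year, mu in [("2021", 2.0), ("2022", 8.0)]:
            measured = rng.normal(mu, 0.3, n)
            estimated = mu + rng.normal(0, 0.3, n) + 0.3 * (measured - mu)
            rows.append(
                pd.DataFrame(
                    {"plot_id": [f"{year}-{i}" for i in range(n)], "year": year,
                     "measured": measured, "estimated": estimated}
                )
            )
        preds = pd.concat(rows, ignore_index=True)
        pooled = regress_estimated_vs_measured(preds, "overall").loc[0, "r2"]
        per_year = regress_estimated_vs_measured(preds, "per-year")["r2"].mean()
        assert pooled > per_year

    def test_constant_measured_rejected(self):
        preds = pd.DataFrame(
            {"plot_id": list("abc"), "measured": [1.0, 1.0, 1.0], "estimated": [1, 2, 3.0]}
        )
        with pytest.raises(ValueError, match="constant"):
            regress_estimated_vs_measured(preds)


class TestRepeatability:
    def test_zero_within_genotype_variance(self):
        est = repeatability([1, 1, 2, 2, 5, 5.0], ["a", "a", "b", "b", "c", "c"])
        assert est.repeatability == pytest.approx(1.0)

    def test_equal_variance_components_give_three_quarters(self, rng):
        # sigma2_g = sigma2_e = 1 with 3 reps -> R = 1/(1 + 1/3) = 0.75
        genos = np.repeat([f"g{i}" for i in range(73)], 3)
        vals = np.repeat(rng.normal(0, 1, 73), 3) + rng.normal(0, 1, len(genos))
        est = repeatability(vals, genos)
        assert est.repeatability == pytest.approx(0.75, abs=0.1)
        assert est.r_reps == 3

    def test_permuted_labels_destroy_repeatability(self, rng):
        genos = np.repeat([f"g{i}" for i in range(73)], 3)
        vals = np.repeat(rng.normal(0, 2, 73), 3) + rng.normal(0, 0.1, len(genos))
        strong = repeatability(vals, genos)
        weak = repeatability(vals, rng.permutation(genos))
        assert strong.repeatability > 0.95
        assert weak.repeatability < 0.15

    def test_affine_invariance(self, rng):
        genos = np.repeat([f"g{i}" for i in range(20)], 3)
        vals = np.repeat(rng.normal(0, 1, 20), 3) + rng.normal(0, 0.5, len(genos))
        a = repeatability(vals, genos)
        b = repeatability(4.2 * vals - 17.0, genos)
        assert a.repeatability == pytest.approx(b.repeatability, abs=1e-12)

    def test_negative_genotype_variance_truncated(self, rng):
        vals = rng.normal(0, 1, 40)  # labels carry no signal
        est = repeatability(vals, np.repeat([f"g{i}" for i in range(20)], 2))
        assert est.sigma2_g >= 0
        assert 0 <= est.repeatability <= 1

    def test_single_plot_genotypes_rejected(self):
        with pytest.raises(ValueError):
            repeatability([1.0, 2.0, 3.0], ["a", "b", "c"])


class TestBins:
    def test_hundred_genotypes_split_10_15_25_50(self):
        assert bin_sizes(100) == {"Excellent": 10, "Good": 15, "Mediocre": 25, "Poor": 50}

    def test_twenty_genotypes_split_2_3_5_10(self):
        assert bin_sizes(20) == {"Excellent": 2, "Good": 3, "Mediocre": 5, "Poor": 10}

    @pytest.mark.parametrize("n", [4, 5, 7, 11, 73, 100, 219, 500])
    def test_bins_partition_any_count(self, n):
        sizes = bin_sizes(n)
        assert sum(sizes.values()) == n
        assert all(v >= 0 for v in sizes.values())

    def test_assignment_follows_rank(self, rng):
        means = pd.Series(rng.normal(4, 1, 100), index=[f"g{i}" for i in range(100)])
        bins = bin_genotypes(means)
        top10 = set(means.sort_values(ascending=False).index[:10])
        assert set(bins[bins == "Excellent"].index) == top10
        assert bins.value_counts().to_dict() == bin_sizes(100)

    def test_ties_break_by_stable_genotype_order(self):
        means = pd.Series([1.0, 1.0, 1.0, 1.0, 0.5], index=list("abcde"))
        bins = bin_genotypes(means)
        assert bins["a"] == "Excellent"  # n=5: Excellent size 1, first tied id wins

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            bin_sizes(3)


class TestConfusionMatrix:
    def _bins(self, rng, n=100):
        means = pd.Series(rng.normal(4, 1, n), index=[f"g{i}" for i in range(n)])
        return bin_genotypes(means), means

    def test_perfect_agreement_is_diagonal(self, rng):
        bins, _ = self._bins(rng)
        cm = confusion_matrix(bins, bins.copy())
        counts = cm.counts.to_numpy()
        assert np.all(counts == np.diag(np.diag(counts)))
        assert dict(zip(BIN_LABELS, np.diag(counts))) == bin_sizes(100)
        assert cm.catastrophic == 0

    def test_reversed_ranking_is_catastrophic(self, rng):
        bins, means = self._bins(rng)
        reversed_bins = bin_genotypes(-means)
        cm = confusion_matrix(bins, reversed_bins)
        assert cm.counts.loc["Excellent", "Poor"] == 10
        assert cm.catastrophic >= 10

    def test_single_poor_predicted_excellent(self, rng):
        bins, means = self._bins(rng)
        est = means.copy()
        worst = means.idxmin()
        est[worst] = means.max() + 1  # push one Poor genotype to the top
        cm = confusion_matrix(bins, bin_genotypes(est))
        assert cm.counts.loc["Poor", "Excellent"] == 1

    def test_margins_match_bin_sizes(self, rng):
        bins, means = self._bins(rng, n=73)
        est = bin_genotypes(means + rng.normal(0, 0.5, 73))
        cm = confusion_matrix(bins, est)
        assert cm.total == 73
        assert cm.counts.sum(axis=1).to_dict() == {k: v for k, v in bin_sizes(73).items()}
        assert cm.counts.sum(axis=0).to_dict() == {k: v for k, v in bin_sizes(73).items()}

    def test_mismatched_genotype_sets_rejected(self, rng):
        bins, _ = self._bins(rng, n=10)
        with pytest.raises(ValueError, match="different genotype"):
            confusion_matrix(bins, bins.iloc[:-1])
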