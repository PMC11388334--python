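"""ALE estimator: oracle equivalence, closed forms and invariances."""

import numpy as np
import pandas as pd
import pytest

from gwyield.ale import ALECurve, bootstrap_ale, compute_ale


def naive_ale(predict, data, feature, k_bins):
    """Independent brute-force first-order ALE (plain loops, no shared code).

    Written directly from the estimator's definition: quantile bins, per-row
    prediction differences between bin edges, accumulated per-bin means,
    centered by the count-weighted average of bin-midpoint values.
    """
    x = data[feature].to_numpy(dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, k_bins + 1)))
    n_bins = len(edges) - 1
    assignments = []
    for xi in x:
        b = n_bins - 1
        for j in range(n_bins):
            if xi <= edges[j + 1]:
                b = j
                break
        assignments.append(b)
    means, counts = [], []
    for b in range(n_bins):
        rows = [i for i, a in enumerate(assignments) if a == b]
        diffs = []
        for i in rows:
            hi = data.iloc[[i]].copy()
            lo = data.iloc[[i]].copy()
            hi[feature] = edges[b + 1]
            lo[feature] = edges[b]
            diffs.append(float(predict(hi)[0]) - float(predict(lo)[0]))
        means.append(sum(diffs) / len(diffs))
        counts.append(len(rows))
    acc = [0.0]
    for m in means:
        acc.append(acc[-1] + m)
    acc = np.array(acc)
    counts = np.array(counts)
    center = sum(counts[j] * (acc[j] + acc[j + 1]) / 2 for j in range(n_bins)) / counts.sum()
    return edges, acc - center, counts


def _random_table(rng, n, corr=0.5):
    z = rng.standard_normal((n, 3))
    x1 = z[:, 0]
    x2 = corr * z[:, 0] + np.sqrt(1 - corr**2) * z[:, 1]
    return pd.DataFrame({"x1": x1, "x2": x2, "x3": z[:, 2]})


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_naive_implementation(self, trial):
        """compute_ale equals the brute-force estimator to 1e-10 on random tables."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(20, 200))
        k = int(rng.integers(2, 12))
        data = _random_table(rng, n, corr=float(rng.uniform(-0.8, 0.8)))
        coefs = rng.normal(0, 1, 6)

        def predict(df):
            return (
                coefs[0] * df["x1"].to_numpy() ** 2
                + coefs[1] * df["x1"].to_numpy()
                + coefs[2] * np.sin(df["x2"].to_numpy())
                + coefs[3] * df["x2"].to_numpy() * df["x1"].to_numpy()
                + coefs[4] * df["x3"].to_numpy()
                + coefs[5]
            )

        curve = compute_ale(predict, data, "x1", k)
        edges, effect, counts = naive_ale(predict, data, "x1", k)
        np.testing.assert_allclose(curve.edges, edges, atol=1e-12)
        np.testing.assert_allclose(curve.effect, effect, atol=1e-10)
        np.testing.assert_array_equal(curve.counts, counts)


class TestClosedForms:
    def test_ignored_feature_gives_zero_effect(self, rng):
        data = _random_table(rng, 120)
        curve = compute_ale(lambda df: 3.0 + 2.0 * df["x2"].to_numpy(), data, "x1", 8)
        np.testing.assert_allclose(curve.effect, 0.0, atol=1e-12)

    @pytest.mark.parametrize("corr", [0.0, 0.9])
    def test_linear_predict_recovers_slope(self, rng, corr):
        """ALE of a + b*x is the line b*(edge - weighted mean edge), any correlation."""
        data = _random_table(rng, 300, corr=corr)
        b = -1.7

        def predict(df):
            return 4.0 + b * df["x1"].to_numpy() + 0.5 * df["x2"].to_numpy()

        curve = compute_ale(predict, data, "x1", 10)
        slopes = np.diff(curve.effect) / np.diff(curve.edges)
        np.testing.assert_allclose(slopes, b, rtol=1e-10)
        # centered: count-weighted mean of bin-midpoint effects is 0
        mids = (curve.effect[:-1] + curve.effect[1:]) / 2
        assert abs(np.sum(mids * curve.counts) / curve.n) < 1e-8

    def test_constant_shift_invariance(self, rng):
        data = _random_table(rng, 150)

        def predict(df):
            return np.sin(df["x1"].to_numpy()) + df["x2"].to_numpy() ** 2

        c1 = compute_ale(predict, data, "x1", 9)
        c2 = compute_ale(lambda df: predict(df) + 123.4, data, "x1", 9)
        np.testing.assert_allclose(c1.effect, c2.effect, atol=1e-10)

    def test_additive_recovery_under_correlation(self, rng):
        """Each feature's ALE recovers its own additive component up to a constant."""
        data = _random_table(rng, 4000, corr=0.9)

        def f1(x):
            return x**2

        def f2(x):
            return 2.0 * x

        def predict(df):
            return f1(df["x1"].to_numpy()) + f2(df["x2"].to_numpy())

        for feat, f in (("x1", f1), ("x2", f2)):
            curve = compute_ale(predict, data, feat, 20)
            truth = f(curve.edges)
            resid = curve.effect - (truth - truth.mean())
            # flat residual up to the centering constant
            assert np.ptp(resid) < 0.05 * max(np.ptp(truth), 1.0)


class TestValidation:
    def test_constant_feature_rejected(self):
        data = pd.DataFrame({"x1": np.ones(50), "x2": np.arange(50.0)})
        with pytest.raises(ValueError):
            compute_ale(lambda df: df["x2"].to_numpy(), data, "x1", 5)

    def test_missing_feature(self, rng):
        data = _random_table(rng, 50)
        with pytest.raises(KeyError):
            compute_ale(lambda df: df["x1"].to_numpy(), data, "nope", 5)

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            ALECurve(np.array([0.0, 1.0, 1.0]), np.zeros(3), np.array([5, 5]), "x", 0.0)


class TestBootstrap:
    @staticmethod
    def _factory(data):
        x = data[["x1"]].to_numpy()
        y = data["y"].to_numpy()
        coef = np.linalg.lstsq(np.c_[np.ones(len(x)), x], y, rcond=None)[0]

        def predict(df):
            return coef[0] + coef[1] * df["x1"].to_numpy()

        return predict

    def test_single_cluster_band_collapses(self, rng):
        """Resampling one cluster returns the full table: band == point curve."""
        data = pd.DataFrame(
            {"x1": rng.normal(0, 1, 60), "cell_id": 0}
        )
        data["y"] = 2.0 * data["x1"] + rng.normal(0, 0.1, 60)
        curve = bootstrap_ale(self._factory, data, "x1", k_bins=5, n_boot=3, seed=0)
        np.testing.assert_allclose(curve.band_low, curve.effect, atol=1e-12)
        np.testing.assert_allclose(curve.band_high, curve.effect, atol=1e-12)

    def test_band_orders_and_contains_point(self, rng):
        data = pd.DataFrame(
            {"x1": rng.normal(0, 1, 200), "cell_id": np.repeat(np.arange(20), 10)}
        )
        data["y"] = data["x1"] ** 2 + rng.normal(0, 0.5, 200)
        curve = bootstrap_ale(self._factory, data, "x1", k_bins=6, n_boot=25, seed=1)
        assert np.all(curve.band_low <= curve.effect + 1e-12)
        assert np.all(curve.effect <= curve.band_high + 1e-12)
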