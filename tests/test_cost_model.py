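import math

import numpy as np
import pytest

from promptner.cost_model import (
    CostPoint,
    LoessModel,
    bootstrap_bands,
    count_tokens,
    fit_asymptotic_exponential,
    loess_predict,
    per_query_cost,
)
from promptner.evaluation import DocCounts
from promptner.corpus import EntityType


class TestTokensAndCost:
    def test_whitespace_tokenizer(self):
        assert count_tokens("") == 0
        assert count_tokens("a b c") == 3

    def test_pluggable_tokenizer_counts_its_own_tokens(self):
        tokenizer = lambda s: list(s)  # character tokenizer
        assert count_tokens("abc", tokenizer) == 3

    @pytest.mark.parametrize(
        "tokens,cents", [(1_000_000, 500.0), (0, 0.0), (380, 0.19)]
    )
    def test_cents_arithmetic(self, tokens, cents):
        assert per_query_cost(tokens) == pytest.approx(cents)

    def test_negative_tokens_rejected(self):
        with pytest.raises(ValueError):
            per_query_cost(-1)


def _curve_points(f0, f_inf, lam, costs, noise=0.0, rng=None):
    pts = []
    for i, c in enumerate(costs):
        f1 = f_inf - (f_inf - f0) * math.exp(-lam * (c - costs[0]))
        if noise:
            f1 += rng.normal(0, noise)
        pts.append(CostPoint(k=i, mean_tokens=c * 2000, cost_cents=c,
                             f1=min(max(f1, 0.0), 1.0)))
    return pts


class TestExponentialFit:
    COSTS = [0.19, 0.30, 0.42, 0.64, 0.90, 1.20, 1.60, 2.00]

    def test_noiseless_recovery(self):
        pts = _curve_points(0.70, 0.76, 10.0, self.COSTS)
        fit = fit_asymptotic_exponential(pts)
        assert fit.valid
        assert fit.f_inf == pytest.approx(0.76, abs=1e-6)
        assert fit.lam == pytest.approx(10.0, abs=1e-5)
        assert fit.delta_c50 == pytest.approx(math.log(2) / 10, abs=1e-6)
        assert fit.rmse < 1e-8

    def test_curve_anchored_at_baseline(self):
        pts = _curve_points(0.5, 0.8, 3.0, self.COSTS)
        fit = fit_asymptotic_exponential(pts)
        assert fit.predict(fit.c0) == pytest.approx(fit.f0, abs=1e-12)

    def test_c95_ratio_identity(self):
        """delta_c95/delta_c50 = log(20)/log(2) for every valid fit."""
        for lam in [0.5, 1.0, 7.3]:
            pts = _curve_points(0.4, 0.6, lam, self.COSTS)
            fit = fit_asymptotic_exponential(pts)
            assert fit.delta_c95 / fit.delta_c50 == pytest.approx(
                math.log(20) / math.log(2), rel=1e-12
            )
            assert fit.c95 == pytest.approx(fit.c0 + fit.delta_c95)

    def test_monotone_when_plateau_above_baseline(self):
        pts = _curve_points(0.3, 0.7, 2.0, self.COSTS)
        fit = fit_asymptotic_exponential(pts)
        grid = np.linspace(fit.c0, 5.0, 200)
        vals = fit.predict(grid)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_sse_matches_grid_search_oracle(self, rng):
        pts = _curve_points(0.40, 0.55, 4.0, self.COSTS, noise=0.01, rng=rng)
        fit = fit_asymptotic_exponential(pts)
        x = np.array([p.cost_cents - pts[0].cost_cents for p in pts])
        y = np.array([p.f1 for p in pts])

        def sse(f_inf, lam):
            pred = f_inf - (f_inf - fit.f0) * np.exp(-lam * x)
            return float(np.sum((pred - y) ** 2))

        best = min(
            sse(fi, la)
            for fi in np.linspace(0.45, 0.65, 201)
            for la in np.linspace(1.0, 8.0, 281)
        )
        fitted_sse = sse(fit.f_inf, fit.lam)
        assert fitted_sse <= best + 1e-8

    def test_non_monotonic_data_flagged_invalid(self):
        costs = self.COSTS
        f1s = [0.23, 0.21, 0.25, 0.20, 0.24, 0.19, 0.22, 0.21]
        pts = [CostPoint(k=i, mean_tokens=0, cost_cents=c, f1=f)
               for i, (c, f) in enumerate(zip(costs, f1s))]
        fit = fit_asymptotic_exponential(pts)
        assert not fit.valid or fit.f_inf > fit.f0  # flat/declining curves flagged

    def test_parameter_recovery_under_noise(self, rng):
        """Median |lambda error| within 20% over 100 noisy synthetic curves."""
        true_lam = 4.0
        errors = []
        for _ in range(100):
            pts = _curve_points(0.5, 0.7, true_lam, self.COSTS, noise=0.01, rng=rng)
            fit = fit_asymptotic_exponential(pts)
            if fit.valid:
                errors.append(abs(fit.lam - true_lam))
        assert np.median(errors) < 0.2 * true_lam

    def test_requires_baseline_point(self):
        pts = _curve_points(0.5, 0.7, 2.0, self.COSTS)[1:]
        with pytest.raises(ValueError):
            fit_asymptotic_exponential(pts)


class TestLoess:
    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(0.1, 2.0, 9)
        model = LoessModel(x=x, y=2.0 + 3.0 * x, span=0.75)
        for x0 in [0.3, 0.77, 1.5, 1.95]:
            assert loess_predict(model, x0) == pytest.approx(2.0 + 3.0 * x0, abs=1e-10)

    def test_direct_normal_equation_oracle_at_training_point(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.1, 0.5, 0.4, 0.8, 0.6])
        model = LoessModel(x=x, y=y, span=0.8)
        x0 = 2.0
        q = math.ceil(0.8 * 5)
        d = np.abs(x - x0)
        nb = np.argsort(d, kind="stable")[:q]
        dmax = d[nb].max()
        w = np.zeros(5)
        w[nb] = (1 - (d[nb] / dmax) ** 3) ** 3
        X = np.column_stack([np.ones(5), x - x0])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert loess_predict(model, x0) == pytest.approx(beta[0], abs=1e-12)

    def test_span_one_on_three_points_equals_global_weighted_regression(self):
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([0.2, 0.6, 0.5])
        model = LoessModel(x=x, y=y, span=1.0)
        x0 = 0.5
        d = np.abs(x - x0)
        w = (1 - (d / d.max()) ** 3) ** 3
        X = np.column_stack([np.ones(3), x - x0])
        beta = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w),
                               rcond=None)[0]
        assert loess_predict(model, x0) == pytest.approx(beta[0], abs=1e-12)

    def test_degenerate_neighborhood_rejected(self):
        model = LoessModel(x=np.array([1.0, 1.0, 1.0, 5.0]),
                           y=np.array([1.0, 1.0, 1.0, 2.0]), span=0.5)
        with pytest.raises(ValueError):
            loess_predict(model, 1.0)

    def test_matches_statsmodels_lowess_on_smooth_data(self):
        """Independent oracle: statsmodels' LOWESS at training abscissae."""
        statsmodels = pytest.importorskip("statsmodels.api")
        # span * n integral so both implementations use the same
        # neighborhood size (conventions differ on ceil vs floor otherwise)
        x = np.linspace(0.0, 3.0, 16)
        y = np.sin(x) * 0.3 + 0.5
        model = LoessModel(x=x, y=y, span=0.75)
        smoothed = statsmodels.nonparametric.lowess(
            y, x, frac=0.75, it=0, return_sorted=True
        )
        ours = np.array([loess_predict(model, xi) for xi in x])
        assert np.allclose(ours, smoothed[:, 1], atol=1e-10)


class TestBootstrapBands:
    def _counts(self, per_doc):
        return [DocCounts(f"d{i}", EntityType.SIGN, *tpl)
                for i, tpl in enumerate(per_doc)]

    def test_identical_documents_zero_width(self):
        per_k = {
            0: self._counts([(1, 2, 2)] * 4),
            1: self._counts([(2, 2, 2)] * 4),
            2: self._counts([(2, 2, 2)] * 4),
        }
        costs = {0: 0.1, 1: 0.3, 2: 0.5}
        band = bootstrap_bands(per_k, costs, grid=[0.2, 0.4],
                               n_replicates=50, seed=0)
        assert np.allclose(band["low"], band["high"])

    def test_seed_determinism(self):
        per_k = {
            0: self._counts([(1, 2, 2), (0, 1, 2), (2, 2, 2)]),
            1: self._counts([(2, 2, 2), (1, 1, 2), (2, 2, 2)]),
            2: self._counts([(2, 2, 2), (1, 1, 2), (1, 2, 2)]),
        }
        costs = {0: 0.1, 1: 0.4, 2: 0.7}
        kwargs = dict(grid=[0.2, 0.3], smoother="loess", span=1.0,
                      n_replicates=100, seed=5)
        a = bootstrap_bands(per_k, costs, **kwargs)
        b = bootstrap_bands(per_k, costs, **kwargs)
        assert np.array_equal(a["low"], b["low"])
        assert np.array_equal(a["high"], b["high"])
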