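import numpy as np
import pandas as pd
import pytest

from cqbatch.cqr import (
    CQRFit,
    ZIQuantileFunction,
    check_loss,
    correct_nonsystematic,
    default_tau_grid,
    fit_cqr_model,
    fit_cqr_otu,
    predict_quantile,
    zi_quantile,
    zi_quantile_level,
)
from cqbatch.data import filter_otus
from cqbatch.nb import correct_systematic
from cqbatch.simulate import SimConfig, generate
from cqbatch.zeros import fit_zero_model


class TestCheckLoss:
    def test_zero_residual(self):
        for tau in (0.1, 0.5, 0.9):
            assert check_loss(0.0, tau) == 0.0

    def test_hand_values(self):
        assert check_loss(4, 0.5) == 2.0
        assert check_loss(-2, 0.25) == pytest.approx(1.5)

    def test_nonnegative_and_tau_domain(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=200) * 10
        for tau in (0.05, 0.5, 0.95):
            assert (check_loss(u, tau) >= 0).all()
        with pytest.raises(ValueError):
            check_loss(1.0, 1.0)


def _empty_design(n):
    idx = list(range(n))
    return pd.DataFrame(index=idx), pd.DataFrame(index=idx)


def grid_search_objective(y, M, taus, alpha_grid):
    """Coarse oracle: scan shared slopes; per-tau intercepts are exact
    (the tau-quantile of the residuals minimizes the check loss)."""
    best = np.inf
    for w in alpha_grid:
        resid = y - M @ np.atleast_1d(w)
        total = 0.0
        for tau in taus:
            b = np.quantile(resid, tau)
            total += np.sum(check_loss(resid - b, tau))
        best = min(best, total)
    return best


class TestFitCQROtu:
    def test_intercept_only_single_tau_is_median(self):
        rng = np.random.default_rng(1)
        y = np.sort(rng.gamma(2, 10, 31)) + 1
        X, B = _empty_design(31)
        fit = fit_cqr_otu(y, X, B, tau_grid=np.array([0.5]))
        assert fit.intercepts[0] == pytest.approx(np.median(y), abs=1e-6)

    def test_intercept_only_grid_recovers_empirical_quantiles(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(3, 5, 60) + 1
        taus = default_tau_grid(19)
        X, B = _empty_design(60)
        fit = fit_cqr_otu(y, X, B, taus, mode="composite")
        lo = np.quantile(y, taus, method="lower")
        hi = np.quantile(y, taus, method="higher")
        assert (fit.intercepts >= lo - 1e-6).all()
        assert (fit.intercepts <= hi + 1e-6).all()

    def test_objective_beats_coarse_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 30
        x = rng.normal(size=n)
        y = 10 + 2.0 * x + rng.gamma(2, 2, n)
        M = x[:, None]
        taus = default_tau_grid(5)
        X = pd.DataFrame({"x1": x})
        B = pd.DataFrame(index=range(n))
        fit = fit_cqr_otu(y, X, B, taus, mode="composite")
        oracle = grid_search_objective(y, M, taus, np.linspace(-1, 5, 61))
        assert fit.objective <= oracle + 1e-6

    def test_objective_no_worse_than_perturbed_coefficients(self):
        rng = np.random.default_rng(4)
        n = 80
        x = rng.normal(size=n)
        y = np.abs(5 + x + rng.standard_t(3, n)) + 1
        taus = default_tau_grid(9)
        X = pd.DataFrame({"x1": x})
        B = pd.DataFrame(index=range(n))
        fit = fit_cqr_otu(y, X, B, taus, mode="composite")
        for _ in range(20):
            b_alt = fit.intercepts + rng.normal(0, 0.5, taus.size)
            a_alt = fit.alpha + rng.normal(0, 0.3, fit.alpha.shape)
            total = sum(
                np.sum(check_loss(y - b_alt[s] - x * a_alt[0], tau))
                for s, tau in enumerate(taus)
            )
            assert fit.objective <= total + 1e-6

    def test_too_few_observations_falls_back(self):
        y = np.array([3.0, 5.0, 9.0, 2.0, 4.0])
        X, B = _empty_design(5)
        fit = fit_cqr_otu(y, X, B, default_tau_grid(19))
        assert fit.fallback and fit.mode == "empirical"

    def test_per_tau_mode_runs_and_rearranges(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        y = np.abs(8 + 2 * x + rng.normal(0, 3, n)) + 1
        X = pd.DataFrame({"x1": x})
        B = pd.DataFrame(index=range(n))
        fit = fit_cqr_otu(y, X, B, default_tau_grid(9), mode="per_tau")
        taus = fit.tau_grid
        for xv in (-1.0, 0.0, 2.0):
            g = [predict_quantile(fit, np.array([xv]), np.zeros(0), t) for t in taus]
            assert all(a <= b + 1e-9 for a, b in zip(g, g[1:]))


class TestPredictQuantile:
    def _fit(self):
        rng = np.random.default_rng(6)
        n = 100
        x = rng.normal(size=n)
        b2 = np.repeat([0.0, 1.0], n // 2)
        y = np.abs(10 + x + 3 * b2 + rng.normal(0, 2, n)) + 1
        X = pd.DataFrame({"x1": x})
        B = pd.DataFrame({"B2": b2})
        return fit_cqr_otu(y, X, B, default_tau_grid(9), mode="composite")

    def test_knot_value_and_monotonicity(self):
        fit = self._fit()
        x_row = np.array([0.3])
        g = fit.intercepts + 0.3 * fit.alpha[0]
        g = np.maximum(np.sort(g), fit.y_min)
        assert predict_quantile(fit, x_row, np.array([0.0]), fit.tau_grid[3]) == pytest.approx(g[3])
        taus = np.linspace(0.02, 0.98, 33)
        vals = [predict_quantile(fit, x_row, np.array([1.0]), t) for t in taus]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_batch_contexts_differ_by_delta(self):
        fit = self._fit()
        x_row = np.array([0.0])
        for tau in fit.tau_grid:
            own = predict_quantile(fit, x_row, np.array([1.0]), tau)
            ref = predict_quantile(fit, x_row, np.array([0.0]), tau)
            if own > fit.y_min and ref > fit.y_min:  # away from the floor
                assert own - ref == pytest.approx(fit.delta[0], abs=1e-8)


class TestZIQuantile:
    qf = ZIQuantileFunction(
        q=0.6,
        tau_grid=np.array([0.25, 0.5, 0.75]),
        grid_values=np.array([1.0, 2.0, 3.0]),
    )

    def test_zero_branch(self):
        assert zi_quantile(self.qf, 0.3) == 0.0

    def test_positive_branch_rescaling(self):
        # (0.7 - 0.4) / 0.6 = 0.5 -> positive_qf(0.5) = 2
        assert zi_quantile(self.qf, 0.7) == pytest.approx(2.0)

    def test_no_zero_inflation_limit(self):
        qf = ZIQuantileFunction(1 - 1e-9, self.qf.tau_grid, self.qf.grid_values)
        for tau in (0.25, 0.5, 0.75):
            assert zi_quantile(qf, tau) == pytest.approx(qf.positive_qf(tau), abs=1e-6)

    def test_branch_identity_around_threshold(self):
        eps = 1e-9
        assert zi_quantile(self.qf, 0.4 - eps) == 0.0
        assert zi_quantile(self.qf, 0.4 + eps) >= self.qf.grid_values[0] - 1e-6

    def test_non_decreasing(self):
        taus = np.linspace(0.01, 0.99, 99)
        vals = [zi_quantile(self.qf, t) for t in taus]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestZIQuantileLevel:
    qf = TestZIQuantile.qf

    def test_zero_maps_to_midpoint_of_zero_mass(self):
        assert zi_quantile_level(self.qf, 0.0) == pytest.approx(0.2)

    def test_round_trip_on_continuous_stretch(self):
        for y in (1.2, 1.8, 2.5, 2.9):
            tau = zi_quantile_level(self.qf, y)
            y_back = zi_quantile(self.qf, tau)
            assert zi_quantile_level(self.qf, y_back) == pytest.approx(tau, abs=1e-6)

    def test_strictly_increasing_on_positive_branch(self):
        ys = np.linspace(1.0, 3.0, 21)
        levels = [zi_quantile_level(self.qf, y) for y in ys]
        assert all(a < b for a, b in zip(levels, levels[1:]))

    def test_below_minimum_clamps_to_first_grid_level(self):
        tau = zi_quantile_level(self.qf, 0.5)
        assert tau == pytest.approx((1 - 0.6) + 0.6 * 0.25 / 2, abs=0.6 * 0.25)
        assert tau >= 0.4


def _stage2_inputs(seed, gamma=(0.6, -0.6), psi=(0.5, -0.5), theta=(0.3, 0.7),
                   n=60, m=25):
    cfg = SimConfig(n_per_batch=(n, n), m=m, gamma=gamma, psi=psi,
                    theta_per_batch=theta, seed=seed)
    table, design, _ = generate(cfg)
    work, _ = filter_otus(table, design)
    stage1, nb_fits = correct_systematic(work, design)
    ref = "B1"
    zfits = fit_zero_model(stage1, design, ref)
    cfits = fit_cqr_model(stage1, design, ref, tau_grid=default_tau_grid(9))
    return stage1, design, zfits, cfits, ref


class TestCorrectNonsystematic:
    def test_reference_batch_unchanged(self):
        stage1, design, zfits, cfits, ref = _stage2_inputs(seed=21)
        out = correct_nonsystematic(stage1, design, zfits, cfits, ref)
        mask = (design.batch == ref).to_numpy()
        np.testing.assert_array_equal(
            out.counts.to_numpy()[mask], stage1.counts.to_numpy()[mask]
        )

    def test_monotone_transport_for_fixed_context(self):
        """For one (sample, OTU) context, larger stage-1 values never map to
        smaller corrected values."""
        stage1, design, zfits, cfits, ref = _stage2_inputs(seed=22)
        from cqbatch.zeros import batch_columns, predict_q_matrix
        from cqbatch.cqr import _grid_matrix

        B_own = batch_columns(design, ref)
        B_ref = B_own * 0.0
        X = design.covariates
        for otu in stage1.otu_ids[:5]:
            zfit, cfit = zfits[otu], cfits[otu]
            i = int(np.flatnonzero((design.batch != ref).to_numpy())[0])
            own = ZIQuantileFunction(
                predict_q_matrix(zfit, X, B_own)[i], cfit.tau_grid,
                _grid_matrix(cfit, X.to_numpy(), B_own.to_numpy())[i])
            refqf = ZIQuantileFunction(
                predict_q_matrix(zfit, X, B_ref)[i], cfit.tau_grid,
                _grid_matrix(cfit, X.to_numpy(), B_ref.to_numpy())[i])
            outs = []
            for y in range(0, 120):
                tau = zi_quantile_level(own, float(y))
                outs.append(zi_quantile(refqf, tau))
            assert all(a <= b + 1e-9 for a, b in zip(outs, outs[1:]))

    def test_transport_exact_on_shared_context(self):
        stage1, design, zfits, cfits, ref = _stage2_inputs(seed=23)
        out = correct_nonsystematic(stage1, design, zfits, cfits, ref)
        otu = stage1.otu_ids[0]
        j = 0
        from cqbatch.zeros import batch_columns, predict_q_matrix
        from cqbatch.cqr import _grid_matrix, _levels_of_values, _values_at_levels

        B_own = batch_columns(design, ref)
        B_ref = B_own * 0.0
        X = design.covariates
        zfit, cfit = zfits[otu], cfits[otu]
        i = int(np.flatnonzero((design.batch != ref).to_numpy() &
                               (stage1.counts[otu] > 0).to_numpy())[0])
        q_own = predict_q_matrix(zfit, X, B_own)[i]
        q_ref = predict_q_matrix(zfit, X, B_ref)[i]
        G_own = _grid_matrix(cfit, X.to_numpy(), B_own.to_numpy())[i]
        G_ref = _grid_matrix(cfit, X.to_numpy(), B_ref.to_numpy())[i]
        y = float(stage1.counts[otu].iloc[i])
        own_qf = ZIQuantileFunction(q_own, cfit.tau_grid, G_own)
        ref_qf = ZIQuantileFunction(q_ref, cfit.tau_grid, G_ref)
        tau_obs = zi_quantile_level(own_qf, y)
        expected = zi_quantile(ref_qf, tau_obs)
        expected = 0.0 if tau_obs < 1 - q_ref else expected
        assert out.counts[otu].iloc[i] == np.round(max(expected, 0.0))

    def test_no_batch_signal_means_near_identity(self):
        stage1, design, zfits, cfits, ref = _stage2_inputs(
            seed=24, gamma=(0, 0), psi=(0, 0), theta=(0.3, 0.3))
        # force zero batch coefficients: contexts then coincide exactly
        for f in zfits.values():
            f.psi[:] = 0.0
            f.q[:] = np.clip(f.q, 1e-6, 1 - 1e-6)
        for f in cfits.values():
            if f.mode == "composite":
                f.delta[:] = 0.0
        out = correct_nonsystematic(stage1, design, zfits, cfits, ref)
        s1 = stage1.counts.to_numpy().astype(float)
        cor = out.counts.to_numpy().astype(float)
        nz = s1 > 0
        # transport through identical own/reference contexts preserves values
        # up to grid interpolation and rounding
        frac_same = np.mean(cor[nz] == s1[nz])
        assert frac_same > 0.8
        rel = np.abs(cor[nz] - s1[nz]) / s1[nz]
        assert np.median(rel) == 0.0
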