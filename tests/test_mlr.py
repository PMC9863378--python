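"""Weighted regression, pruning, ranking and leverage diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm

import qsarpt as q
from qsarpt.errors import CollinearityError, InsufficientDataError

from conftest import make_clearance
from test_selection import matrix_from


def planted_data(seed=0, n_comp=15, n_desc=4, betas=(0.2, -0.15, 0.1, 0.0),
                 intercept=0.5, noise=0.0, n_reps=5):
    rng = np.random.default_rng(seed)
    Xs = q.scale_matrix(matrix_from(rng.normal(size=(n_comp, n_desc))))
    mu = intercept + Xs.values @ np.asarray(betas)
    y = make_clearance(Xs.compound_ids, mu, n_reps=n_reps, noise=noise, seed=seed + 1)
    return Xs, y


class TestFitWLS:
    def test_exact_linear_fit(self):
        Xs, y = planted_data(betas=(0.2, -0.15, 0.0, 0.0), noise=0.0)
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1")
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.coef, [0.2, -0.15], atol=1e-10)

    @pytest.mark.parametrize("weighting", ["1", "1/Y", "1/Y2"])
    def test_matches_statsmodels_oracle(self, weighting):
        Xs, y = planted_data(noise=0.05)
        m = q.fit_wls(Xs, y, ("D1", "D2", "D3"), weighting)
        ci = y.records["ci"].to_numpy()
        row_of = {c: i for i, c in enumerate(Xs.compound_ids)}
        Z = Xs.columns(("D1", "D2", "D3"))[
            [row_of[c] for c in y.records["compound_id"]]
        ]
        w = {"1": np.ones_like(ci), "1/Y": 1 / ci, "1/Y2": 1 / ci**2}[weighting]
        res = sm.WLS(ci, sm.add_constant(Z), weights=w).fit()
        np.testing.assert_allclose(
            np.r_[m.intercept, m.coef], res.params, atol=1e-8
        )
        np.testing.assert_allclose(m.pvalues, res.pvalues[1:], atol=1e-8)
        assert m.aic == pytest.approx(res.aic, abs=1e-6)
        assert m.bic == pytest.approx(res.bic, abs=1e-6)

    def test_weighted_equals_sqrtw_row_scaling(self):
        Xs, y = planted_data(noise=0.05)
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1/Y")
        ci = y.records["ci"].to_numpy()
        row_of = {c: i for i, c in enumerate(Xs.compound_ids)}
        Z = Xs.columns(("D1", "D2"))[[row_of[c] for c in y.records["compound_id"]]]
        design = np.column_stack([np.ones(len(ci)), Z])
        sw = np.sqrt(1 / ci)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], ci * sw, rcond=None)
        np.testing.assert_allclose(np.r_[m.intercept, m.coef], beta, atol=1e-10)

    @pytest.mark.parametrize("weighting", ["1", "1/Y", "1/Y2"])
    def test_leverage_sums_to_parameter_count(self, weighting):
        Xs, y = planted_data(noise=0.03)
        m = q.fit_wls(Xs, y, ("D1", "D2", "D3"), weighting)
        assert m.leverage.sum() == pytest.approx(m.n_descriptors + 1, abs=1e-9)
        assert np.all(m.leverage >= 0) and np.all(m.leverage <= 1)

    def test_centroid_prediction_is_intercept(self):
        Xs, y = planted_data(noise=0.05)
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1/Y")
        assert m.predict_scaled(np.zeros((1, 2)))[0] == pytest.approx(m.intercept)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(2)
        V = rng.normal(size=(10, 3))
        V[:, 2] = V[:, 0] + V[:, 1]
        Xs = q.scale_matrix(matrix_from(V))
        y = make_clearance(Xs.compound_ids, np.linspace(0.2, 0.8, 10), n_reps=3)
        with pytest.raises(CollinearityError):
            q.fit_wls(Xs, y, ("D1", "D2", "D3"), "1")

    def test_insufficient_data(self):
        Xs, _ = planted_data(n_comp=3, n_desc=4)
        y = make_clearance(Xs.compound_ids, [0.2, 0.5, 0.8], n_reps=1)
        with pytest.raises(InsufficientDataError):
            q.fit_wls(Xs, y, ("D1", "D2", "D3"), "1")

    def test_raw_coefficient_backtransform(self):
        Xs, y = planted_data(noise=0.02)
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1")
        b0, betas = m.coefficients_raw()
        raw = np.column_stack(
            [Xs.values[:, 0] * Xs.scale[0] + Xs.center[0],
             Xs.values[:, 1] * Xs.scale[1] + Xs.center[1]]
        )
        np.testing.assert_allclose(
            b0 + raw @ betas, m.predict_raw(raw), atol=1e-10
        )


class TestPruneModel:
    def test_noise_descriptor_removed(self):
        # 75 independent observations; the pure-noise descriptor's t-test is
        # nominal, so pruning should drop it in at least 90 % of simulations
        removed = 0
        for seed in range(20):
            Xs, y = planted_data(
                seed=seed, n_comp=75, n_reps=1, intercept=0.55,
                betas=(0.12, -0.1, 0.08, 0.0), noise=0.05,
            )
            m = q.fit_wls(Xs, y, ("D1", "D2", "D3", "D4"), "1/Y")
            pruned = q.prune_model(Xs, y, m)
            removed += "D4" not in pruned.codes
        assert removed >= 18

    def test_strong_model_unchanged(self):
        kept = 0
        for seed in range(20):
            Xs, y = planted_data(
                seed=seed, n_comp=75, n_reps=1, intercept=0.55,
                betas=(0.12, -0.1, 0.08, 0.06), noise=0.05,
            )
            m = q.fit_wls(Xs, y, ("D1", "D2", "D3", "D4"), "1/Y")
            kept += q.prune_model(Xs, y, m).codes == m.codes
        assert kept >= 18

    def test_pure_noise_outcome_degenerates(self):
        rng = np.random.default_rng(7)
        Xs = q.scale_matrix(matrix_from(rng.normal(size=(15, 3))))
        y = make_clearance(
            Xs.compound_ids, np.full(15, 0.5), n_reps=5, noise=0.1, seed=7
        )
        m = q.fit_wls(Xs, y, ("D1", "D2", "D3"), "1")
        pruned = q.prune_model(Xs, y, m)
        assert pruned.degenerate
        assert pruned.n_descriptors == 0


class TestRankModels:
    def test_bic_prefers_parsimonious_nested_model(self):
        Xs, y = planted_data(seed=11, betas=(0.25, -0.2, 0.0, 0.0), noise=0.05)
        small = q.fit_wls(Xs, y, ("D1", "D2"), "1/Y")
        big = q.fit_wls(Xs, y, ("D1", "D2", "D3"), "1/Y")
        ranked = q.rank_models([big, small], r2_min=0.0)
        assert ranked[0].codes == ("D1", "D2")

    def test_low_r2_filtered(self):
        Xs, y = planted_data(seed=3, betas=(0.08, 0.0, 0.0, 0.0), noise=0.12)
        m = q.fit_wls(Xs, y, ("D1",), "1")
        assert m.r2 < 0.7
        assert q.rank_models([m], r2_min=0.7) == []

    def test_single_survivor_returned(self):
        Xs, y = planted_data(seed=1, noise=0.03)
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1/Y")
        ranked = q.rank_models([m], r2_min=0.5)
        assert ranked == [m]


class TestLeverageFlags:
    def test_balanced_design_unflagged(self):
        # two-level full factorial: every compound shares the same hat value
        V = np.array(
            [[-1, -1], [-1, 1], [1, -1], [1, 1]] * 2, dtype=float
        )
        Xs = q.scale_matrix(matrix_from(V))
        y = make_clearance(Xs.compound_ids, np.linspace(0.2, 0.9, 8), n_reps=3)
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1")
        assert not any(q.flag_high_leverage(m).values())

    def test_displaced_outlier_flagged(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(15, 2))
        V[0] = 10 * np.abs(V).max(axis=0)  # far outside the cloud
        Xs = q.scale_matrix(matrix_from(V))
        y = make_clearance(
            Xs.compound_ids, np.linspace(0.2, 0.9, 15), n_reps=5, noise=0.02, seed=5
        )
        m = q.fit_wls(Xs, y, ("D1", "D2"), "1")
        flags = q.flag_high_leverage(m)
        assert flags["C1"]
        assert sum(flags.values()) == 1

    def test_leverage_share_replicate_invariant(self):
        Xs, _ = planted_data(seed=9)
        for reps in (1, 5):
            y = make_clearance(
                Xs.compound_ids, np.linspace(0.2, 0.9, 15), n_reps=reps
            )
            m = q.fit_wls(Xs, y, ("D1", "D2"), "1")
            if reps == 1:
                share1 = m.leverage_share()
            else:
                np.testing.assert_allclose(
                    m.leverage_share().to_numpy(), share1.to_numpy(), atol=1e-10
                )
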