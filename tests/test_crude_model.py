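"""Single-country model: sampler contracts, degenerate limits, GP prediction."""

import numpy as np
import pytest

import gpvalue as g
from gpvalue.crude_model import McmcDraws, posterior_summary
from gpvalue.state_space import kernel_matrix, levels_matrix, parse_state_code


def _records(y_by, reps=1):
    """AdjustedRecords: {respondent: [(code, y), ...]} replicated `reps` times."""
    out = []
    for r in range(reps):
        for rid, vals in y_by.items():
            for code, y in vals:
                out.append(g.AdjustedRecord(f"{rid}_{r}", parse_state_code(code), y))
    return out


def _single_draw(states, u, *, intercept=1.0, slopes=(0.0,) * 6, sigma_sq=0.04,
                 gamma0=0.0, tau_sq=1e-12, v_sq=0.01, system=None, roughness=None):
    """Hand-built one-draw McmcDraws for deterministic prediction checks."""
    system = system or g.DEFAULT_SYSTEM
    roughness = roughness or g.RoughnessParams.default(system)
    R = 1
    return McmcDraws(
        states=list(states),
        system=system,
        roughness=roughness,
        respondent_ids=["r0", "r1"],
        u=np.asarray([u], dtype=float),
        alpha=np.ones((R, 2)),
        mean_intercept=np.full(R, intercept),
        mean_slopes=np.tile(np.asarray(slopes, dtype=float), (R, 1)),
        re_coefficients=np.full((R, 1), gamma0),
        tau_sq=np.full(R, tau_sq),
        v_sq=np.full(R, v_sq),
        sigma_sq=np.full(R, sigma_sq),
        alpha_bar=np.exp(np.full(R, gamma0) + 0.5 * np.full(R, tau_sq)),
        config=g.McmcConfig(n_iterations=2, n_burnin=1, thin=1),
    )


@pytest.fixture(scope="module")
def tiny_fit():
    """Fast deterministic fit on a tiny hand-made dataset."""
    y_by = {
        f"p{j}": [("211111", 0.90 + 0.01 * (j % 3)), ("343433", 0.55 - 0.01 * j),
                  ("645655", 0.30 + 0.02 * (j % 2))]
        for j in range(8)
    }
    data = _records(y_by)
    cfg = g.McmcConfig(n_iterations=400, n_burnin=200, thin=2, seed=5)
    return data, cfg, g.fit_crude(data, cfg)


class TestSamplerContracts:
    def test_same_seed_gives_identical_draws(self, tiny_fit):
        data, cfg, draws = tiny_fit
        again = g.fit_crude(data, cfg)
        assert np.array_equal(draws.u, again.u)
        assert np.array_equal(draws.alpha, again.alpha)
        assert np.array_equal(draws.sigma_sq, again.sigma_sq)

    def test_variance_draws_positive(self, tiny_fit):
        _, _, draws = tiny_fit
        assert (draws.tau_sq > 0).all()
        assert (draws.v_sq > 0).all()
        assert (draws.sigma_sq > 0).all()

    def test_full_health_fixed_at_one_in_every_draw(self, tiny_fit):
        _, _, draws = tiny_fit
        mat = g.posterior_draw_matrix(draws, [draws.system.full_health])
        assert np.all(mat == 1.0)

    def test_retained_draw_count(self, tiny_fit):
        _, cfg, draws = tiny_fit
        assert draws.n_draws == cfg.n_retained == 100

    def test_rejects_full_health_in_data(self):
        data = _records({"r0": [("111111", 1.0), ("645655", 0.3)],
                         "r1": [("111111", 1.0), ("645655", 0.4)]})
        with pytest.raises(ValueError, match="full health"):
            g.fit_crude(data, g.McmcConfig(n_iterations=10, n_burnin=5))

    def test_rejects_single_state_or_respondent(self):
        cfg = g.McmcConfig(n_iterations=10, n_burnin=5)
        with pytest.raises(ValueError):
            g.fit_crude(_records({"a": [("645655", 0.3)], "b": [("645655", 0.4)]}), cfg)
        with pytest.raises(ValueError):
            g.fit_crude(_records({"a": [("645655", 0.3), ("211111", 0.9)]}), cfg)


class TestDegenerateLimits:
    def test_alpha_one_tiny_noise_recovers_state_means(self):
        """With multipliers fixed at 1 and near-zero noise the posterior means
        of u collapse to the per-state sample means."""
        rng = np.random.default_rng(0)
        codes = ["213421", "343433", "443444", "645655"]
        true = {"213421": 0.72, "343433": 0.55, "443444": 0.44, "645655": 0.31}
        y_by = {
            f"p{j}": [(c, true[c] + 1e-4 * rng.standard_normal()) for c in codes]
            for j in range(10)
        }
        data = _records(y_by)
        cfg = g.McmcConfig(n_iterations=600, n_burnin=300, thin=1, seed=1)
        draws = g.fit_crude(data, cfg, fix_alpha=True, fixed_v_sq=1e-8)
        for k, s in enumerate(draws.states):
            obs = np.mean([y for rid in y_by for c, y in y_by[rid] if c == s.code])
            assert draws.u[:, k].mean() == pytest.approx(obs, abs=5e-4)

    def test_linear_gaussian_posterior_matches_dense_oracle(self):
        """alpha fixed at 1, fixed mean/scale/noise: the sampler draws iid from
        the exact Gaussian posterior, whose mean an independent dense-matrix
        conditioning oracle reproduces."""
        codes = ["211111", "232232", "343433", "544443", "645655"]
        states = [parse_state_code(c) for c in codes]
        y_obs = {"211111": 0.9, "232232": 0.7, "343433": 0.55, "544443": 0.45,
                 "645655": 0.3}
        y_by = {f"p{j}": [(c, y_obs[c]) for c in codes] for j in range(4)}
        data = _records(y_by)
        sigma_sq, v_sq = 0.04, 0.01
        mean = g.GpMeanParams(0.6, (0.0,) * 6)
        cfg = g.McmcConfig(n_iterations=4200, n_burnin=200, thin=1, seed=2, adapt=False)
        draws = g.fit_crude(
            data, cfg, fix_alpha=True, fixed_mean=mean,
            fixed_sigma_sq=sigma_sq, fixed_v_sq=v_sq,
        )

        # oracle: condition the joint normal of (u, all observations) directly
        rough = g.RoughnessParams.default()
        full = g.DEFAULT_SYSTEM.full_health
        C = kernel_matrix(states + [full], rough, jitter=0.0)
        m = len(states)
        # anchored prior via explicit partitioned conditioning on u(full)=1
        mu0 = np.full(m + 1, 0.6)
        cond_mean = mu0[:m] + C[:m, m] * (1.0 - mu0[m])
        cond_cov = sigma_sq * (C[:m, :m] - np.outer(C[:m, m], C[:m, m]))
        cond_cov += cfg.jitter * np.eye(m)
        n_rep = 4
        A = np.vstack([np.eye(m)] * n_rep)
        y = np.concatenate([[y_obs[c] for c in codes]] * n_rep)
        # z = y - 1 + alpha = u + eps with alpha = 1
        z = y - 1.0 + 1.0
        S_yy = A @ cond_cov @ A.T + v_sq * np.eye(m * n_rep)
        gain = cond_cov @ A.T @ np.linalg.inv(S_yy)
        oracle_mean = cond_mean + gain @ (z - A @ cond_mean)
        oracle_sd = np.sqrt(np.diag(cond_cov - gain @ A @ cond_cov))

        mc_se = oracle_sd / np.sqrt(draws.n_draws)
        order = {s.code: k for k, s in enumerate(draws.states)}
        for c, om, se in zip(codes, oracle_mean, mc_se):
            assert draws.u[:, order[c]].mean() == pytest.approx(om, abs=4.5 * se)

    def test_two_chains_different_seeds_agree_statistically(self, desk_fit):
        import dataclasses

        draws = desk_fit["draws"]
        other = g.fit_crude(
            desk_fit["data"]["donor"], dataclasses.replace(desk_fit["config"], seed=123)
        )
        assert np.allclose(draws.u.mean(0), other.u.mean(0), atol=0.02)


class TestPopulationMeanUtility:
    def test_full_health_is_exactly_one(self, tiny_fit):
        _, _, draws = tiny_fit
        assert g.population_mean_utility(draws, draws.system.full_health) == (1.0, 0.0)

    def test_identity_multiplier_gives_ubar_equal_u(self):
        states = [parse_state_code("232232"), parse_state_code("645655")]
        d = _single_draw(states, [0.7, 0.3], gamma0=0.0, tau_sq=1e-300)
        for k, s in enumerate(states):
            mean, _ = g.population_mean_utility(d, s)
            assert mean == pytest.approx(d.u[0, k], abs=1e-12)

    def test_lognormal_mean_closed_form(self):
        states = [parse_state_code("232232"), parse_state_code("645655")]
        d = _single_draw(states, [0.7, 0.3], gamma0=0.1, tau_sq=0.04)
        assert d.alpha_bar[0] == pytest.approx(np.exp(0.12), rel=1e-12)
        mean, _ = g.population_mean_utility(d, states[0])
        assert mean == pytest.approx(1 - np.exp(0.12) * 0.3, rel=1e-12)


class TestPredictStates:
    def test_modeled_state_reproduces_retained_draws(self, tiny_fit):
        _, _, draws = tiny_fit
        s = draws.states[1]
        mat = g.posterior_draw_matrix(draws, [s])
        assert np.array_equal(mat[:, 0], draws.u[:, 1])

    def test_conditional_matches_brute_force_partition(self):
        """3 modeled states + 1 new state, single fixed draw: conditional mean
        and variance must match the explicit joint-normal partition formula."""
        codes = ["213421", "343433", "645655"]
        states = [parse_state_code(c) for c in codes]
        new = parse_state_code("443444")
        u = [0.7, 0.5, 0.3]
        intercept, slopes, sigma_sq = 0.95, (-0.02, -0.01, -0.03, -0.02, -0.01, -0.02), 0.05
        d = _single_draw(states, u, intercept=intercept, slopes=slopes, sigma_sq=sigma_sq)
        pred = g.predict_states(d, [new], conditional_mean_only=True)

        # brute force: joint normal over (modeled, full, new), condition on
        # (modeled draws, anchor) via the standard partition formula
        rough, full = d.roughness, d.system.full_health
        allst = states + [full, new]
        C = kernel_matrix(allst, rough, jitter=0.0)
        C[np.diag_indices_from(C)] += d.config.jitter
        S = levels_matrix(allst) - 1.0
        mu = intercept + S @ np.asarray(slopes)
        cov = sigma_sq * C
        obs_idx, new_idx = [0, 1, 2, 3], [4]
        S_oo = cov[np.ix_(obs_idx, obs_idx)]
        S_no = cov[np.ix_(new_idx, obs_idx)]
        vals = np.array([*u, 1.0])
        bf_mean = (mu[4] + S_no @ np.linalg.solve(S_oo, vals - mu[obs_idx])).item()
        assert pred.mean[0] == pytest.approx(bf_mean, abs=1e-10)

        # with sampling on, the draw variance matches the partition variance
        bf_var = (cov[4, 4] - S_no @ np.linalg.solve(S_oo, S_no.T)).item()
        R = 4000
        dR = _single_draw(states, u, intercept=intercept, slopes=slopes, sigma_sq=sigma_sq)
        for attr in ("u", "alpha", "mean_intercept", "mean_slopes", "re_coefficients",
                     "tau_sq", "v_sq", "sigma_sq", "alpha_bar"):
            setattr(dR, attr, np.repeat(getattr(dR, attr), R, axis=0))
        mat = g.posterior_draw_matrix(dR, [new], seed=3)
        assert mat[:, 0].mean() == pytest.approx(bf_mean, abs=4 * np.sqrt(bf_var / R))
        assert mat[:, 0].var(ddof=1) == pytest.approx(bf_var, rel=0.1)

    def test_far_state_reverts_to_prior(self):
        """A state with negligible kernel correlation to everything modeled
        reverts to the GP mean function with variance ~ sigma^2."""
        states = [parse_state_code("211111"), parse_state_code("121111")]
        slopes = (-0.02, -0.02, -0.02, -0.02, -0.02, -0.02)
        d = _single_draw(states, [0.9, 0.85], intercept=1.0, slopes=slopes, sigma_sq=0.04)
        pits = d.system.pits
        pred = g.predict_states(d, [pits], conditional_mean_only=True)
        s = np.asarray(pits.levels) - 1.0
        prior_mean = 1.0 + s @ np.asarray(slopes)
        assert pred.mean[0] == pytest.approx(prior_mean, abs=1e-3)


class TestExportPosterior:
    def test_cov_diagonal_equals_empirical_variance(self, tiny_fit):
        _, _, draws = tiny_fit
        post = g.export_posterior(draws, draws.states)
        assert np.allclose(np.diag(post.cov), draws.u.var(axis=0, ddof=1))
        assert np.allclose(post.mean, draws.u.mean(axis=0))

    def test_permutation_invariance(self, tiny_fit):
        _, _, draws = tiny_fit
        post = g.export_posterior(draws, draws.states)
        perm = [2, 0, 1]
        post_p = g.export_posterior(draws, [draws.states[i] for i in perm])
        assert np.allclose(post_p.mean, post.mean[perm])
        assert np.allclose(post_p.cov, post.cov[np.ix_(perm, perm)])

    def test_full_health_row_is_exact(self, tiny_fit):
        _, _, draws = tiny_fit
        post = g.export_posterior(draws)
        k = post.index_of(draws.system.full_health)
        assert post.mean[k] == 1.0
        assert np.all(post.cov[k] == 0.0)

    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        _, _, draws = tiny_fit
        post = g.export_posterior(draws)
        post.save(tmp_path)
        back = g.CountryPosterior.load(tmp_path)
        assert [s.code for s in back.states] == [s.code for s in post.states]
        assert np.allclose(back.mean, post.mean)
        assert np.allclose(back.cov, post.cov, atol=1e-9)


class TestMonteCarloPrecision:
    def test_ubar_mcse_below_half_percent_at_default_config(self, desk_fit):
        """Batch-means Monte-Carlo se of every reported population mean
        utility stays below 0.005 at the default chain length."""
        from gpvalue.crude_model import batch_means_mcse

        data = desk_fit["data"]["donor"]
        draws = g.fit_crude(data, g.McmcConfig(seed=2))  # default config
        ubar = 1.0 - draws.alpha_bar[:, None] * (1.0 - draws.u)
        mcse = [batch_means_mcse(ubar[:, k]) for k in range(ubar.shape[1])]
        assert max(mcse) < 0.005


class TestPosteriorSummary:
    def test_summary_table_shape_and_anchor(self, tiny_fit):
        _, _, draws = tiny_fit
        df = posterior_summary(draws)
        assert list(df.columns) == ["state", "post_mean", "post_sd"]
        assert df.iloc[0]["state"] == "111111"
        assert df.iloc[0]["post_mean"] == 1.0
        assert df.iloc[0]["post_sd"] == 0.0
        assert (df["post_sd"][1:] > 0).all()
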