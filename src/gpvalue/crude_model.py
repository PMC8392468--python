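"""Single-country nonparametric Bayesian valuation model.

The observation model for respondent ``j`` valuing state ``x_ij`` is

    y_ij = 1 - alpha_j (1 - u(x_ij)) + eps_ij,
    alpha_j ~ LogNormal(t_j' gamma, tau^2),   eps_ij ~ N(0, v^2),

where ``u`` is the (representative-respondent) utility function, anchored at
``u(full health) = 1``, and the lognormal multiplier ``alpha_j`` scales each
respondent's disutility ``1 - u``.  ``u`` carries a Gaussian-process prior
with a linear mean in the (centred) dimension levels and squared-exponential
correlation; the anchor is imposed by conditioning the GP on
``u(full health) = 1``.  Variance hyperparameters get the standard
noninformative priors p(tau^2) ~ 1/tau^2, p(v^2) ~ 1/v^2, p(sigma^2) ~ 1/sigma.

Inference is Metropolis-within-Gibbs:

* ``u`` over the valued states is a block multivariate-normal full
  conditional (the model is linear-Gaussian given the alphas);
* each ``log alpha_j`` is a random-walk Metropolis step (all respondents
  proposed in parallel, accepted elementwise), followed by a joint scale move
  that shifts every ``log alpha_j`` and rescales the disutility surface
  together — the likelihood is invariant along that direction, so elementwise
  updates alone mix very poorly across it;
* ``tau^2`` and ``v^2`` have inverse-gamma full conditionals;
* the GP mean intercept/slopes have a normal full conditional;
* ``log sigma^2`` is a random-walk Metropolis step.

Proposal scales adapt toward a target acceptance rate during burn-in and are
frozen afterwards.  Population mean utilities are
``ubar(x) = 1 - abar (1 - u(x))`` with ``abar = exp(gamma_0 + tau^2/2)``, the
mean of the lognormal multiplier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from ._mvn import chol_logdet
from .sg_preprocessing import AdjustedRecord
from .state_space import (
    DEFAULT_SYSTEM,
    DescriptiveSystem,
    HealthState,
    RoughnessParams,
    kernel_matrix,
    levels_matrix,
    parse_state_code,
)

__all__ = [
    "GpMeanParams",
    "RespondentEffectParams",
    "NoiseParams",
    "GpScaleParams",
    "McmcConfig",
    "McmcDraws",
    "CountryPosterior",
    "fit_crude",
    "population_mean_utility",
    "predict_states",
    "posterior_draw_matrix",
    "export_posterior",
]


@dataclass(frozen=True)
class GpMeanParams:
    """Linear GP mean: intercept + slopes' (levels - 1)."""

    intercept: float
    slopes: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "slopes", tuple(float(s) for s in self.slopes))
        if len(self.slopes) != 6:
            raise ValueError("need 6 slopes")
        if not np.isfinite([self.intercept, *self.slopes]).all():
            raise ValueError("GP mean parameters must be finite")


@dataclass(frozen=True)
class RespondentEffectParams:
    """Lognormal respondent-multiplier parameters (intercept-only by default)."""

    coefficients: tuple[float, ...]
    tau_sq: float

    def __post_init__(self) -> None:
        if self.tau_sq <= 0:
            raise ValueError("tau_sq must be positive")


@dataclass(frozen=True)
class NoiseParams:
    v_sq: float

    def __post_init__(self) -> None:
        if self.v_sq <= 0:
            raise ValueError("v_sq must be positive")


@dataclass(frozen=True)
class GpScaleParams:
    """GP marginal variance and the (fixed) kernel roughness."""

    sigma_sq: float
    roughness: RoughnessParams

    def __post_init__(self) -> None:
        if self.sigma_sq <= 0:
            raise ValueError("sigma_sq must be positive")


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 10_000
    n_burnin: int = 2_000
    thin: int = 5
    seed: int = 0
    proposal_sd_log_alpha: float = 0.1
    proposal_sd_log_sigma: float = 0.1
    proposal_sd_log_scale: float = 0.1
    jitter: float = 1e-8
    adapt: bool = True
    # Weakly-informative proper priors on the GP-mean coefficients.  The
    # likelihood is exactly flat along a joint rescaling of the respondent
    # multipliers and the disutility surface, and with improper flat priors
    # the posterior drifts along that gauge; proper priors at substantively
    # generous scales pin it.  Utilities live in [-1, 1], so a per-level
    # decrement can never exceed 2/(l_d - 1) <= 0.67: N(0, 0.3^2) slopes are
    # generous.  The mean surface passes near 1 at full health: N(1, 1^2)
    # intercept.
    mean_prior_intercept_loc: float = 1.0
    mean_prior_intercept_sd: float = 1.0
    mean_prior_slope_sd: float = 0.3
    # The lognormal multiplier location is a pure gauge parameter: the data
    # constrain only the products alpha_j (1 - u(x)), so the location is
    # identified by convention alone.  A tight N(0, 0.05^2) prior fixes the
    # gauge at "median multiplier = 1"; population mean utilities
    # ubar = 1 - abar (1 - u) are exactly invariant to this choice.
    re_location_prior_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if min(self.n_iterations, self.thin) < 1:
            raise ValueError("n_iterations and thin must be positive")
        if min(self.proposal_sd_log_alpha, self.proposal_sd_log_sigma,
               self.proposal_sd_log_scale, self.jitter) <= 0:
            raise ValueError("proposal sds and jitter must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class CountryPosterior:
    """Posterior of latent utilities over a state set.

    Usable directly as a donor prior for another country: ``mean`` and ``cov``
    are the posterior mean vector and covariance matrix of ``u`` at ``states``.
    """

    states: list[HealthState]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = len(self.states)
        if self.mean.shape != (n,) or self.cov.shape != (n, n):
            raise ValueError("mean/cov shapes inconsistent with state list")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov), 0.0))

    def index_of(self, state: HealthState) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"state {state.code} not in posterior bundle") from None

    def subset(self, states: Sequence[HealthState]) -> "CountryPosterior":
        idx = [self.index_of(s) for s in states]
        return CountryPosterior(list(states), self.mean[idx], self.cov[np.ix_(idx, idx)])

    # -- text serialisation: a summary CSV plus a covariance CSV ------------

    def save(self, directory: str | Path, prefix: str = "posterior") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / f"{prefix}_mean.csv", "w", newline="\n") as fh:
            fh.write("state,post_mean,post_sd\n")
            for s, m, sd in zip(self.states, self.mean, self.sd):
                fh.write(f"{s.code},{m:.10g},{sd:.10g}\n")
        with open(directory / f"{prefix}_cov.csv", "w", newline="\n") as fh:
            fh.write(",".join(s.code for s in self.states) + "\n")
            for row in self.cov:
                fh.write(",".join(format(v, ".10g") for v in row) + "\n")

    @classmethod
    def load(
        cls,
        directory: str | Path,
        prefix: str = "posterior",
        system: DescriptiveSystem = DEFAULT_SYSTEM,
    ) -> "CountryPosterior":
        directory = Path(directory)
        states: list[HealthState] = []
        means: list[float] = []
        with open(directory / f"{prefix}_mean.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                states.append(parse_state_code(row["state"], system))
                means.append(float(row["post_mean"]))
        cov = np.loadtxt(directory / f"{prefix}_cov.csv", delimiter=",", skiprows=1, ndmin=2)
        return cls(states, np.asarray(means), cov)


@dataclass
class McmcDraws:
    """Retained MCMC draws plus everything needed to predict new states."""

    states: list[HealthState]  # modelled (valued) states, full health excluded
    system: DescriptiveSystem
    roughness: RoughnessParams
    respondent_ids: list[str]
    u: np.ndarray  # (R, m) latent utilities at `states`
    alpha: np.ndarray  # (R, J) respondent multipliers
    mean_intercept: np.ndarray  # (R,)
    mean_slopes: np.ndarray  # (R, 6)
    re_coefficients: np.ndarray  # (R, 1) lognormal location (intercept-only)
    tau_sq: np.ndarray  # (R,)
    v_sq: np.ndarray  # (R,)
    sigma_sq: np.ndarray  # (R,)
    alpha_bar: np.ndarray  # (R,) population-mean multiplier per draw
    config: McmcConfig
    donors: Optional[list[CountryPosterior]] = None
    donor_weights: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.u.shape[0]

    def state_index(self, state: HealthState) -> Optional[int]:
        try:
            return self.states.index(state)
        except ValueError:
            return None


# ---------------------------------------------------------------------------
# data preparation


def _prepare(data: Sequence[AdjustedRecord], system: DescriptiveSystem):
    if not data:
        raise ValueError("no adjusted records supplied")
    full = system.full_health
    states = sorted({r.state for r in data}, key=lambda s: s.code)
    if full in states:
        raise ValueError("full health is anchored at 1 and must not appear in the data")
    if len(states) < 2:
        raise ValueError("need at least 2 distinct valued states")
    resp = sorted({r.respondent_id for r in data})
    if len(resp) < 2:
        raise ValueError("need at least 2 respondents")
    sidx = {s: i for i, s in enumerate(states)}
    ridx = {r: i for i, r in enumerate(resp)}
    y = np.array([r.y for r in data], dtype=float)
    if np.any(np.abs(y) > 1.0):
        raise ValueError("adjusted values must lie in [-1, 1]")
    state_idx = np.array([sidx[r.state] for r in data], dtype=int)
    resp_idx = np.array([ridx[r.respondent_id] for r in data], dtype=int)
    return states, resp, y, state_idx, resp_idx


def _base_prior_pieces(
    states: list[HealthState],
    system: DescriptiveSystem,
    donors: Optional[list[CountryPosterior]],
    weights: Optional[np.ndarray],
):
    """Donor ("base") prior mean/cov over modelled states + the anchor.

    For the crude model the base is identically zero; for the transfer model
    it is the (weighted) sum of donor posterior means and covariances.
    """
    m = len(states)
    full = system.full_health
    if donors:
        from .prior_transfer_model import combine_donors  # local import, no cycle at runtime

        base_mean, base_cov = combine_donors(donors, states + [full], weights)
        return base_mean[:m], float(base_mean[m]), base_cov[:m, :m], base_cov[:m, m], float(
            base_cov[m, m]
        )
    return np.zeros(m), 0.0, np.zeros((m, m)), np.zeros(m), 0.0


class _AnchoredPrior:
    """GP prior over modelled states conditioned on u(full health) = 1.

    The unconditioned prior over (states, full) has mean
    ``base(x) + gamma + beta' s(x)`` (``s`` = centred levels, so s(full) = 0)
    and covariance ``B + sigma^2 C``.  Conditioning on the anchor value 1
    yields mean ``a + H theta`` with ``H = [1 - w, S]`` and a covariance that
    no longer depends on ``theta``.
    """

    def __init__(self, pieces, S, C_mm, C_mf, sigma_sq, jitter):
        base_m, base_f, B_mm, B_mf, B_ff = pieces
        self.sigma_sq = float(sigma_sq)
        sig_ff = B_ff + sigma_sq
        w = (B_mf + sigma_sq * C_mf) / sig_ff
        cov = B_mm + sigma_sq * C_mm - np.outer(w, w) * sig_ff
        cov[np.diag_indices_from(cov)] += jitter
        try:
            self.L = cholesky(cov, lower=True)
        except np.linalg.LinAlgError:
            # one retry with inflated jitter, then abort with a diagnostic
            cov[np.diag_indices_from(cov)] += 1e4 * jitter
            try:
                self.L = cholesky(cov, lower=True)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"GP prior covariance not positive definite at sigma_sq="
                    f"{sigma_sq:.3g} even with jitter {1e4 * jitter:.1e}; "
                    "check for duplicate states or a degenerate donor covariance"
                ) from exc
        self.logdet = chol_logdet(self.L)
        self.cov_inv = cho_solve((self.L, True), np.eye(len(w)))
        self.a = base_m + w * (1.0 - base_f)
        self.H = np.column_stack([1.0 - w, S])

    def mean(self, theta: np.ndarray) -> np.ndarray:
        return self.a + self.H @ theta

    def log_density(self, u: np.ndarray, theta: np.ndarray) -> float:
        z = solve_triangular(self.L, u - self.mean(theta), lower=True)
        return -0.5 * (self.logdet + float(z @ z))


def _run_sampler(
    y: np.ndarray,
    state_idx: np.ndarray,
    resp_idx: np.ndarray,
    S: np.ndarray,
    C_mm: np.ndarray,
    C_mf: np.ndarray,
    pieces,
    config: McmcConfig,
    *,
    fix_alpha: bool = False,
    fixed_mean: Optional[GpMeanParams] = None,
    fixed_sigma_sq: Optional[float] = None,
    fixed_v_sq: Optional[float] = None,
):
    rng = np.random.default_rng(config.seed)
    m = C_mm.shape[0]
    n_obs = y.shape[0]
    n_resp = int(resp_idx.max()) + 1
    obs_per_resp = np.bincount(resp_idx, minlength=n_resp)

    # --- initial values ------------------------------------------------
    u = np.clip(
        np.bincount(state_idx, weights=y, minlength=m)
        / np.maximum(np.bincount(state_idx, minlength=m), 1),
        -0.999,
        0.999,
    )
    s_alpha = np.zeros(n_resp)  # log alpha_j
    gamma0 = 0.0
    tau_sq = 0.04
    v_sq = max(float(np.var(y - u[state_idx])), 1e-4)
    sigma_sq = fixed_sigma_sq if fixed_sigma_sq is not None else 0.04
    prior = _AnchoredPrior(pieces, S, C_mm, C_mf, sigma_sq, config.jitter)
    if fixed_mean is not None:
        theta = np.array([fixed_mean.intercept, *fixed_mean.slopes])
    else:
        # least-squares start for the mean coefficients
        theta, *_ = np.linalg.lstsq(prior.H, u - prior.a, rcond=None)
    if fixed_v_sq is not None:
        v_sq = fixed_v_sq

    sd_a = config.proposal_sd_log_alpha
    sd_s = config.proposal_sd_log_sigma
    sd_c = config.proposal_sd_log_scale
    acc_a = acc_s = prop_s = 0
    prop_a = 0
    acc_c = prop_c = 0
    window_c = 0
    win_acc_c = 0.0
    theta_prior_mean = np.array([config.mean_prior_intercept_loc] + [0.0] * 6)
    theta_prior_prec = np.diag(
        [1.0 / config.mean_prior_intercept_sd**2] + [1.0 / config.mean_prior_slope_sd**2] * 6
    )

    R = config.n_retained
    out = {
        "u": np.empty((R, m)),
        "alpha": np.empty((R, n_resp)),
        "theta": np.empty((R, 7)),
        "gamma0": np.empty(R),
        "tau_sq": np.empty(R),
        "v_sq": np.empty(R),
        "sigma_sq": np.empty(R),
    }
    r = 0
    window_a = window_s = 0
    win_acc_a = win_acc_s = 0.0

    for it in range(config.n_iterations):
        alpha = np.exp(s_alpha)
        a_obs = alpha[resp_idx]

        # (a) u | rest: block MVN full conditional.
        # z_ij = y_ij - 1 + alpha_j = alpha_j u(x_ij) + eps_ij
        z = y - 1.0 + a_obs
        d = np.bincount(state_idx, weights=a_obs**2, minlength=m)
        b = np.bincount(state_idx, weights=a_obs * z, minlength=m)
        prec = prior.cov_inv + np.diag(d / v_sq)
        rhs = prior.cov_inv @ prior.mean(theta) + b / v_sq
        Lp = cholesky(prec, lower=True)
        mu = cho_solve((Lp, True), rhs)
        u = mu + solve_triangular(Lp.T, rng.standard_normal(m), lower=False)

        # (b) log alpha_j | rest: parallel random-walk Metropolis.
        w_obs = 1.0 - u[state_idx]
        if not fix_alpha:
            A = np.bincount(resp_idx, weights=w_obs**2, minlength=n_resp)
            B = np.bincount(resp_idx, weights=(1.0 - y) * w_obs, minlength=n_resp)
            prop = s_alpha + sd_a * rng.standard_normal(n_resp)
            a_new = np.exp(prop)
            ll_new = -(a_new**2 * A - 2.0 * a_new * B) / (2.0 * v_sq)
            ll_old = -(alpha**2 * A - 2.0 * alpha * B) / (2.0 * v_sq)
            lp_new = -0.5 * (prop - gamma0) ** 2 / tau_sq
            lp_old = -0.5 * (s_alpha - gamma0) ** 2 / tau_sq
            accept = np.log(rng.random(n_resp)) < (ll_new + lp_new - ll_old - lp_old)
            s_alpha = np.where(accept, prop, s_alpha)
            alpha = np.exp(s_alpha)
            a_obs = alpha[resp_idx]
            acc_a += int(accept.sum())
            prop_a += n_resp
            win_acc_a += accept.mean()
            window_a += 1

            # (b2) joint scale move along the alpha/disutility ridge.
            # The likelihood is invariant under alpha -> c alpha with
            # (1 - u) -> (1 - u)/c; only the priors (and the Jacobian c^-m)
            # decide, so this move lets the chain traverse the ridge that
            # elementwise updates cannot.
            logc = sd_c * rng.standard_normal()
            c_scale = np.exp(logc)
            s_new = s_alpha + logc
            u_new = 1.0 - (1.0 - u) / c_scale
            lp_new = prior.log_density(u_new, theta) - 0.5 * np.sum(
                (s_new - gamma0) ** 2
            ) / tau_sq
            lp_old = prior.log_density(u, theta) - 0.5 * np.sum(
                (s_alpha - gamma0) ** 2
            ) / tau_sq
            if np.log(rng.random()) < lp_new - lp_old - m * logc:
                s_alpha, u = s_new, u_new
                alpha = np.exp(s_alpha)
                a_obs = alpha[resp_idx]
                w_obs = 1.0 - u[state_idx]
                win_acc_c += 1.0
                acc_c += 1
            prop_c += 1
            window_c += 1

            # (c1) respondent-effect location and variance.
            prec0 = n_resp / tau_sq + 1.0 / config.re_location_prior_sd**2
            gamma0 = rng.normal(s_alpha.sum() / tau_sq / prec0, 1.0 / np.sqrt(prec0))
            ss = float(np.sum((s_alpha - gamma0) ** 2))
            tau_sq = (0.5 * ss + 1e-12) / rng.gamma(0.5 * n_resp)

        # (c2) observation noise.
        if fixed_v_sq is None:
            resid = y - (1.0 - a_obs * w_obs)
            v_sq = (0.5 * float(resid @ resid) + 1e-12) / rng.gamma(0.5 * n_obs)

        # (d) GP mean coefficients: normal full conditional under the
        # weakly-informative proper prior.
        if fixed_mean is None:
            Hw = solve_triangular(prior.L, prior.H, lower=True)
            uw = solve_triangular(prior.L, u - prior.a, lower=True)
            M = Hw.T @ Hw + theta_prior_prec
            Lm = cholesky(M, lower=True)
            t_hat = cho_solve((Lm, True), Hw.T @ uw + theta_prior_prec @ theta_prior_mean)
            theta = t_hat + solve_triangular(Lm.T, rng.standard_normal(7), lower=False)

        # (e) log sigma^2: random-walk Metropolis.
        if fixed_sigma_sq is None:
            s_cur = np.log(prior.sigma_sq)
            s_prop = s_cur + sd_s * rng.standard_normal()
            prior_prop = _AnchoredPrior(pieces, S, C_mm, C_mf, float(np.exp(s_prop)), config.jitter)
            # p(sigma^2) ~ sigma^-1 plus the log-scale Jacobian gives +s/2
            lp = prior_prop.log_density(u, theta) + 0.5 * s_prop
            lc = prior.log_density(u, theta) + 0.5 * s_cur
            if np.log(rng.random()) < lp - lc:
                prior = prior_prop
                acc_s += 1
                win_acc_s += 1.0
            prop_s += 1
            window_s += 1

        # adaptive proposal scaling during burn-in
        if config.adapt and it < config.n_burnin and window_a >= 50:
            rate = win_acc_a / window_a
            sd_a = float(np.clip(sd_a * np.exp(rate - 0.35), 1e-3, 5.0))
            win_acc_a = 0.0
            window_a = 0
        if config.adapt and it < config.n_burnin and window_s >= 50:
            rate = win_acc_s / window_s
            sd_s = float(np.clip(sd_s * np.exp(rate - 0.35), 1e-3, 5.0))
            win_acc_s = 0.0
            window_s = 0
        if config.adapt and it < config.n_burnin and window_c >= 50:
            rate = win_acc_c / window_c
            sd_c = float(np.clip(sd_c * np.exp(rate - 0.35), 1e-3, 5.0))
            win_acc_c = 0.0
            window_c = 0

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            out["u"][r] = u
            out["alpha"][r] = alpha
            out["theta"][r] = theta
            out["gamma0"][r] = gamma0
            out["tau_sq"][r] = tau_sq
            out["v_sq"][r] = v_sq
            out["sigma_sq"][r] = prior.sigma_sq
            r += 1

    diagnostics = {
        "accept_rate_log_alpha": acc_a / max(prop_a, 1),
        "accept_rate_log_sigma": acc_s / max(prop_s, 1),
        "accept_rate_log_scale": acc_c / max(prop_c, 1),
        "proposal_sd_log_alpha_final": sd_a,
        "proposal_sd_log_sigma_final": sd_s,
        "proposal_sd_log_scale_final": sd_c,
    }
    return out, diagnostics


def _fit(
    data: Sequence[AdjustedRecord],
    config: Optional[McmcConfig],
    system: DescriptiveSystem,
    roughness: Optional[RoughnessParams],
    donors: Optional[list[CountryPosterior]],
    donor_weights: Optional[Sequence[float]],
    **fixes,
) -> McmcDraws:
    config = config or McmcConfig()
    roughness = roughness or RoughnessParams.default(system)
    states, resp, y, state_idx, resp_idx = _prepare(data, system)
    full = system.full_health
    C_all = kernel_matrix(states + [full], roughness, jitter=0.0)
    m = len(states)
    C_mm, C_mf = C_all[:m, :m], C_all[:m, m]
    S = levels_matrix(states) - 1.0
    weights = None if donor_weights is None else np.asarray(donor_weights, dtype=float)
    pieces = _base_prior_pieces(states, system, donors, weights)
    out, diagnostics = _run_sampler(
        y, state_idx, resp_idx, S, C_mm, C_mf, pieces, config, **fixes
    )
    return McmcDraws(
        states=states,
        system=system,
        roughness=roughness,
        respondent_ids=resp,
        u=out["u"],
        alpha=out["alpha"],
        mean_intercept=out["theta"][:, 0],
        mean_slopes=out["theta"][:, 1:],
        re_coefficients=out["gamma0"][:, None],
        tau_sq=out["tau_sq"],
        v_sq=out["v_sq"],
        sigma_sq=out["sigma_sq"],
        alpha_bar=np.exp(out["gamma0"] + 0.5 * out["tau_sq"]),
        config=config,
        donors=list(donors) if donors else None,
        donor_weights=weights,
        diagnostics=diagnostics,
    )


def fit_crude(
    data: Sequence[AdjustedRecord],
    config: Optional[McmcConfig] = None,
    *,
    system: DescriptiveSystem = DEFAULT_SYSTEM,
    roughness: Optional[RoughnessParams] = None,
    fix_alpha: bool = False,
    fixed_mean: Optional[GpMeanParams] = None,
    fixed_sigma_sq: Optional[float] = None,
    fixed_v_sq: Optional[float] = None,
) -> McmcDraws:
    """Fit the single-country model with noninformative priors.

    The ``fix_*`` keywords freeze individual blocks of the sampler; they exist
    for degenerate-case checks (e.g. the linear-Gaussian limit with all
    multipliers fixed at 1) and are not used in normal analyses.
    """
    return _fit(
        data,
        config,
        system,
        roughness,
        donors=None,
        donor_weights=None,
        fix_alpha=fix_alpha,
        fixed_mean=fixed_mean,
        fixed_sigma_sq=fixed_sigma_sq,
        fixed_v_sq=fixed_v_sq,
    )


# ---------------------------------------------------------------------------
# posterior summaries and GP prediction


def _mean_matrix(draws: McmcDraws, states: list[HealthState]) -> np.ndarray:
    """Per-draw unconditioned prior mean at ``states``: base + gamma + beta's."""
    S = levels_matrix(states) - 1.0
    base = np.zeros(len(states))
    if draws.donors:
        from .prior_transfer_model import combine_donors

        base, _ = combine_donors(draws.donors, states, draws.donor_weights)
    theta = np.column_stack([draws.mean_intercept, draws.mean_slopes])  # (R, 7)
    H = np.column_stack([np.ones(len(states)), S])
    return base[None, :] + theta @ H.T  # (R, n)


def posterior_draw_matrix(
    draws: McmcDraws,
    states: Sequence[HealthState],
    *,
    seed: int = 0,
    conditional_mean_only: bool = False,
) -> np.ndarray:
    """Per-draw latent utilities ``u`` at ``states``, shape ``(R, len(states))``.

    Modelled states return their retained draws; full health is identically 1;
    any other state is drawn from (or, with ``conditional_mean_only``, set to
    the mean of) the GP conditional given that draw's modelled utilities, mean
    coefficients and scale, conditioning jointly on the anchor.
    """
    states = list(states)
    full = draws.system.full_health
    R = draws.n_draws
    result = np.empty((R, len(states)))
    new_states: list[HealthState] = []
    new_cols: list[int] = []
    for k, s in enumerate(states):
        if s == full:
            result[:, k] = 1.0
        else:
            i = draws.state_index(s)
            if i is not None:
                result[:, k] = draws.u[:, i]
            else:
                new_states.append(s)
                new_cols.append(k)
    if not new_states:
        return result

    rng = np.random.default_rng(seed)
    modeled = draws.states + [full]
    m1 = len(modeled)
    p = len(new_states)
    C_all = kernel_matrix(modeled + new_states, draws.roughness, jitter=0.0)
    C_all[np.diag_indices_from(C_all)] += draws.config.jitter
    vals = np.column_stack([draws.u, np.ones(R)])  # (R, m+1)
    m0_mod = _mean_matrix(draws, modeled)  # (R, m+1)
    m0_new = _mean_matrix(draws, new_states)  # (R, p)

    if not draws.donors:
        # sigma^2 scales the whole prior covariance, so the conditioning gain
        # is draw-independent and everything vectorises across draws.
        c = cho_factor(C_all[:m1, :m1], lower=True)
        G = cho_solve(c, C_all[:m1, m1:]).T  # (p, m+1)
        R_cond = C_all[m1:, m1:] - G @ C_all[:m1, m1:]
        mean_new = m0_new + (vals - m0_mod) @ G.T
        if conditional_mean_only:
            draws_new = mean_new
        else:
            Lc = cholesky(R_cond + draws.config.jitter * np.eye(p), lower=True)
            noise = rng.standard_normal((R, p)) @ Lc.T
            draws_new = mean_new + np.sqrt(draws.sigma_sq)[:, None] * noise
    else:
        from .prior_transfer_model import combine_donors

        base_mean, B_all = combine_donors(
            draws.donors, modeled + new_states, draws.donor_weights
        )
        draws_new = np.empty((R, p))
        for rdx in range(R):
            Sig = B_all + draws.sigma_sq[rdx] * C_all
            Sig[np.diag_indices_from(Sig)] += draws.config.jitter
            c = cho_factor(Sig[:m1, :m1], lower=True)
            G = cho_solve(c, Sig[:m1, m1:]).T
            mean_r = m0_new[rdx] + G @ (vals[rdx] - m0_mod[rdx])
            if conditional_mean_only:
                draws_new[rdx] = mean_r
            else:
                V = Sig[m1:, m1:] - G @ Sig[:m1, m1:]
                Lc = cholesky(V + draws.config.jitter * np.eye(p), lower=True)
                draws_new[rdx] = mean_r + Lc @ rng.standard_normal(p)
    result[:, new_cols] = draws_new
    return result


def predict_states(
    draws: McmcDraws,
    new_states: Sequence[HealthState],
    *,
    seed: int = 0,
    conditional_mean_only: bool = False,
) -> CountryPosterior:
    """Posterior of ``u`` at arbitrary states via GP conditioning per draw."""
    states = list(new_states)
    mat = posterior_draw_matrix(
        draws, states, seed=seed, conditional_mean_only=conditional_mean_only
    )
    mean = mat.mean(axis=0)
    centred = mat - mean
    cov = centred.T @ centred / max(mat.shape[0] - 1, 1)
    full = draws.system.full_health
    for k, s in enumerate(states):
        if s == full:  # exact anchor
            mean[k] = 1.0
            cov[k, :] = 0.0
            cov[:, k] = 0.0
    return CountryPosterior(states, mean, cov)


def export_posterior(
    draws: McmcDraws, states: Optional[Sequence[HealthState]] = None, *, seed: int = 0
) -> CountryPosterior:
    """Posterior mean/cov of the latent ``u`` (not ``ubar``) as a donor bundle.

    Defaults to the modelled states plus the full-health anchor.
    """
    if states is None:
        states = [draws.system.full_health] + list(draws.states)
    return predict_states(draws, states, seed=seed)


def population_mean_utility(
    draws: McmcDraws, state: HealthState, *, seed: int = 0
) -> tuple[float, float]:
    """Posterior mean and sd of ``ubar(x) = 1 - abar (1 - u(x))``."""
    u = posterior_draw_matrix(draws, [state], seed=seed)[:, 0]
    ubar = 1.0 - draws.alpha_bar * (1.0 - u)
    if state == draws.system.full_health:
        return 1.0, 0.0
    return float(ubar.mean()), float(ubar.std(ddof=1))


def batch_means_mcse(chain: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of a chain mean via non-overlapping batch
    means (robust to autocorrelation at realistic batch sizes)."""
    x = np.asarray(chain, dtype=float)
    if len(x) < 2 * n_batches:
        raise ValueError("chain too short for the requested number of batches")
    n = len(x) // n_batches * n_batches
    bm = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(bm.std(ddof=1) / np.sqrt(n_batches))


def posterior_summary(
    draws: McmcDraws,
    states: Optional[Sequence[HealthState]] = None,
    *,
    seed: int = 0,
):
    """Population mean-utility summary table: ``state, post_mean, post_sd``."""
    import pandas as pd

    if states is None:
        states = [draws.system.full_health] + list(draws.states)
    u = posterior_draw_matrix(draws, states, seed=seed)
    ubar = 1.0 - draws.alpha_bar[:, None] * (1.0 - u)
    full = draws.system.full_health
    rows = []
    for k, s in enumerate(states):
        if s == full:
            rows.append((s.code, 1.0, 0.0))
        else:
            rows.append((s.code, float(ubar[:, k].mean()), float(ubar[:, k].std(ddof=1))))
    return pd.DataFrame(rows, columns=["state", "post_mean", "post_sd"])
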