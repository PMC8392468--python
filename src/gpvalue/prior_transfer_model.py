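"""Cross-country informative-prior transfer.

A donor country's posterior over utilities — mean ``E(u_k(x))`` and
covariance ``cov(u_k(x), u_k(x'))`` — becomes the backbone of the target
country's GP prior:

    prior mean        m(x) = sum_k E(u_k(x)) + gamma + beta' x
    prior covariance  sum_k cov(u_k(x), u_k(x')) + sigma^2 c(x, x')

where the intercept ``gamma`` and per-dimension slopes ``beta`` absorb the
systematic country offset and ``sigma^2 c`` carries target-specific GP
fluctuation.  With a single donor this is the two-country transfer model;
the sum form handles any number of donors with (by default) equal weights.
Donor posteriors are plugged in as fixed quantities (two-stage estimation);
``gamma``, ``beta`` and ``sigma^2`` are sampled under the same noninformative
priors as the single-country model, with the identical sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .crude_model import (
    CountryPosterior,
    GpScaleParams,
    McmcConfig,
    McmcDraws,
    _fit,
)
from .sg_preprocessing import AdjustedRecord
from .state_space import (
    DEFAULT_SYSTEM,
    DescriptiveSystem,
    HealthState,
    RoughnessParams,
    kernel_matrix,
    levels_matrix,
)

__all__ = ["TransferPrior", "build_transfer_prior", "fit_transfer", "combine_donors"]


def combine_donors(
    donors: Sequence[CountryPosterior],
    states: Sequence[HealthState],
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sum of donor posterior means and covariances at ``states``.

    Every donor bundle must cover every requested state; a donor that was fit
    without a state should have been exported with that state predicted via GP
    conditioning first.
    """
    if not donors:
        raise ValueError("need at least one donor posterior")
    if weights is None:
        weights = np.ones(len(donors))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(donors),):
        raise ValueError("one weight per donor required")
    n = len(states)
    mean = np.zeros(n)
    cov = np.zeros((n, n))
    for wk, donor in zip(weights, donors):
        try:
            sub = donor.subset(list(states))
        except KeyError as exc:
            raise ValueError(
                f"donor posterior does not cover a required state: {exc.args[0]}; "
                "export the donor with that state predicted via GP conditioning"
            ) from None
        mean += wk * sub.mean
        cov += wk * sub.cov
    return mean, cov


@dataclass
class TransferPrior:
    """The target-country GP prior assembled from donor posteriors.

    ``base_mean`` / ``base_cov`` hold the summed donor components at
    ``states``; the offset intercept/slopes and the GP scale are the
    target-specific parameters (sampled during fitting, but settable here for
    direct evaluation of the prior).
    """

    states: list[HealthState]
    base_mean: np.ndarray
    base_cov: np.ndarray
    roughness: RoughnessParams
    offset_intercept: float = 0.0
    offset_slopes: tuple[float, ...] = (0.0,) * 6
    sigma_sq: float = 0.04
    donors: list[CountryPosterior] = field(default_factory=list)
    donor_weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.base_mean = np.asarray(self.base_mean, dtype=float)
        self.base_cov = np.asarray(self.base_cov, dtype=float)
        n = len(self.states)
        if self.base_mean.shape != (n,) or self.base_cov.shape != (n, n):
            raise ValueError("base mean/cov shapes inconsistent with states")
        eig = np.linalg.eigvalsh(0.5 * (self.base_cov + self.base_cov.T))
        if eig.min() < -1e-8:
            raise ValueError("donor covariance must be positive semidefinite")

    @property
    def scale(self) -> GpScaleParams:
        return GpScaleParams(self.sigma_sq, self.roughness)

    def prior_mean(self) -> np.ndarray:
        """m(x) = sum_k E(u_k(x)) + gamma + beta' s(x) at the prior's states."""
        S = levels_matrix(self.states) - 1.0
        return self.base_mean + self.offset_intercept + S @ np.asarray(self.offset_slopes)

    def prior_cov(self, jitter: float = 0.0) -> np.ndarray:
        """sum_k cov_k + sigma^2 c(x, x') at the prior's states."""
        C = kernel_matrix(self.states, self.roughness, jitter=jitter)
        return self.base_cov + self.sigma_sq * C


def build_transfer_prior(
    donors: Sequence[CountryPosterior],
    target_states: Sequence[HealthState],
    roughness: Optional[RoughnessParams] = None,
    *,
    system: DescriptiveSystem = DEFAULT_SYSTEM,
    donor_weights: Optional[Sequence[float]] = None,
    offset_intercept: float = 0.0,
    offset_slopes: Sequence[float] = (0.0,) * 6,
    sigma_sq: float = 0.04,
) -> TransferPrior:
    """Assemble the donor-informed GP prior at ``target_states``."""
    roughness = roughness or RoughnessParams.default(system)
    weights = None if donor_weights is None else np.asarray(donor_weights, dtype=float)
    states = list(target_states)
    base_mean, base_cov = combine_donors(donors, states, weights)
    return TransferPrior(
        states=states,
        base_mean=base_mean,
        base_cov=base_cov,
        roughness=roughness,
        offset_intercept=float(offset_intercept),
        offset_slopes=tuple(float(v) for v in offset_slopes),
        sigma_sq=float(sigma_sq),
        donors=list(donors),
        donor_weights=weights,
    )


def fit_transfer(
    data: Sequence[AdjustedRecord],
    donors: Sequence[CountryPosterior] | CountryPosterior,
    config: Optional[McmcConfig] = None,
    *,
    system: DescriptiveSystem = DEFAULT_SYSTEM,
    roughness: Optional[RoughnessParams] = None,
    donor_weights: Optional[Sequence[float]] = None,
    **fixes,
) -> McmcDraws:
    """Fit the target country with donor posteriors as the informative prior.

    Identical sampler to the single-country fit; only the GP prior mean and
    covariance differ (donor components held fixed, offsets and scale
    sampled).  Donor bundles are never mutated.
    """
    if isinstance(donors, CountryPosterior):
        donors = [donors]
    return _fit(data, config, system, roughness, list(donors), donor_weights, **fixes)
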