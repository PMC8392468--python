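"""Synthetic standard-gamble valuation data with known ground truth.

The generator reproduces exactly the statistical structure the valuation
model assumes, for a donor country and a linked target country:

* donor utilities are one draw from the GP prior (linear mean in centred
  levels, squared-exponential correlation, scale ``sigma^2``) conditioned on
  ``u(full health) = 1``;
* target utilities are the donor truth plus a linear country offset
  ``gamma* + beta*' s(x)`` plus an independent GP fluctuation, again anchored
  at full health;
* observed values are ``y = 1 - alpha_j (1 - u(x)) + eps`` with lognormal
  respondent multipliers and normal noise, clipped to the instrument's
  [-1, 1] range, with completely-at-random missingness.

Each respondent values ``quota - 1`` ordinary states (balanced round-robin
allocation) plus the pits state, mirroring the survey design in which the
pits valuation doubles as the chaining anchor.  The default parameter values
give observed state means spanning roughly 0.3-0.95 with about 4% clipping-free
respondent noise, the shape of real SG valuation data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from ._mvn import condition_mvn, sample_mvn
from .sg_preprocessing import AdjustedRecord, RawSgRecord
from .state_space import (
    DEFAULT_SYSTEM,
    DescriptiveSystem,
    HealthState,
    RoughnessParams,
    enumerate_states,
    kernel_matrix,
    levels_matrix,
)

__all__ = [
    "TruthParams",
    "SimulationScenario",
    "GroundTruth",
    "sample_true_utilities",
    "generate_valuations",
    "simulate",
    "paper_shaped_scenario",
    "random_states",
]


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters.

    Defaults: a linear utility surface dropping from 1 at full health to about
    0.31 at the pits, mild GP curvature (sigma^2 = 0.01, deviations from
    linearity of roughly 0.1), lognormal respondent multipliers with location
    0 and tau^2 = 0.04, observation noise v^2 = 0.01, and a modest mixed-sign
    country offset for the target.
    """

    mean_intercept: float = 1.0
    mean_slopes: tuple[float, ...] = (-0.030, -0.025, -0.025, -0.035, -0.025, -0.022)
    sigma_sq: float = 0.01
    gamma0: float = 0.0
    tau_sq: float = 0.04
    v_sq: float = 0.01
    transfer_intercept: float = 0.03
    transfer_slopes: tuple[float, ...] = (-0.004, 0.003, -0.002, 0.004, -0.003, 0.002)

    def __post_init__(self) -> None:
        # zeros are allowed: they give the exact degenerate limits
        if min(self.sigma_sq, self.v_sq, self.tau_sq) < 0:
            raise ValueError("variance parameters must be non-negative")


@dataclass
class SimulationScenario:
    """A two-country study design plus its generative truth."""

    donor_states: list[HealthState]
    target_states: list[HealthState]
    n_donor_respondents: int
    n_target_respondents: int
    donor_quota: int = 6
    target_quota: int = 8
    system: DescriptiveSystem = DEFAULT_SYSTEM
    roughness: Optional[RoughnessParams] = None
    truth: TruthParams = field(default_factory=TruthParams)
    missing_rate: float = 0.0
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        if self.roughness is None:
            self.roughness = RoughnessParams.default(self.system)
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        full = self.system.full_health
        pits = self.system.pits
        for name, states, quota, n_resp in (
            ("donor", self.donor_states, self.donor_quota, self.n_donor_respondents),
            ("target", self.target_states, self.target_quota, self.n_target_respondents),
        ):
            if full in states:
                raise ValueError(f"{name} states must not include full health")
            if pits not in states:
                raise ValueError(f"{name} states must include the pits (chaining anchor)")
            if len(set(states)) != len(states):
                raise ValueError(f"duplicate {name} states")
            if quota < 2:
                raise ValueError("quota must be >= 2 (>= 1 ordinary state plus the pits)")
            if quota - 1 > len(states) - 1:
                raise ValueError(f"{name} quota exceeds available ordinary states")
            if n_resp < 2:
                raise ValueError("need at least 2 respondents per country")


@dataclass
class GroundTruth:
    """True utilities, respondent multipliers and all scenario parameters."""

    scenario: SimulationScenario
    donor_utilities: dict[HealthState, float]
    target_utilities: dict[HealthState, float]
    donor_alphas: np.ndarray
    target_alphas: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "truth": asdict(self.scenario.truth),
            "missing_rate": self.scenario.missing_rate,
            "seed": self.scenario.seed,
            "donor_utilities": {s.code: v for s, v in self.donor_utilities.items()},
            "target_utilities": {s.code: v for s, v in self.target_utilities.items()},
            "donor_alphas": self.donor_alphas.tolist(),
            "target_alphas": self.target_alphas.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def random_states(
    n: int,
    rng: np.random.Generator,
    system: DescriptiveSystem = DEFAULT_SYSTEM,
    include_pits: bool = True,
    min_decrement: int = 1,
) -> list[HealthState]:
    """Sample ``n`` distinct states (never full health; pits forced in by default).

    ``min_decrement`` restricts the pool to states whose total level decrement
    ``sum(levels - 1)`` is at least that value; recovery experiments use it to
    keep true utilities away from the upper boundary, where the clipped
    instrument censors observations the fitted likelihood treats as exact.
    """
    pool = [
        s
        for s in enumerate_states(system)
        if s != system.full_health and sum(s.levels) - 6 >= min_decrement
    ]
    if len(pool) < n:
        raise ValueError("state pool smaller than requested sample")
    idx = rng.choice(len(pool), size=n, replace=False)
    states = [pool[i] for i in sorted(idx)]
    if include_pits and system.pits not in states:
        states[-1] = system.pits
    return states


def _anchored_gp_draw(
    rng: np.random.Generator,
    states: list[HealthState],
    mean: np.ndarray,
    sigma_sq: float,
    roughness: RoughnessParams,
    system: DescriptiveSystem,
) -> np.ndarray:
    """Draw u at ``states`` from GP(mean, sigma^2 c) given u(full health) = 1.

    ``mean`` must include the implied prior mean at full health as its last
    entry; ``states`` excludes full health.
    """
    full = system.full_health
    C = kernel_matrix(states + [full], roughness, jitter=1e-10)
    cov = sigma_sq * C
    m_c, V_c = condition_mvn(mean, cov, np.array([len(states)]), np.array([1.0]))
    return sample_mvn(rng, m_c, V_c)


def sample_true_utilities(
    scenario: SimulationScenario, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Draw ground-truth utility surfaces and respondent multipliers.

    Donor truth is drawn over the union of donor and target states so the two
    surfaces are linked state-by-state; the target surface adds the country
    offset and an independent anchored GP fluctuation.  With ``sigma_sq = 0``
    both surfaces are exactly linear in centred levels (anchored at 1).
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    tr = scenario.truth
    all_states = list(scenario.donor_states)
    for s in scenario.target_states:
        if s not in all_states:
            all_states.append(s)
    S = levels_matrix(all_states) - 1.0
    slopes = np.asarray(tr.mean_slopes)
    m0 = np.append(tr.mean_intercept + S @ slopes, tr.mean_intercept)
    if tr.sigma_sq > 0:
        u_all = _anchored_gp_draw(
            rng, all_states, m0, tr.sigma_sq, scenario.roughness, scenario.system
        )
    else:
        # degenerate GP: the anchored mean is exactly linear with intercept 1
        u_all = 1.0 + S @ slopes
    donor_u = dict(zip(all_states, u_all))
    # latent utilities are unbounded under the GP; small excursions past 1 near
    # full health are normal, material ones indicate a pathological scenario
    if np.any(np.abs(u_all) > 1.05):
        import warnings

        warnings.warn("true donor utilities leave [-1, 1] materially; pathological scenario")

    t_states = list(scenario.target_states)
    St = levels_matrix(t_states) - 1.0
    off = np.asarray(tr.transfer_slopes)
    mt = np.append(
        np.array([donor_u[s] for s in t_states]) + tr.transfer_intercept + St @ off,
        1.0 + tr.transfer_intercept,
    )
    if tr.sigma_sq > 0:
        u_t = _anchored_gp_draw(
            rng, t_states, mt, tr.sigma_sq, scenario.roughness, scenario.system
        )
    else:
        # degenerate limit: anchoring at full health cancels the offset intercept
        u_t = mt[:-1] - tr.transfer_intercept
    target_u = dict(zip(t_states, u_t))

    donor_alphas = rng.lognormal(tr.gamma0, np.sqrt(tr.tau_sq), scenario.n_donor_respondents)
    target_alphas = rng.lognormal(tr.gamma0, np.sqrt(tr.tau_sq), scenario.n_target_respondents)
    return GroundTruth(scenario, donor_u, target_u, donor_alphas, target_alphas)


def _country_valuations(
    rng: np.random.Generator,
    prefix: str,
    states: list[HealthState],
    utilities: dict[HealthState, float],
    alphas: np.ndarray,
    quota: int,
    truth: TruthParams,
    missing_rate: float,
    clip: bool,
    system: DescriptiveSystem,
):
    pits = system.pits
    ordinary = [s for s in states if s != pits]
    records: list[AdjustedRecord] = []
    n_missing = 0
    n_clipped = 0
    n_total = 0
    width = max(4, len(str(len(alphas))))
    for j, alpha in enumerate(alphas):
        rid = f"{prefix}{j:0{width}d}"
        assigned = [ordinary[(j * (quota - 1) + k) % len(ordinary)] for k in range(quota - 1)]
        assigned.append(pits)
        for x in assigned:
            n_total += 1
            if missing_rate > 0 and rng.random() < missing_rate:
                n_missing += 1
                continue
            y = 1.0 - alpha * (1.0 - utilities[x]) + rng.normal(0.0, np.sqrt(truth.v_sq))
            if clip:
                y_c = float(np.clip(y, -1.0, 1.0))
                if y_c != y:
                    n_clipped += 1
                y = y_c
            records.append(AdjustedRecord(rid, x, y))
    info = {
        "n_expected": n_total,
        "n_missing": n_missing,
        "n_observed": len(records),
        "n_clipped": n_clipped,
        "clipped_fraction": n_clipped / max(len(records) + n_missing, 1),
    }
    return records, info


def generate_valuations(
    truth: GroundTruth,
    scenario: Optional[SimulationScenario] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[AdjustedRecord]], dict[str, dict]]:
    """Generate per-country adjusted valuation records from a ground truth."""
    scenario = scenario or truth.scenario
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    data: dict[str, list[AdjustedRecord]] = {}
    info: dict[str, dict] = {}
    for country, states, utils, alphas, quota in (
        ("donor", scenario.donor_states, truth.donor_utilities, truth.donor_alphas,
         scenario.donor_quota),
        ("target", scenario.target_states, truth.target_utilities, truth.target_alphas,
         scenario.target_quota),
    ):
        data[country], info[country] = _country_valuations(
            rng, country[0], states, utils, alphas, quota, scenario.truth,
            scenario.missing_rate, scenario.clip, scenario.system,
        )
    return data, info


def simulate(
    scenario: SimulationScenario,
) -> tuple[GroundTruth, dict[str, list[AdjustedRecord]], dict[str, dict]]:
    """Draw truth and valuations in one deterministic pass from ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    truth = sample_true_utilities(scenario, rng)
    data, info = generate_valuations(truth, scenario, rng)
    return truth, data, info


def raw_records(
    records: list[AdjustedRecord], system: DescriptiveSystem = DEFAULT_SYSTEM
) -> list[RawSgRecord]:
    """Re-express adjusted records on the raw SG scale (convenience export).

    The pits row carries the pits valuation itself; other rows invert the
    chaining formula, clipping to [0, 1] where noise pushed ``y`` below the
    respondent's pits value (the physical instrument cannot produce those).
    """
    pits = system.pits
    by_resp: dict[str, list[AdjustedRecord]] = {}
    for r in records:
        by_resp.setdefault(r.respondent_id, []).append(r)
    out: list[RawSgRecord] = []
    for rid in sorted(by_resp):
        recs = by_resp[rid]
        p = next((r.y for r in recs if r.state == pits), None)
        for r in recs:
            if r.state == pits:
                out.append(RawSgRecord(rid, r.state, r.y, True))
            elif p is None or p >= 1.0:
                out.append(RawSgRecord(rid, r.state, None, False))
            else:
                sg = float(np.clip((r.y - p) / (1.0 - p), 0.0, 1.0))
                out.append(RawSgRecord(rid, r.state, sg, False))
    return out


def paper_shaped_scenario(
    scale: float = 1.0, seed: int = 0, **overrides
) -> SimulationScenario:
    """The study-shaped design: donor 249 states x 611 respondents x quota 6,
    target 49 states x 126 respondents x quota 8.

    ``scale`` shrinks the respondent counts (rounded, floor 2) for desk-speed
    runs; state sets and quotas are unchanged.  Extra keyword arguments
    override scenario fields (e.g. ``missing_rate`` or ``truth``).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    donor_states = random_states(249, rng)
    target_states = random_states(49, rng)
    defaults = dict(
        donor_states=donor_states,
        target_states=target_states,
        n_donor_respondents=max(2, round(611 * scale)),
        n_target_respondents=max(2, round(126 * scale)),
        donor_quota=6,
        target_quota=8,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationScenario(**defaults)
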