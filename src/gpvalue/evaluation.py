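"""Predictive-performance battery: RMSE, Bland-Altman agreement, monotonicity.

Predicted population mean utilities are compared with observed sample means
state by state.  Differences are defined as observed minus predicted; the
Bland-Altman limits of agreement are ``mean bias +/- 1.96 sd`` with the
population (n-divisor) standard deviation, and the full-health row (observed
1, predicted 1) is included wherever present.  The monotonicity audit samples
states without replacement, pairs each with a uniformly chosen adjacent state
(one dimension, one level apart) and counts pairs where the dominating state
— the one with the lower level in the differing dimension — gets a strictly
lower predicted value.  A small QALY illustration converts utility
differences into cost-per-QALY terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .state_space import DEFAULT_SYSTEM, DescriptiveSystem, HealthState, parse_state_code

__all__ = [
    "PredictionTable",
    "AgreementReport",
    "MonotonicityReport",
    "ModelComparison",
    "rmse",
    "bland_altman",
    "monotonicity_audit",
    "sample_adjacent_pairs",
    "qaly_cost_illustration",
    "compare_models",
    "load_table1",
    "table1_prediction_table",
]

Z_95 = 1.96


@dataclass
class PredictionTable:
    """Per-state observed means vs posterior predictions."""

    states: list[HealthState]
    observed_mean: np.ndarray
    post_mean: np.ndarray
    post_sd: np.ndarray

    def __post_init__(self) -> None:
        self.observed_mean = np.asarray(self.observed_mean, dtype=float)
        self.post_mean = np.asarray(self.post_mean, dtype=float)
        self.post_sd = np.asarray(self.post_sd, dtype=float)
        n = len(self.states)
        if not (self.observed_mean.shape == self.post_mean.shape == self.post_sd.shape == (n,)):
            raise ValueError("column lengths must match the state list")
        if len({s.code for s in self.states}) != n:
            raise ValueError("states must be unique")
        if np.any(np.abs(self.observed_mean) > 1) or np.any(np.abs(self.post_mean) > 1):
            raise ValueError("utility values must lie in [-1, 1]")
        if np.any(self.post_sd < 0):
            raise ValueError("posterior sds must be non-negative")

    def __len__(self) -> int:
        return len(self.states)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        observed: str = "observed_mean",
        mean: str = "post_mean",
        sd: str = "post_sd",
        system: DescriptiveSystem = DEFAULT_SYSTEM,
    ) -> "PredictionTable":
        states = [parse_state_code(str(c), system) for c in df["state"]]
        return cls(states, df[observed].to_numpy(), df[mean].to_numpy(), df[sd].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [s.code for s in self.states],
                "observed_mean": self.observed_mean,
                "post_mean": self.post_mean,
                "post_sd": self.post_sd,
            }
        )


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary of observed-minus-predicted differences."""

    rmse: float
    mean_bias: float
    diff_sd: float
    loa_low: float
    loa_high: float
    loa_range: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.diff_sd < 0 or self.n < 1:
            raise ValueError("invalid agreement report")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MonotonicityReport:
    n_pairs: int
    n_violations: int
    violation_rate: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def rmse(table: PredictionTable) -> float:
    """Root mean squared error of predicted vs observed means, all rows."""
    if len(table) == 0:
        raise ValueError("empty prediction table")
    d = table.post_mean - table.observed_mean
    return float(np.sqrt(np.mean(d * d)))


def bland_altman(table: PredictionTable) -> AgreementReport:
    """Limits of agreement for observed - predicted differences."""
    if len(table) < 2:
        raise ValueError("Bland-Altman needs at least 2 rows")
    d = table.observed_mean - table.post_mean
    bias = float(d.mean())
    sd = float(d.std(ddof=0))
    return AgreementReport(
        rmse=rmse(table),
        mean_bias=bias,
        diff_sd=sd,
        loa_low=bias - Z_95 * sd,
        loa_high=bias + Z_95 * sd,
        loa_range=2 * Z_95 * sd,
        n=len(table),
    )


def sample_adjacent_pairs(
    system: DescriptiveSystem = DEFAULT_SYSTEM,
    n_pairs: int = 10_000,
    seed: int = 0,
    return_primaries: bool = False,
):
    """Sample ``n_pairs`` (better, worse) adjacent state pairs.

    Primary states are drawn without replacement from the whole system; the
    partner is a uniform draw among the 6-12 states adjacent to the primary.
    Each pair is oriented so the first state has the lower level in the single
    differing dimension (the dominating state).
    """
    levels = np.array(
        list(itertools.product(*(range(1, l + 1) for l in system.levels_per_dimension))),
        dtype=int,
    )
    if n_pairs > len(levels):
        raise ValueError("n_pairs exceeds the number of states in the system")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(levels), size=n_pairs, replace=False)
    caps = np.asarray(system.levels_per_dimension)
    pairs: list[tuple[HealthState, HealthState]] = []
    for idx in picks:
        base = levels[idx]
        moves = [
            (d, delta)
            for d in range(6)
            for delta in (-1, 1)
            if 1 <= base[d] + delta <= caps[d]
        ]
        d, delta = moves[rng.integers(len(moves))]
        other = base.copy()
        other[d] += delta
        a, b = HealthState(tuple(base)), HealthState(tuple(other))
        pairs.append((a, b) if delta == 1 else (b, a))
    if return_primaries:
        return pairs, [HealthState(tuple(levels[i])) for i in picks]
    return pairs


def monotonicity_audit(
    predict: Callable[[HealthState], float],
    system: DescriptiveSystem = DEFAULT_SYSTEM,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> MonotonicityReport:
    """Count adjacent pairs whose better state is predicted strictly worse.

    Ties count as monotone, so a constant predictor scores zero.
    """
    pairs = sample_adjacent_pairs(system, n_pairs, seed)
    n_violations = sum(1 for better, worse in pairs if predict(better) < predict(worse))
    return MonotonicityReport(n_pairs, n_violations, n_violations / n_pairs, seed)


def qaly_cost_illustration(
    utility_a: float, utility_b: float, years: float, cost: float
) -> tuple[float, float, float, float]:
    """QALYs and cost per QALY for two utility estimates of the same profile."""
    for u in (utility_a, utility_b):
        if not 0 < u <= 1:
            raise ValueError("utilities must lie in (0, 1]")
    if years <= 0 or cost < 0:
        raise ValueError("years must be positive and cost non-negative")
    qalys_a, qalys_b = utility_a * years, utility_b * years
    return qalys_a, qalys_b, cost / qalys_a, cost / qalys_b


@dataclass
class ModelComparison:
    """Agreement reports plus the tables behind the comparison figures."""

    agreement: dict[str, AgreementReport]
    rmse: dict[str, float]
    figure1: dict[str, pd.DataFrame]  # per model, sorted by predicted mean
    figure3: pd.DataFrame  # observed vs each model's predictions


def compare_models(tables: Mapping[str, PredictionTable]) -> ModelComparison:
    """Consolidated comparison of several models over a common state set."""
    if not tables:
        raise ValueError("no prediction tables supplied")
    names = list(tables)
    ref = {s.code for s in tables[names[0]].states}
    for name in names[1:]:
        if {s.code for s in tables[name].states} != ref:
            raise ValueError("prediction tables must share the same state set")
    agreement = {n: bland_altman(t) for n, t in tables.items()}
    rmse_by = {n: agreement[n].rmse for n in names}
    figure1 = {}
    for n, t in tables.items():
        df = t.to_dataframe()
        df["error"] = df["observed_mean"] - df["post_mean"]
        figure1[n] = df.sort_values("post_mean", kind="mergesort").reset_index(drop=True)
    base = tables[names[0]].to_dataframe()[["state", "observed_mean"]]
    for n, t in tables.items():
        base = base.merge(
            t.to_dataframe()[["state", "post_mean"]].rename(columns={"post_mean": f"{n}_mean"}),
            on="state",
        )
    return ModelComparison(agreement, rmse_by, figure1, base)


# ---------------------------------------------------------------------------
# packaged reference table


def load_table1() -> pd.DataFrame:
    """The packaged per-state reference table: observed means, donor (UK)
    prior summaries, and both models' posterior summaries."""
    with resources.files("gpvalue").joinpath("fixtures/table1.csv").open() as fh:
        return pd.read_csv(fh, dtype={"state": str})


def table1_prediction_table(model: str = "crude") -> PredictionTable:
    """A PredictionTable for one of the packaged models: 'crude', 'model1' or 'uk'."""
    if model not in ("crude", "model1", "uk"):
        raise ValueError("model must be one of 'crude', 'model1', 'uk'")
    df = load_table1()
    return PredictionTable.from_dataframe(
        df, observed="observed_mean", mean=f"{model}_mean", sd=f"{model}_sd"
    )
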