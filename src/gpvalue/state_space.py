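"""SF-6D descriptive system: state codes, adjacency, and the GP correlation kernel.

The SF-6D classifies health on six ordinal dimensions (physical functioning,
role limitation, social functioning, pain, mental health, vitality) with
between 4 and 6 levels each.  A health state is a six-digit code, one digit
per dimension; ``111111`` is full health and ``645655`` ("the pits") is the
worst state.  The default system spans 6*4*5*6*5*5 = 18,000 states.

Utilities over states are modelled with a Gaussian process whose correlation
kernel is squared-exponential in the ordinal levels,

    c(x, x') = exp{ -sum_d b_d (x_d - x'_d)^2 },

with per-dimension roughness ``b_d`` fixed at ``2.5 / (l_d - 1)^2`` so that
two states at opposite extremes of any single dimension correlate at
exp(-2.5) ~ 0.08.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "DescriptiveSystem",
    "HealthState",
    "RoughnessParams",
    "DEFAULT_SYSTEM",
    "parse_state_code",
    "state_count",
    "enumerate_states",
    "adjacent_states",
    "kernel_correlation",
    "kernel_matrix",
    "levels_matrix",
]

_SF6D_LEVELS = (6, 4, 5, 6, 5, 5)
_SF6D_NAMES = (
    "physical functioning",
    "role limitation",
    "social functioning",
    "pain",
    "mental health",
    "vitality",
)


@dataclass(frozen=True)
class HealthState:
    """A single health state: one 1-based level per dimension."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))
        if any(v < 1 for v in self.levels):
            raise ValueError(f"levels must be >= 1, got {self.levels}")

    @property
    def code(self) -> str:
        """Six-digit string form, digit ``d`` = level on dimension ``d``."""
        return "".join(str(v) for v in self.levels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


@dataclass(frozen=True)
class DescriptiveSystem:
    """A multi-level descriptive system; defaults to the SF-6D."""

    levels_per_dimension: tuple[int, ...] = _SF6D_LEVELS
    dimension_names: tuple[str, ...] = _SF6D_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "levels_per_dimension", tuple(int(v) for v in self.levels_per_dimension)
        )
        object.__setattr__(self, "dimension_names", tuple(self.dimension_names))
        if len(self.levels_per_dimension) != 6:
            raise ValueError("a descriptive system has exactly 6 dimensions")
        if len(self.dimension_names) != 6:
            raise ValueError("need 6 dimension names")
        if any(l < 2 for l in self.levels_per_dimension):
            raise ValueError("every dimension needs at least 2 levels")

    @property
    def n_dimensions(self) -> int:
        return len(self.levels_per_dimension)

    @property
    def full_health(self) -> HealthState:
        return HealthState((1,) * self.n_dimensions)

    @property
    def pits(self) -> HealthState:
        """The worst state (maximum level on every dimension)."""
        return HealthState(self.levels_per_dimension)

    def contains(self, state: HealthState) -> bool:
        return len(state.levels) == self.n_dimensions and all(
            1 <= v <= l for v, l in zip(state.levels, self.levels_per_dimension)
        )


DEFAULT_SYSTEM = DescriptiveSystem()


@dataclass(frozen=True)
class RoughnessParams:
    """Per-dimension kernel decay rates ``b_d``.

    The default ``b_d = 2.5 / (l_d - 1)^2`` fixes the correlation between the
    two extreme levels of any dimension at exp(-2.5); larger ``b_d`` lets the
    utility surface deviate more sharply from its linear mean.
    """

    b: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))
        if len(self.b) != 6:
            raise ValueError("need one roughness parameter per dimension")
        if any(v <= 0 for v in self.b):
            raise ValueError("roughness parameters must be positive")

    @classmethod
    def default(cls, system: DescriptiveSystem = DEFAULT_SYSTEM) -> "RoughnessParams":
        return cls(tuple(2.5 / (l - 1) ** 2 for l in system.levels_per_dimension))


def parse_state_code(code: str, system: DescriptiveSystem = DEFAULT_SYSTEM) -> HealthState:
    """Parse a six-digit state code, validating each digit against the system.

    Raises ``ValueError`` for malformed codes or digits outside ``[1, l_d]``,
    naming the offending dimension.
    """
    if not isinstance(code, str):
        raise ValueError(f"state code must be a string, got {type(code).__name__}")
    code = code.strip()
    if len(code) != 6 or not code.isdigit():
        raise ValueError(f"state code must be 6 digit characters, got {code!r}")
    levels = tuple(int(ch) for ch in code)
    for d, (lev, l_d) in enumerate(zip(levels, system.levels_per_dimension)):
        if not 1 <= lev <= l_d:
            raise ValueError(
                f"level {lev} out of range [1, {l_d}] on dimension {d + 1} "
                f"({system.dimension_names[d]}) in state code {code!r}"
            )
    return HealthState(levels)


def state_count(system: DescriptiveSystem = DEFAULT_SYSTEM) -> int:
    """Total number of states = product of per-dimension level counts."""
    return int(np.prod(system.levels_per_dimension))


def enumerate_states(system: DescriptiveSystem = DEFAULT_SYSTEM) -> Iterator[HealthState]:
    """Yield every state of the system in lexicographic code order."""
    for combo in itertools.product(*(range(1, l + 1) for l in system.levels_per_dimension)):
        yield HealthState(combo)


def adjacent_states(
    state: HealthState, system: DescriptiveSystem = DEFAULT_SYSTEM
) -> set[HealthState]:
    """States differing from ``state`` in exactly one dimension by one level.

    Every state of the default system has between 6 (corner states such as
    full health or the pits) and 12 (all-interior states) neighbours.
    """
    if not system.contains(state):
        raise ValueError(f"state {state.code} is not in the system")
    out: set[HealthState] = set()
    for d, (lev, l_d) in enumerate(zip(state.levels, system.levels_per_dimension)):
        for delta in (-1, 1):
            new = lev + delta
            if 1 <= new <= l_d:
                levels = list(state.levels)
                levels[d] = new
                out.add(HealthState(tuple(levels)))
    return out


def kernel_correlation(x: HealthState, x2: HealthState, b: RoughnessParams) -> float:
    """Squared-exponential correlation between the utilities of two states."""
    d = np.asarray(x.levels, dtype=float) - np.asarray(x2.levels, dtype=float)
    return float(np.exp(-np.dot(np.asarray(b.b), d * d)))


def levels_matrix(states: Iterable[HealthState]) -> np.ndarray:
    """Stack state levels into an ``(n, 6)`` float array."""
    return np.asarray([s.levels for s in states], dtype=float)


def kernel_matrix(
    states: list[HealthState], b: RoughnessParams, jitter: float = 1e-8
) -> np.ndarray:
    """Correlation matrix over ``states`` with ``jitter`` added to the diagonal.

    The raw kernel matrix is symmetric with unit diagonal but can be
    numerically singular when states are close in level space; the diagonal
    jitter restores positive definiteness.  Duplicate states are allowed and
    simply yield off-diagonal entries of 1.
    """
    if len(states) == 0:
        raise ValueError("need at least one state")
    L = levels_matrix(states)
    bb = np.asarray(b.b)
    diff = L[:, None, :] - L[None, :, :]
    K = np.exp(-np.einsum("ijd,d->ij", diff * diff, bb))
    K[np.diag_indices_from(K)] += jitter
    return K
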