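"""Standard-gamble preprocessing: chaining, truncation and inclusion bookkeeping.

Each respondent values a handful of states against full health and the pits
using the standard gamble (SG), plus one direct valuation of the pits itself.
Raw SG indifference probabilities live on [0, 1]; they are chained onto the
death = 0 / full health = 1 utility scale through the respondent's own pits
valuation ``P``::

    SGADJ = SG + (1 - SG) * P

Pits valuations below -1 (states much worse than death) are floored at -1
before chaining.  The adjusted values are the dependent variable ``y`` of the
valuation model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .state_space import DEFAULT_SYSTEM, DescriptiveSystem, HealthState, parse_state_code

__all__ = [
    "RawSgRecord",
    "AdjustedRecord",
    "InclusionReport",
    "adjust_sg",
    "truncate_pits_value",
    "build_dataset",
    "read_raw_csv",
    "write_raw_csv",
    "read_adjusted_csv",
    "write_adjusted_csv",
]


@dataclass(frozen=True)
class RawSgRecord:
    """One raw SG response.

    ``sg`` is the indifference probability in [0, 1] for ordinary questions;
    for the pits question it is the direct pits valuation (possibly negative,
    floored at -1 downstream).  ``sg = None`` marks a missing response.
    """

    respondent_id: str
    state: HealthState
    sg: Optional[float]
    is_pits_question: bool = False


@dataclass(frozen=True)
class AdjustedRecord:
    """One chained valuation on the [-1, 1] scale."""

    respondent_id: str
    state: HealthState
    y: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.y <= 1.0:
            raise ValueError(f"adjusted value {self.y} outside [-1, 1]")


@dataclass(frozen=True)
class InclusionReport:
    """Respondent/value accounting for a valuation dataset."""

    n_respondents_contacted: int
    n_excluded: int
    n_eligible: int
    n_expected_values: int
    n_missing: int
    n_observed: int

    def __post_init__(self) -> None:
        if min(asdict(self).values()) < 0:
            raise ValueError("inclusion counts must be non-negative")
        if self.n_eligible != self.n_respondents_contacted - self.n_excluded:
            raise ValueError("n_eligible must equal contacted - excluded")
        if self.n_observed != self.n_expected_values - self.n_missing:
            raise ValueError("n_observed must equal expected - missing")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def to_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in asdict(self).items())


def adjust_sg(sg: float, pits_value: float) -> float:
    """Chain an SG probability through the (truncated) pits valuation."""
    if not 0.0 <= sg <= 1.0:
        raise ValueError(f"sg value {sg} outside [0, 1]")
    if not -1.0 <= pits_value <= 1.0:
        raise ValueError(f"pits value {pits_value} outside [-1, 1]")
    return sg + (1.0 - sg) * pits_value


def truncate_pits_value(raw_pits: float) -> float:
    """Floor a raw pits valuation at -1 (worse-than-death responses)."""
    if raw_pits > 1.0:
        raise ValueError(f"pits valuation {raw_pits} exceeds 1")
    return max(raw_pits, -1.0)


def build_dataset(
    records: Iterable[RawSgRecord],
    quota: int,
    *,
    n_contacted: Optional[int] = None,
    n_excluded_upstream: int = 0,
) -> tuple[list[AdjustedRecord], InclusionReport]:
    """Chain raw SG records onto [-1, 1] and account for every value.

    Respondents without a usable (non-missing, unique) pits valuation are
    excluded entirely.  For eligible respondents the pits record itself enters
    the dataset with ``y`` equal to the truncated pits valuation, and every
    other record is chained through it.  ``n_missing`` is defined as the
    shortfall from the per-respondent quota, so the report identities hold
    even when a respondent has fewer rows than ``quota``.

    ``n_contacted`` / ``n_excluded_upstream`` let callers fold in respondents
    removed before any records exist (e.g. protocol exclusions).
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    by_resp: dict[str, list[RawSgRecord]] = {}
    for rec in records:
        by_resp.setdefault(rec.respondent_id, []).append(rec)

    n_seen = len(by_resp)
    if n_contacted is None:
        n_contacted = n_seen + n_excluded_upstream
        n_excluded = n_excluded_upstream
    else:
        # contacted respondents with no records at all were excluded upstream
        if n_contacted < n_seen:
            raise ValueError("n_contacted smaller than the respondents in the records")
        n_excluded = n_contacted - n_seen

    adjusted: list[AdjustedRecord] = []
    n_eligible = 0
    for rid in sorted(by_resp):
        recs = by_resp[rid]
        pits_recs = [r for r in recs if r.is_pits_question]
        if len(pits_recs) != 1 or pits_recs[0].sg is None:
            n_excluded += 1
            continue
        n_eligible += 1
        pits = truncate_pits_value(pits_recs[0].sg)
        adjusted.append(AdjustedRecord(rid, pits_recs[0].state, pits))
        for r in recs:
            if r.is_pits_question or r.sg is None:
                continue
            adjusted.append(AdjustedRecord(rid, r.state, adjust_sg(r.sg, pits)))

    n_expected = n_eligible * quota
    n_observed = len(adjusted)
    report = InclusionReport(
        n_respondents_contacted=n_contacted,
        n_excluded=n_excluded,
        n_eligible=n_eligible,
        n_expected_values=n_expected,
        n_missing=n_expected - n_observed,
        n_observed=n_observed,
    )
    return adjusted, report


# ---------------------------------------------------------------------------
# CSV interfaces: respondent_id,state,sg,is_pits (raw) / respondent_id,state,y


def read_raw_csv(
    path: str | Path, system: DescriptiveSystem = DEFAULT_SYSTEM
) -> list[RawSgRecord]:
    out: list[RawSgRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"respondent_id", "state", "sg", "is_pits"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"raw SG CSV must have columns {sorted(required)}")
        for row in reader:
            sg = row["sg"].strip()
            out.append(
                RawSgRecord(
                    respondent_id=row["respondent_id"],
                    state=parse_state_code(row["state"], system),
                    sg=float(sg) if sg else None,
                    is_pits_question=row["is_pits"].strip().lower() in ("1", "true", "yes"),
                )
            )
    return out


def write_raw_csv(path: str | Path, records: Sequence[RawSgRecord]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("respondent_id,state,sg,is_pits\n")
        for r in records:
            sg = "" if r.sg is None else format(r.sg, ".10g")
            fh.write(f"{r.respondent_id},{r.state.code},{sg},{int(r.is_pits_question)}\n")


def read_adjusted_csv(
    path: str | Path, system: DescriptiveSystem = DEFAULT_SYSTEM
) -> list[AdjustedRecord]:
    out: list[AdjustedRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"respondent_id", "state", "y"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"adjusted CSV must have columns {sorted(required)}")
        for row in reader:
            out.append(
                AdjustedRecord(
                    respondent_id=row["respondent_id"],
                    state=parse_state_code(row["state"], system),
                    y=float(row["y"]),
                )
            )
    return out


def write_adjusted_csv(path: str | Path, records: Sequence[AdjustedRecord]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("respondent_id,state,y\n")
        for r in records:
            fh.write(f"{r.respondent_id},{r.state.code},{format(r.y, '.10g')}\n")
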