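"""Observation windows and cohort eligibility.

Each user's timeline is anchored at their first pain record, :math:`t_0`.
A "month" is a 30-day block from that anchor.  The *predictor* window is
the first month, :math:`[t_0, t_0 + 30\\,\\text{d})`, and the *outcome*
window is the sixth month, :math:`[t_0 + 150\\,\\text{d}, t_0 +
180\\,\\text{d})`; both intervals are half-open so a record can never be
counted twice.  Eligibility for the prediction experiments requires at
least five records in *both* windows (two is the mathematical minimum for
a volatility score, five improves its reliability) and excludes users who
reported *other* as their gender.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Mapping, Sequence

from .records_io import PainRecord, UserProfile

MONTH_DAYS = 30
PREDICTOR_OFFSET_DAYS = (0, 30)
OUTCOME_OFFSET_DAYS = (150, 180)
MIN_RECORDS_PER_WINDOW = 5

__all__ = [
    "ObservationWindow",
    "WindowPair",
    "build_windows",
    "filter_eligible",
    "MONTH_DAYS",
    "MIN_RECORDS_PER_WINDOW",
]


@dataclass(frozen=True)
class ObservationWindow:
    """A half-open [start, end) slice of one user's record stream."""

    user_id: str
    role: str  # "predictor" | "outcome"
    start: object
    end: object
    records: tuple[PainRecord, ...]

    @property
    def n(self) -> int:
        return len(self.records)

    def ratings(self) -> tuple[int, ...]:
        return tuple(r.severity for r in self.records)


@dataclass(frozen=True)
class WindowPair:
    predictor: ObservationWindow
    outcome: ObservationWindow
    n_unassigned: int  # records falling in neither window (provenance)


def build_windows(records: Sequence[PainRecord]) -> dict[str, WindowPair]:
    """Assign each user's records to predictor/outcome windows.

    Records must cover at least one user; users lacking records inside a
    window simply get an empty window.  Records outside both windows are
    dropped from the windows but counted in ``n_unassigned``.
    """
    by_user: dict[str, list[PainRecord]] = {}
    for rec in records:
        by_user.setdefault(rec.user_id, []).append(rec)
    out: dict[str, WindowPair] = {}
    for uid, recs in by_user.items():
        recs = sorted(recs, key=lambda r: r.timestamp)
        t0 = recs[0].timestamp
        spans = {
            "predictor": (
                t0 + timedelta(days=PREDICTOR_OFFSET_DAYS[0]),
                t0 + timedelta(days=PREDICTOR_OFFSET_DAYS[1]),
            ),
            "outcome": (
                t0 + timedelta(days=OUTCOME_OFFSET_DAYS[0]),
                t0 + timedelta(days=OUTCOME_OFFSET_DAYS[1]),
            ),
        }
        windows = {}
        assigned = 0
        for role, (start, end) in spans.items():
            members = tuple(r for r in recs if start <= r.timestamp < end)
            assigned += len(members)
            windows[role] = ObservationWindow(uid, role, start, end, members)
        out[uid] = WindowPair(
            predictor=windows["predictor"],
            outcome=windows["outcome"],
            n_unassigned=len(recs) - assigned,
        )
    return out


def filter_eligible(
    users: Iterable[UserProfile],
    windows: Mapping[str, WindowPair],
    min_records: int = MIN_RECORDS_PER_WINDOW,
) -> list[str]:
    """Return user ids eligible for prediction, sorted by user id.

    A user qualifies with at least ``min_records`` records in the predictor
    window AND in the outcome window, and a gender other than ``other``.
    Users absent from ``windows`` (no records at all) are ineligible.
    """
    eligible = []
    for user in users:
        pair = windows.get(user.user_id)
        if pair is None or user.gender == "other":
            continue
        if pair.predictor.n >= min_records and pair.outcome.n >= min_records:
            eligible.append(user.user_id)
    return sorted(eligible)
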