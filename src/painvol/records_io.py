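"""Domain types and delimited-text I/O for user profiles and pain records.

Two plain-text exports drive the pipeline: a *users* file (one profile per
row) and a *records* file (one self-report event per row).  Both are
pipe-delimited with a semicolon inner delimiter for multi-valued fields —
commas are common inside free-text condition names, so neither delimiter may
appear inside a value and the writers enforce that.  The first line of each
file names the dialect version so readers can fail fast on foreign files.

The third format handled here is the feature-matrix export: an RFC-4180 CSV
with a ``user_id`` column, the 130 canonical predictor features and a
``label`` column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .vocab import (
    CONDITION_CATEGORIES,
    DEFAULT_VOCABULARIES,
    GENDERS,
    MEDICATION_ROLES,
)

FIELD_DELIM = "|"
INNER_DELIM = ";"
_PAIR_DELIM = ":"   # name:role / name:cat+cat inside one inner-delimited item
_CAT_DELIM = "+"

USERS_DIALECT = "# painvol-users v1 field-delim=| inner-delim=;"
RECORDS_DIALECT = "# painvol-records v1 field-delim=| inner-delim=;"

USER_COLUMNS = (
    "user_id", "gender", "age_at_first_record", "conditions",
    "condition_categories", "medications",
)
RECORD_COLUMNS = (
    "user_id", "timestamp", "severity", "locations", "symptoms",
    "characteristics", "environments", "aggravating_factors",
    "alleviating_factors", "ineffective_factors", "medications_used",
    "pain_type", "pain_duration",
)


@dataclass(frozen=True)
class Medication:
    """A profile medication with zero or more category tags."""

    name: str
    categories: tuple[str, ...] = ()


@dataclass(frozen=True)
class UserProfile:
    """Demographics and self-reported clinical profile for one app user.

    Unknown states are explicit: ``gender='unknown'`` and
    ``age_at_first_record=None`` are valid, representable values rather than
    absent fields.  Users with ``gender='other'`` are representable but are
    excluded downstream by the eligibility filter.
    """

    user_id: str
    gender: str = "unknown"
    age_at_first_record: int | None = None
    conditions: tuple[str, ...] = ()
    condition_categories: frozenset[str] = frozenset()
    medications: tuple[Medication, ...] = ()

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"invalid gender {self.gender!r}")
        age = self.age_at_first_record
        if age is not None and age < 0:
            raise ValueError(f"negative age {age}")
        bad = self.condition_categories - set(CONDITION_CATEGORIES)
        if bad:
            raise ValueError(f"unknown condition categories {sorted(bad)}")


@dataclass(frozen=True)
class PainRecord:
    """One self-report event.

    Severity (0–10 integer) is the only mandatory item; every multi-valued
    field may be empty.  Descriptor and factor tokens are validated against
    their vocabularies at construction.
    """

    user_id: str
    timestamp: datetime
    severity: int
    locations: frozenset[str] = frozenset()
    symptoms: frozenset[str] = frozenset()
    characteristics: frozenset[str] = frozenset()
    environments: frozenset[str] = frozenset()
    aggravating_factors: frozenset[str] = frozenset()
    alleviating_factors: frozenset[str] = frozenset()
    ineffective_factors: frozenset[str] = frozenset()
    medications_used: frozenset[tuple[str, str]] = frozenset()
    pain_type: str | None = None
    pain_duration: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.severity, int) or not 0 <= self.severity <= 10:
            raise ValueError(
                f"severity must be an integer in [0, 10], got {self.severity!r}"
            )
        for vocab_name in (
            "locations", "symptoms", "characteristics", "environments",
            "aggravating_factors", "alleviating_factors", "ineffective_factors",
        ):
            DEFAULT_VOCABULARIES[vocab_name].validate(getattr(self, vocab_name))
        for name, role in self.medications_used:
            if role not in MEDICATION_ROLES:
                raise ValueError(f"invalid medication role {role!r} for {name!r}")


def _check_value(value: str, line_no: int) -> str:
    if FIELD_DELIM in value or INNER_DELIM in value:
        raise ValueError(
            f"line {line_no}: value {value!r} contains a reserved delimiter"
        )
    return value


def _join_set(tokens: Iterable[str]) -> str:
    return INNER_DELIM.join(sorted(tokens))


def _split_set(text: str) -> frozenset[str]:
    return frozenset(t for t in text.split(INNER_DELIM) if t)


# ---------------------------------------------------------------------------
# users file


def write_users(users: Sequence[UserProfile], path: str | Path) -> None:
    lines = [USERS_DIALECT, FIELD_DELIM.join(USER_COLUMNS)]
    for i, u in enumerate(users, start=3):
        meds = INNER_DELIM.join(
            m.name + (_PAIR_DELIM + _CAT_DELIM.join(m.categories)
                      if m.categories else "")
            for m in u.medications
        )
        row = (
            u.user_id,
            u.gender,
            "" if u.age_at_first_record is None else str(u.age_at_first_record),
            INNER_DELIM.join(u.conditions),
            _join_set(u.condition_categories),
            meds,
        )
        for v in (u.user_id, u.gender, *u.conditions, *(m.name for m in u.medications)):
            _check_value(v, i)
        lines.append(FIELD_DELIM.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_users(path: str | Path) -> list[UserProfile]:
    """Parse a users file; unparseable gender/age map to unknown.

    Raises ``ValueError`` naming the line number for malformed rows and for
    duplicate user ids.  Row order is preserved.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# painvol-users"):
        raise ValueError(f"{path}: missing users dialect header")
    if len(lines) < 2 or tuple(lines[1].split(FIELD_DELIM)) != USER_COLUMNS:
        raise ValueError(f"{path}: line 2: unexpected column header")
    users: list[UserProfile] = []
    seen: set[str] = set()
    for line_no, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(FIELD_DELIM)
        if len(parts) != len(USER_COLUMNS):
            raise ValueError(
                f"line {line_no}: expected {len(USER_COLUMNS)} fields, "
                f"got {len(parts)}"
            )
        uid, gender, age_s, conds_s, cats_s, meds_s = parts
        if not uid:
            raise ValueError(f"line {line_no}: empty user_id")
        if uid in seen:
            raise ValueError(f"line {line_no}: duplicate user_id {uid!r}")
        seen.add(uid)
        if gender not in GENDERS:
            gender = "unknown"
        try:
            age: int | None = int(age_s)
            if age < 0:
                age = None
        except ValueError:
            age = None
        meds = []
        for item in meds_s.split(INNER_DELIM):
            if not item:
                continue
            name, _, cats = item.partition(_PAIR_DELIM)
            meds.append(
                Medication(name, tuple(c for c in cats.split(_CAT_DELIM) if c))
            )
        try:
            users.append(
                UserProfile(
                    user_id=uid,
                    gender=gender,
                    age_at_first_record=age,
                    conditions=tuple(c for c in conds_s.split(INNER_DELIM) if c),
                    condition_categories=_split_set(cats_s),
                    medications=tuple(meds),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    return users


# ---------------------------------------------------------------------------
# records file


def write_records(records: Sequence[PainRecord], path: str | Path) -> None:
    lines = [RECORDS_DIALECT, FIELD_DELIM.join(RECORD_COLUMNS)]
    for i, r in enumerate(records, start=3):
        _check_value(r.user_id, i)
        meds = INNER_DELIM.join(
            f"{name}{_PAIR_DELIM}{role}"
            for name, role in sorted(r.medications_used)
        )
        row = (
            r.user_id,
            r.timestamp.isoformat(),
            str(r.severity),
            _join_set(r.locations),
            _join_set(r.symptoms),
            _join_set(r.characteristics),
            _join_set(r.environments),
            _join_set(r.aggravating_factors),
            _join_set(r.alleviating_factors),
            _join_set(r.ineffective_factors),
            meds,
            r.pain_type or "",
            r.pain_duration or "",
        )
        lines.append(FIELD_DELIM.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_records(path: str | Path) -> list[PainRecord]:
    """Parse a records file, validating severities and vocabulary tokens.

    Records are returned sorted by ``(user_id, timestamp)``; ties on the
    timestamp keep file order (a stable sort) and trigger a warning, since
    the ordering of same-instant reports is otherwise ambiguous.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# painvol-records"):
        raise ValueError(f"{path}: missing records dialect header")
    if len(lines) < 2 or tuple(lines[1].split(FIELD_DELIM)) != RECORD_COLUMNS:
        raise ValueError(f"{path}: line 2: unexpected column header")
    records: list[PainRecord] = []
    for line_no, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(FIELD_DELIM)
        if len(parts) != len(RECORD_COLUMNS):
            raise ValueError(
                f"line {line_no}: expected {len(RECORD_COLUMNS)} fields, "
                f"got {len(parts)}"
            )
        (uid, ts_s, sev_s, loc_s, sym_s, chr_s, env_s, agg_s, alv_s, inf_s,
         med_s, ptype, pdur) = parts
        try:
            ts = datetime.fromisoformat(ts_s)
        except ValueError as exc:
            raise ValueError(f"line {line_no}: bad timestamp {ts_s!r}") from exc
        try:
            severity = int(sev_s)
        except ValueError as exc:
            raise ValueError(f"line {line_no}: bad severity {sev_s!r}") from exc
        meds = set()
        for item in med_s.split(INNER_DELIM):
            if not item:
                continue
            name, _, role = item.partition(_PAIR_DELIM)
            meds.add((name, role))
        try:
            records.append(
                PainRecord(
                    user_id=uid,
                    timestamp=ts,
                    severity=severity,
                    locations=_split_set(loc_s),
                    symptoms=_split_set(sym_s),
                    characteristics=_split_set(chr_s),
                    environments=_split_set(env_s),
                    aggravating_factors=_split_set(agg_s),
                    alleviating_factors=_split_set(alv_s),
                    ineffective_factors=_split_set(inf_s),
                    medications_used=frozenset(meds),
                    pain_type=ptype or None,
                    pain_duration=pdur or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    keys = [(r.user_id, r.timestamp) for r in records]
    if len(set(keys)) != len(keys):
        warnings.warn(
            "records with identical (user_id, timestamp) keep file order; "
            "their relative ordering is ambiguous",
            stacklevel=2,
        )
    order = sorted(range(len(records)), key=keys.__getitem__)
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# feature matrix


def write_feature_matrix(features, labels, path: str | Path) -> None:
    """Write feature vectors plus class labels as a CSV feature matrix.

    ``features`` is a sequence of objects exposing ``user_id`` and
    ``to_series()`` (the canonical 130-entry feature series); all vectors
    must share the same schema.  Floats are written with full ``repr``
    precision so a re-read reproduces the values bit-exactly.
    """
    features = list(features)
    labels = list(labels)
    if len(features) != len(labels):
        raise ValueError("features and labels differ in length")
    series = [fv.to_series() for fv in features]
    if series:
        ref = list(series[0].index)
        for fv, s in zip(features, series):
            if list(s.index) != ref:
                raise ValueError(
                    f"feature schema mismatch for user {fv.user_id!r}"
                )
        frame = pd.DataFrame(series)
    else:
        from .features import feature_names  # noqa: PLC0415 — avoid cycle at import

        frame = pd.DataFrame(columns=feature_names())
    frame.insert(0, "user_id", [fv.user_id for fv in features])
    frame["label"] = labels
    frame.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-matrix CSV back as a DataFrame indexed by user_id.

    Categorical columns are kept as strings even when their labels look
    numeric (e.g. the condition-count bins "1", "2", "3").
    """
    from .features import CATEGORICAL_FEATURES  # noqa: PLC0415 — avoid cycle

    dtypes: dict[str, type] = {"user_id": str}
    dtypes.update({c: str for c in CATEGORICAL_FEATURES})
    frame = pd.read_csv(path, dtype=dtypes, float_precision="round_trip")
    return frame.set_index("user_id")
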