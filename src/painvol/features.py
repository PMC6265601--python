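"""The canonical 130-feature predictor vector.

Every eligible user is summarised by 130 features computed from their
profile and their predictor-window (first month) records:

==============================  =====
block                           count
==============================  =====
gender (categorical)                1
age group (8 bins)                  1
number of conditions (5 bins)       1
condition-category flags            5
record entries (count, days)        2
severity (mean, SD, group)          3
trend change                        1
volatility (value, level)           2
descriptor flags                   64
factor flags                       43
medication-category flags           5
neuropathic pain flag               1
mental-health flag                  1
==============================  =====

Missing profile information maps to an explicit *unknown* category, never
to an error, so the feature count is 130 for every user including the
all-missing case.  Categoricals stay single columns here; one-hot
expansion happens at model-fit time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import ObservationWindow
from .records_io import PainRecord, UserProfile
from .vocab import (
    CONDITION_CATEGORIES,
    DEFAULT_VOCABULARIES,
    DESCRIPTOR_VOCABS,
    FACTOR_VOCABS,
    MEDICATION_CATEGORIES,
    MENTAL_HEALTH_AGGRAVATING,
    MENTAL_HEALTH_SYMPTOMS,
    NEUROPATHIC_AGGRAVATING,
    NEUROPATHIC_CHARACTERISTICS,
)
from .volatility import compute_volatility, compute_sd

__all__ = [
    "FeatureVector",
    "AGE_BINS",
    "N_CONDITION_BINS",
    "SEVERITY_GROUPS",
    "extract_features",
    "categorize_age",
    "categorize_severity",
    "compute_trend_change",
    "flag_neuropathic",
    "flag_mental_health",
    "count_flags",
    "feature_names",
    "feature_schema",
    "features_to_frame",
    "CATEGORICAL_FEATURES",
    "CONTINUOUS_FEATURES",
]

AGE_BINS = (
    "unknown", "(0,20]", "(20,30]", "(30,40]", "(40,50]", "(50,60]",
    "(60,70]", ">70",
)
N_CONDITION_BINS = ("unknown", "1", "2", "3", ">3")
SEVERITY_GROUPS = ("mild", "moderate", "severe")

_FIELD_PREFIX = {
    "locations": "loc",
    "symptoms": "sym",
    "characteristics": "chr",
    "environments": "env",
    "aggravating_factors": "agg",
    "alleviating_factors": "alv",
    "ineffective_factors": "inf",
}

#: Canonical names of the three single-column categoricals plus the
#: severity grouping; everything else is numeric.
CATEGORICAL_FEATURES = ("gender", "age_group", "n_conditions_group",
                        "severity_group")
CONTINUOUS_FEATURES = ("n_records", "n_active_days", "severity_mean",
                       "severity_sd", "trend_change", "predictor_volatility")


def _slug(token: str) -> str:
    return token.replace(" ", "_").replace("-", "_")


def _flag_names() -> dict[str, list[str]]:
    names: dict[str, list[str]] = {"descriptor": [], "factor": []}
    for vname in DESCRIPTOR_VOCABS:
        prefix = _FIELD_PREFIX[vname]
        names["descriptor"] += [
            f"{prefix}_{_slug(t)}" for t in DEFAULT_VOCABULARIES[vname].members
        ]
    for vname in FACTOR_VOCABS:
        prefix = _FIELD_PREFIX[vname]
        names["factor"] += [
            f"{prefix}_{_slug(t)}" for t in DEFAULT_VOCABULARIES[vname].members
        ]
    return names


def feature_names() -> list[str]:
    """The canonical, stable order of the 130 feature columns."""
    flags = _flag_names()
    return (
        ["gender", "age_group", "n_conditions_group"]
        + [f"cond_{_slug(c)}" for c in CONDITION_CATEGORIES]
        + ["n_records", "n_active_days"]
        + ["severity_mean", "severity_sd", "severity_group"]
        + ["trend_change"]
        + ["predictor_volatility", "predictor_volatility_level"]
        + flags["descriptor"]
        + flags["factor"]
        + [f"med_{_slug(c)}" for c in MEDICATION_CATEGORIES]
        + ["neuropathic_pain", "mental_health"]
    )


def feature_schema() -> pd.DataFrame:
    """(name, block, type) for every canonical feature column."""
    flags = _flag_names()
    rows = []

    def add(names: Iterable[str], block: str, ftype: str) -> None:
        rows.extend({"name": n, "block": block, "type": ftype} for n in names)

    add(["gender"], "demographics", "categorical")
    add(["age_group"], "demographics", "categorical")
    add(["n_conditions_group"], "conditions", "categorical")
    add([f"cond_{_slug(c)}" for c in CONDITION_CATEGORIES], "conditions", "binary")
    add(["n_records", "n_active_days"], "app_usage", "count")
    add(["severity_mean", "severity_sd"], "severity", "continuous")
    add(["severity_group"], "severity", "categorical")
    add(["trend_change"], "trend", "continuous")
    add(["predictor_volatility"], "volatility", "continuous")
    add(["predictor_volatility_level"], "volatility", "binary")
    add(flags["descriptor"], "descriptors", "binary")
    add(flags["factor"], "factors", "binary")
    add([f"med_{_slug(c)}" for c in MEDICATION_CATEGORIES], "medications", "binary")
    add(["neuropathic_pain"], "clinical", "binary")
    add(["mental_health"], "clinical", "binary")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureVector:
    """The 130 canonical predictor features for one eligible user."""

    user_id: str
    gender_cat: str
    age_cat: str
    n_conditions_cat: str
    condition_flags: tuple[int, ...]     # 5
    n_records: int
    n_active_days: int
    severity_mean: float
    severity_sd: float
    severity_group: str
    trend_change: float
    predictor_volatility: float
    predictor_volatility_level: int
    descriptor_flags: tuple[int, ...]    # 64
    factor_flags: tuple[int, ...]        # 43
    medication_flags: tuple[int, ...]    # 5
    neuropathic_flag: int
    mental_health_flag: int

    def __post_init__(self) -> None:
        for name, expected in (
            ("condition_flags", 5), ("descriptor_flags", 64),
            ("factor_flags", 43), ("medication_flags", 5),
        ):
            if len(getattr(self, name)) != expected:
                raise ValueError(f"{name} must have {expected} entries")

    def to_series(self) -> pd.Series:
        values = (
            [self.gender_cat, self.age_cat, self.n_conditions_cat]
            + list(self.condition_flags)
            + [self.n_records, self.n_active_days]
            + [self.severity_mean, self.severity_sd, self.severity_group]
            + [self.trend_change]
            + [self.predictor_volatility, self.predictor_volatility_level]
            + list(self.descriptor_flags)
            + list(self.factor_flags)
            + list(self.medication_flags)
            + [self.neuropathic_flag, self.mental_health_flag]
        )
        return pd.Series(values, index=feature_names(), name=self.user_id)


def categorize_age(age: int | None) -> str:
    """Map years at first record to one of 8 bins; lower-exclusive edges."""
    if age is None:
        return "unknown"
    if age <= 0:
        raise ValueError(f"known age must be positive, got {age}")
    for upper, label in zip((20, 30, 40, 50, 60, 70), AGE_BINS[1:7]):
        if age <= upper:
            return label
    return ">70"


def categorize_n_conditions(n: int) -> str:
    """Bin the number of self-reported conditions; 0 reported = unknown."""
    if n <= 0:
        return "unknown"
    if n <= 3:
        return str(n)
    return ">3"


def categorize_severity(mean_rating: float) -> str:
    """mild (< 4), moderate (4 to 7 inclusive), severe (> 7)."""
    if mean_rating < 4:
        return "mild"
    if mean_rating <= 7:
        return "moderate"
    return "severe"


def compute_trend_change(records: Sequence[PainRecord]) -> float:
    """End-minus-start difference of an OLS trend line through the ratings.

    The regressor is elapsed days since the first record in the window
    (irregular sampling makes index-based slopes scale-dependent), and the
    returned value is slope × elapsed span, i.e. the fitted rise over the
    window.  Returns 0 when all timestamps coincide.
    """
    if len(records) < 2:
        return 0.0
    t0 = min(r.timestamp for r in records)
    x = np.array(
        [(r.timestamp - t0).total_seconds() / 86400.0 for r in records]
    )
    y = np.array([r.severity for r in records], dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return 0.0
    slope = np.polyfit(x, y, 1)[0]
    return float(slope * span)


def flag_neuropathic(records: Sequence[PainRecord]) -> int:
    """1 iff any single record carries >= 2 of the five neuropathic items.

    The qualifying items are four pain characteristics plus one aggravating
    factor, counted within the same record — qualifying items spread across
    different records do not fire the flag.
    """
    for r in records:
        count = len(r.characteristics & set(NEUROPATHIC_CHARACTERISTICS))
        count += len(r.aggravating_factors & set(NEUROPATHIC_AGGRAVATING))
        if count >= 2:
            return 1
    return 0


def flag_mental_health(records: Sequence[PainRecord]) -> int:
    """1 iff any record has an anxiety/depression symptom or a negative
    mood/stress aggravating factor."""
    for r in records:
        if r.symptoms & set(MENTAL_HEALTH_SYMPTOMS):
            return 1
        if r.aggravating_factors & set(MENTAL_HEALTH_AGGRAVATING):
            return 1
    return 0


def count_flags(records: Sequence[PainRecord], vocabulary_name: str) -> tuple[int, ...]:
    """Window-level presence flags, one per token, in vocabulary order."""
    vocab = DEFAULT_VOCABULARIES[vocabulary_name]
    present: set[str] = set()
    for r in records:
        present |= getattr(r, vocabulary_name)
    return tuple(1 if tok in present else 0 for tok in vocab.members)


def _medication_flags(
    profile: UserProfile, records: Sequence[PainRecord]
) -> tuple[int, ...]:
    # category lookup via the profile's medication list; a flag fires only
    # when a categorised medication is attached to a record in the window
    cats_by_name = {m.name: set(m.categories) for m in profile.medications}
    present: set[str] = set()
    for r in records:
        for name, _role in r.medications_used:
            present |= cats_by_name.get(name, set())
    return tuple(1 if c in present else 0 for c in MEDICATION_CATEGORIES)


def extract_features(
    profile: UserProfile,
    window: ObservationWindow,
    threshold: float,
) -> FeatureVector:
    """Build the 130-feature vector from a profile and a predictor window.

    ``threshold`` is the global volatility threshold from the clustering
    step; it determines ``predictor_volatility_level`` (no window-local
    re-clustering).  A pure function of its inputs.
    """
    records = window.records
    if not records:
        raise ValueError(
            f"empty predictor window for user {profile.user_id!r}; "
            "eligibility should be enforced upstream"
        )
    ratings = [r.severity for r in records]
    vol = compute_volatility(ratings) if len(ratings) >= 2 else 0.0
    sd = compute_sd(ratings) if len(ratings) >= 2 else 0.0
    mean = float(np.mean(ratings))
    descriptor_flags = tuple(
        f for vname in DESCRIPTOR_VOCABS for f in count_flags(records, vname)
    )
    factor_flags = tuple(
        f for vname in FACTOR_VOCABS for f in count_flags(records, vname)
    )
    return FeatureVector(
        user_id=profile.user_id,
        gender_cat=profile.gender,
        age_cat=categorize_age(profile.age_at_first_record),
        n_conditions_cat=categorize_n_conditions(len(profile.conditions)),
        condition_flags=tuple(
            1 if c in profile.condition_categories else 0
            for c in CONDITION_CATEGORIES
        ),
        n_records=len(records),
        n_active_days=len({r.timestamp.date() for r in records}),
        severity_mean=mean,
        severity_sd=sd,
        severity_group=categorize_severity(mean),
        trend_change=compute_trend_change(records),
        predictor_volatility=vol,
        predictor_volatility_level=1 if vol > threshold else 0,
        descriptor_flags=descriptor_flags,
        factor_flags=factor_flags,
        medication_flags=_medication_flags(profile, records),
        neuropathic_flag=flag_neuropathic(records),
        mental_health_flag=flag_mental_health(records),
    )


def features_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame indexed by user_id."""
    if not vectors:
        return pd.DataFrame(columns=feature_names())
    frame = pd.DataFrame([v.to_series() for v in vectors])
    frame.index.name = "user_id"
    return frame
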