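"""Synthetic pain-app cohorts with a known latent volatility structure.

No public pain-app export exists, so every downstream stage is exercised on
generated data whose ground truth is known.  The generator emulates:

* per-user record streams over six 30-day months, anchored at the user's
  first record;
* integer severity ratings 0–10 produced by a discretised mean-reverting
  (AR(1)-style) walk whose innovation scale is calibrated per latent regime
  so the realised mean absolute successive difference concentrates near a
  target (defaults 0.8 for the *low* regime and 3.0 for the *high* regime,
  well separated around a mid-1 threshold);
* multi-valued descriptor/factor fields drawn from the fixed vocabularies;
* latent low/high volatility regimes for month 1 and month 6, with a
  plantable month-1 → month-6 signal; and
* the characteristic missingness of self-reported profiles (25% gender
  unknown, 31% age unknown, 2% of users reporting no descriptors, 8%
  reporting no factors).

The planted signal has two routes, both scaled by ``signal_strength``:
the month-1 regime agrees with the month-6 regime with probability
``0.5 + signal_strength * (regime_persistence - 0.5)`` (so month-1
volatility — itself an extracted feature — is predictive), and five
designated descriptor tokens appear in month 1 with probability shifted up
for month-6-high users and down for month-6-low users.  At
``signal_strength = 0`` both routes collapse to independence and every
month-1 feature is uninformative about the month-6 class: the null
configuration.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy.signal import lfilter

from .records_io import Medication, PainRecord, UserProfile
from .vocab import (
    DEFAULT_VOCABULARIES,
    MEDICATION_ROLES,
)

__all__ = [
    "RecordCountDistribution",
    "GeneratorConfig",
    "StepModel",
    "calibrate_step_scale",
    "generate_cohort",
    "SIGNAL_TOKENS",
]

#: Five designated descriptor tokens carrying the planted month-1 signal:
#: (field, token).  Four of them also drive the mental-health screening
#: flag, which is a realistic correlate of volatile pain.
SIGNAL_TOKENS = (
    ("symptoms", "anxiety"),
    ("symptoms", "depression"),
    ("aggravating_factors", "stress"),
    ("aggravating_factors", "negative mood"),
    ("characteristics", "burning"),
)

# Synthetic stand-ins for the app's proprietary condition and medication
# lists: free-text name -> category tags used by the feature extractor.
CONDITION_POOL: tuple[tuple[str, str | None], ...] = (
    ("fibromyalgia", "fibromyalgia"),
    ("chronic widespread pain", "fibromyalgia"),
    ("migraine", "headaches"),
    ("tension headache", "headaches"),
    ("cluster headache", "headaches"),
    ("chronic low back pain", "back pain"),
    ("sciatica", "back pain"),
    ("degenerative disc disease", "back pain"),
    ("osteoarthritis", "arthritis"),
    ("rheumatoid arthritis", "arthritis"),
    ("psoriatic arthritis", "arthritis"),
    ("major depressive disorder", "depression-anxiety"),
    ("generalized anxiety disorder", "depression-anxiety"),
    ("neck pain", None),
    ("pelvic pain", None),
    ("post-surgical pain", None),
    ("carpal tunnel syndrome", None),
    ("endometriosis", None),
)

MEDICATION_POOL: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("morphine", ("opioids",)),
    ("oxycodone", ("opioids",)),
    ("tramadol", ("opioids",)),
    ("amitriptyline", ("tricyclic antidepressants",)),
    ("nortriptyline", ("tricyclic antidepressants",)),
    ("gabapentin", ("anticonvulsants",)),
    ("pregabalin", ("anticonvulsants",)),
    ("nabilone", ("cannabinoids",)),
    ("medical cannabis", ("cannabinoids",)),
    ("duloxetine", ("SNRIs",)),
    ("venlafaxine", ("SNRIs",)),
    ("ibuprofen", ()),
    ("acetaminophen", ()),
    ("naproxen", ()),
)

PAIN_TYPES = ("chronic", "acute", "intermittent")
PAIN_DURATIONS = (
    "less than 1 hour", "1 to 12 hours", "12 to 24 hours", "more than 24 hours",
)


@dataclass(frozen=True)
class RecordCountDistribution:
    """Poisson record count per user-month with optional minimum enforcement."""

    mean: float = 12.0
    minimum: int = 5
    enforce_minimum: bool = True

    def sample(self, rng: np.random.Generator) -> int:
        n = int(rng.poisson(self.mean))
        if self.enforce_minimum:
            n = max(n, self.minimum)
        return n


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; identical (config, seed) gives
    identical output."""

    n_users: int = 800
    seed: int = 0
    p_high_outcome: float = 171 / 782
    regime_persistence: float = 0.85
    low_state_mean_abs_step: float = 0.8
    high_state_mean_abs_step: float = 3.0
    records_per_month: RecordCountDistribution = field(
        default_factory=RecordCountDistribution
    )
    p_gender_unknown: float = 0.25
    p_gender_other: float = 0.0
    p_age_unknown: float = 0.31
    p_no_descriptors: float = 0.02
    p_no_factors: float = 0.08
    signal_strength: float = 0.8
    n_months: int = 6

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        for name in (
            "p_high_outcome", "regime_persistence", "p_gender_unknown",
            "p_gender_other", "p_age_unknown", "p_no_descriptors",
            "p_no_factors",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if not self.low_state_mean_abs_step < self.high_state_mean_abs_step:
            raise ValueError("low regime step target must be below the high one")
        if self.n_months < 6:
            raise ValueError("need at least 6 months to cover both windows")


@dataclass(frozen=True)
class StepModel:
    """Severity-step dynamics achieving a target mean absolute step.

    ``kind='ar'`` is the discretised mean-reverting walk
    ``x' = mu + ar_coeff * (x - mu) + sigma * eps`` with the emitted rating
    ``clip(round(x'), 0, 10)``.  ``kind='constant'`` emits the baseline
    forever (target 0) and ``kind='alternating'`` emits 0/10 alternation —
    the only pattern reaching a mean absolute step of 10.
    """

    kind: str  # "ar" | "constant" | "alternating"
    ar_coeff: float = 0.0
    sigma: float = 0.0


_CAL_N_STEPS = 100_000
_CAL_MU = 5.0
_CAL_SEED = 987_654_321  # internal; calibration is independent of cohort seeds
_BURN_IN = 60            # steps discarded so every path starts stationary


def _realized_mean_abs_step(
    ar_coeff: float, sigma: float, n: int = _CAL_N_STEPS, mu: float = _CAL_MU,
    seed: int = _CAL_SEED,
) -> float:
    eps = np.random.default_rng(seed).standard_normal(n + _BURN_IN)
    x = lfilter([1.0], [1.0, -ar_coeff], sigma * eps)[_BURN_IN:] + mu
    r = np.clip(np.round(x), 0.0, 10.0)
    return float(np.abs(np.diff(r)).mean())


@functools.lru_cache(maxsize=32)
def calibrate_step_scale(target_mean_abs_step: float) -> StepModel:
    """Find step dynamics whose realised mean absolute step matches a target.

    For targets in (0, 10) the AR coefficient is picked from a coarse
    ladder ordered by preference for weak persistence — near-independent
    steps concentrate the realised month-level V most tightly, while
    strong (anti-)persistence inflates its dispersion; targets above ~5
    are reachable only with anti-persistent dynamics on a clipped 0–10
    scale.  The innovation scale is then bisected until a 100 000-step
    stationary simulation lands within 5% of the target after integer
    clipping.  Target 0 yields the constant path; target 10 the
    degenerate alternating-extremes path; targets above 10 are
    unattainable and raise ``ValueError``.
    """
    t = float(target_mean_abs_step)
    if t < 0:
        raise ValueError("target must be non-negative")
    if t > 10:
        raise ValueError("mean absolute step above 10 is unattainable on 0-10")
    if t == 0:
        return StepModel("constant")
    if t == 10:
        return StepModel("alternating")
    for a in (0.0, 0.3, -0.3, 0.6, -0.6, -0.85, -0.97):
        hi = 80.0
        if _realized_mean_abs_step(a, hi) < t:
            continue
        lo = 0.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if _realized_mean_abs_step(a, mid) < t:
                lo = mid
            else:
                hi = mid
        sigma = (lo + hi) / 2.0
        if abs(_realized_mean_abs_step(a, sigma) - t) <= 0.05 * t:
            return StepModel("ar", ar_coeff=a, sigma=sigma)
    raise RuntimeError(f"calibration failed for target {t}")  # pragma: no cover


def _severity_path(
    model: StepModel, n: int, mu: float, rng: np.random.Generator
) -> np.ndarray:
    if model.kind == "constant":
        return np.full(n, int(np.clip(round(mu), 0, 10)), dtype=int)
    if model.kind == "alternating":
        out = np.zeros(n, dtype=int)
        out[1::2] = 10
        return out
    eps = rng.standard_normal(n + _BURN_IN)
    x = lfilter([1.0], [1.0, -model.ar_coeff], model.sigma * eps)[_BURN_IN:] + mu
    return np.clip(np.round(x), 0, 10).astype(int)


def _sample_tokens(
    rng: np.random.Generator, pool: tuple[str, ...], low: int, high: int
) -> set[str]:
    # partial Fisher-Yates with scalar draws; ~10x faster than rng.choice
    # on the small pools used here
    n = len(pool)
    k = low + int(rng.random() * (high - low + 1))
    if k <= 0 or n == 0:
        return set()
    k = min(k, n)
    idx = list(range(n))
    out = set()
    for i in range(k):
        j = i + int(rng.random() * (n - i))
        idx[i], idx[j] = idx[j], idx[i]
        out.add(pool[idx[i]])
    return out


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[UserProfile], list[PainRecord], list[str]]:
    """Generate profiles, six months of pain records and true month-6 states.

    Returns ``(profiles, records, states)`` with ``states[i]`` in
    ``{"low", "high"}`` giving the latent month-6 volatility regime of
    ``profiles[i]``.  Records are returned sorted by (user_id, timestamp).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    models = {
        "low": calibrate_step_scale(cfg.low_state_mean_abs_step),
        "high": calibrate_step_scale(cfg.high_state_mean_abs_step),
    }
    vocab = {name: v.members for name, v in DEFAULT_VOCABULARIES.items()}
    eff_persistence = 0.5 + cfg.signal_strength * (cfg.regime_persistence - 0.5)
    base_date = datetime(2023, 1, 1, 8, 0)

    profiles: list[UserProfile] = []
    records: list[PainRecord] = []
    states: list[str] = []

    for u in range(cfg.n_users):
        uid = f"u{u:05d}"
        state6 = "high" if rng.random() < cfg.p_high_outcome else "low"
        same = rng.random() < eff_persistence
        state1 = state6 if same else ("low" if state6 == "high" else "high")

        # ---- profile -----------------------------------------------------
        g = rng.random()
        if g < cfg.p_gender_unknown:
            gender = "unknown"
        elif g < cfg.p_gender_unknown + cfg.p_gender_other:
            gender = "other"
        else:
            gender = "female" if rng.random() < 0.62 else "male"
        if rng.random() < cfg.p_age_unknown:
            age: int | None = None
        else:
            age = int(np.clip(round(rng.normal(46.0, 14.0)), 18, 85))
        n_cond = int(rng.poisson(1.5))
        cond_idx = rng.choice(
            len(CONDITION_POOL), size=min(n_cond, len(CONDITION_POOL)),
            replace=False,
        )
        conditions = tuple(CONDITION_POOL[i][0] for i in cond_idx)
        cond_cats = frozenset(
            CONDITION_POOL[i][1] for i in cond_idx if CONDITION_POOL[i][1]
        )
        n_meds = int(rng.integers(0, 4))
        med_idx = rng.choice(len(MEDICATION_POOL), size=n_meds, replace=False)
        meds = tuple(
            Medication(MEDICATION_POOL[i][0], MEDICATION_POOL[i][1])
            for i in med_idx
        )
        profiles.append(
            UserProfile(
                user_id=uid, gender=gender, age_at_first_record=age,
                conditions=conditions, condition_categories=cond_cats,
                medications=meds,
            )
        )
        states.append(state6)

        # ---- record stream ----------------------------------------------
        no_desc = rng.random() < cfg.p_no_descriptors
        no_fact = rng.random() < cfg.p_no_factors
        t0 = base_date + timedelta(days=int(rng.integers(0, 365)))
        mu = float(rng.integers(3, 8))
        # per-user preferred token subsets (users report habitual items)
        pref = {
            "locations": tuple(_sample_tokens(rng, vocab["locations"], 3, 4)),
            "symptoms": tuple(_sample_tokens(rng, vocab["symptoms"], 2, 4)),
            "characteristics": tuple(
                _sample_tokens(rng, vocab["characteristics"], 2, 3)
            ),
            "environments": tuple(
                _sample_tokens(rng, vocab["environments"], 2, 3)
            ),
            "aggravating_factors": tuple(
                _sample_tokens(rng, vocab["aggravating_factors"], 2, 4)
            ),
            "alleviating_factors": tuple(
                _sample_tokens(rng, vocab["alleviating_factors"], 2, 4)
            ),
            "ineffective_factors": tuple(
                _sample_tokens(rng, vocab["ineffective_factors"], 1, 3)
            ),
        }

        month_counts = [
            cfg.records_per_month.sample(rng) for _ in range(cfg.n_months)
        ]
        n_total = sum(month_counts)
        regimes = np.empty(n_total, dtype=object)
        pos = 0
        timestamps: list[datetime] = []
        for m, n_m in enumerate(month_counts):
            regime = state6 if m == cfg.n_months - 1 else state1
            regimes[pos:pos + n_m] = regime
            days = rng.integers(0, 30, size=n_m)
            minutes = rng.integers(8 * 60, 22 * 60, size=n_m)
            month_ts = sorted(
                t0 + timedelta(days=int(m * 30 + days[j]),
                               minutes=int(minutes[j]))
                for j in range(n_m)
            )
            timestamps.extend(month_ts)
            pos += n_m
        timestamps[0] = t0  # anchor: first record defines the user's t0
        # severities: one continuous walk, the regime choosing the step model
        sev = np.empty(n_total, dtype=int)
        start = 0
        for regime, n_block in _runs(regimes):
            sev[start:start + n_block] = _severity_path(
                models[regime], n_block, mu, rng
            )
            start += n_block

        # designated month-1 signal flags, shifted by month-6 state
        delta = 0.3 * cfg.signal_strength
        p_tok = min(0.95, max(0.05, 0.5 + (delta if state6 == "high" else -delta)))
        n_month1 = month_counts[0]
        planted: dict[int, list[tuple[str, str]]] = {}
        for fld, tok in SIGNAL_TOKENS:
            if n_month1 == 0 or rng.random() >= p_tok:
                continue
            target = int(rng.integers(0, n_month1))
            planted.setdefault(target, []).append((fld, tok))

        for i in range(n_total):
            fields: dict[str, set[str]] = {}
            if no_desc:
                for name in ("locations", "symptoms", "characteristics",
                             "environments"):
                    fields[name] = set()
            else:
                fields["locations"] = _sample_tokens(rng, pref["locations"], 1, 2)
                fields["symptoms"] = _sample_tokens(rng, pref["symptoms"], 0, 2)
                fields["characteristics"] = _sample_tokens(
                    rng, pref["characteristics"], 1, 2
                )
                fields["environments"] = _sample_tokens(
                    rng, pref["environments"], 0, 1
                )
            if no_fact:
                for name in ("aggravating_factors", "alleviating_factors",
                             "ineffective_factors"):
                    fields[name] = set()
            else:
                fields["aggravating_factors"] = _sample_tokens(
                    rng, pref["aggravating_factors"], 0, 2
                )
                fields["alleviating_factors"] = _sample_tokens(
                    rng, pref["alleviating_factors"], 0, 2
                )
                fields["ineffective_factors"] = _sample_tokens(
                    rng, pref["ineffective_factors"], 0, 1
                )
            for fld, tok in planted.get(i, ()):
                blocked = (no_desc and fld in ("symptoms", "characteristics")) \
                    or (no_fact and fld == "aggravating_factors")
                if not blocked:
                    fields[fld].add(tok)
            meds_used: set[tuple[str, str]] = set()
            if meds and rng.random() < 0.5:
                med = meds[int(rng.integers(0, len(meds)))]
                role = MEDICATION_ROLES[int(rng.integers(0, len(MEDICATION_ROLES)))]
                meds_used.add((med.name, role))
            records.append(
                PainRecord(
                    user_id=uid,
                    timestamp=timestamps[i],
                    severity=int(sev[i]),
                    locations=frozenset(fields["locations"]),
                    symptoms=frozenset(fields["symptoms"]),
                    characteristics=frozenset(fields["characteristics"]),
                    environments=frozenset(fields["environments"]),
                    aggravating_factors=frozenset(fields["aggravating_factors"]),
                    alleviating_factors=frozenset(fields["alleviating_factors"]),
                    ineffective_factors=frozenset(fields["ineffective_factors"]),
                    medications_used=frozenset(meds_used),
                    pain_type=(
                        PAIN_TYPES[int(rng.integers(0, len(PAIN_TYPES)))]
                        if rng.random() < 0.7 else None
                    ),
                    pain_duration=(
                        PAIN_DURATIONS[int(rng.integers(0, len(PAIN_DURATIONS)))]
                        if rng.random() < 0.5 else None
                    ),
                )
            )

    records.sort(key=lambda r: (r.user_id, r.timestamp))
    return profiles, records, states


def _runs(values: np.ndarray):
    """Yield (value, run_length) for consecutive equal entries."""
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            yield values[start], i - start
            start = i


def null_config(**overrides) -> GeneratorConfig:
    """A convenience config with no feature→outcome signal planted."""
    overrides.setdefault("signal_strength", 0.0)
    return GeneratorConfig(**overrides)
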