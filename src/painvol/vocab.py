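"""Controlled vocabularies for pain-record descriptor and factor fields.

Pain-tracking apps present fixed pick-lists for the optional items of a pain
record.  The cardinalities here are structural and fixed — 24 pain locations,
20 associated symptoms, 13 pain characteristics and 7 environments (64
descriptor tokens), plus 15 aggravating, 14 alleviating and 14 ineffective
factors (43 factor tokens) — because they define the width of the flag blocks
in the predictor feature schema.  The token *names* shipped here are a
synthetic default set with those cardinalities; the real app's lists are
proprietary, so deployments against real exports should supply their own
token names via :func:`load_vocabularies`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "Vocabulary",
    "DEFAULT_VOCABULARIES",
    "EXPECTED_SIZES",
    "DESCRIPTOR_VOCABS",
    "FACTOR_VOCABS",
    "MEDICATION_CATEGORIES",
    "CONDITION_CATEGORIES",
    "MEDICATION_ROLES",
    "GENDERS",
    "NEUROPATHIC_CHARACTERISTICS",
    "NEUROPATHIC_AGGRAVATING",
    "MENTAL_HEALTH_SYMPTOMS",
    "MENTAL_HEALTH_AGGRAVATING",
    "load_vocabularies",
]

#: Required member counts per vocabulary; member order is canonical and
#: defines feature-column order downstream.
EXPECTED_SIZES = {
    "locations": 24,
    "symptoms": 20,
    "characteristics": 13,
    "environments": 7,
    "aggravating_factors": 15,
    "alleviating_factors": 14,
    "ineffective_factors": 14,
}

#: Vocabularies whose union forms the 64 descriptor flags.
DESCRIPTOR_VOCABS = ("locations", "symptoms", "characteristics", "environments")
#: Vocabularies whose union forms the 43 factor flags.
FACTOR_VOCABS = ("aggravating_factors", "alleviating_factors", "ineffective_factors")


@dataclass(frozen=True)
class Vocabulary:
    """An ordered, fixed-size token list for one multi-valued record field."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"vocabulary {self.name!r} has duplicate tokens")
        expected = EXPECTED_SIZES.get(self.name)
        if expected is not None and len(self.members) != expected:
            raise ValueError(
                f"vocabulary {self.name!r} must have {expected} tokens, "
                f"got {len(self.members)}"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, token: str) -> bool:
        return token in self.members

    def validate(self, tokens) -> None:
        for tok in tokens:
            if tok not in self.members:
                raise ValueError(
                    f"token {tok!r} is not in the {self.name!r} vocabulary"
                )


_DEFAULT_TOKENS = {
    "locations": (
        "head", "face", "jaw", "neck", "left shoulder", "right shoulder",
        "upper arm", "elbow", "forearm", "wrist", "hand", "chest",
        "upper back", "lower back", "abdomen", "pelvis", "hip", "buttock",
        "thigh", "knee", "lower leg", "ankle", "foot", "toes",
    ),
    "symptoms": (
        "anxiety", "depression", "dizziness", "fever", "fatigue", "nausea",
        "vomiting", "insomnia", "poor appetite", "weakness", "stiffness",
        "swelling", "sweating", "chills", "irritability",
        "poor concentration", "memory problems", "restlessness",
        "shortness of breath", "palpitations",
    ),
    "characteristics": (
        "aching", "burning", "cramping", "dull", "electric shocks",
        "numbness", "pins and needles or tingling", "pressure", "sharp",
        "shooting", "stabbing", "tender", "throbbing",
    ),
    "environments": (
        "home", "work", "school", "outdoors", "vehicle", "public place",
        "bed",
    ),
    "aggravating_factors": (
        "sitting", "standing", "walking", "exercise", "lifting", "bending",
        "driving", "working", "stress", "negative mood",
        "light touch or clothing", "cold weather", "hot weather", "noise",
        "bright light",
    ),
    "alleviating_factors": (
        "rest", "sleep", "medication", "heat", "ice", "stretching",
        "massage", "gentle exercise", "distraction", "meditation",
        "walking", "lying down", "music", "warm bath",
    ),
    "ineffective_factors": (
        "rest", "sleep", "medication", "heat", "ice", "stretching",
        "massage", "gentle exercise", "distraction", "meditation",
        "walking", "lying down", "music", "warm bath",
    ),
}

DEFAULT_VOCABULARIES: dict[str, Vocabulary] = {
    name: Vocabulary(name, members) for name, members in _DEFAULT_TOKENS.items()
}

#: The five medication categories mapped from the app's medication list.
MEDICATION_CATEGORIES = (
    "opioids",
    "tricyclic antidepressants",
    "anticonvulsants",
    "cannabinoids",
    "SNRIs",
)

#: The five pain-condition categories mapped from free-text conditions.
CONDITION_CATEGORIES = (
    "fibromyalgia",
    "headaches",
    "back pain",
    "arthritis",
    "depression-anxiety",
)

#: Role a profile medication may take when attached to a pain record.
MEDICATION_ROLES = ("aggravating", "effective", "ineffective")

GENDERS = ("male", "female", "other", "unknown")

# Clinical screening rules evaluated per record in the feature extractor.
# Neuropathic pain: >=2 of these five items within a single record.
NEUROPATHIC_CHARACTERISTICS = (
    "pins and needles or tingling",
    "burning",
    "numbness",
    "electric shocks",
)
NEUROPATHIC_AGGRAVATING = ("light touch or clothing",)
# Mental-health involvement: any one of these in any record.
MENTAL_HEALTH_SYMPTOMS = ("anxiety", "depression")
MENTAL_HEALTH_AGGRAVATING = ("negative mood", "stress")


def load_vocabularies(path: str | Path) -> dict[str, Vocabulary]:
    """Load replacement vocabularies from a YAML mapping of name -> token list.

    Cardinalities are enforced: each list must match :data:`EXPECTED_SIZES`.
    Names not present in the file fall back to the synthetic defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    vocabs = dict(DEFAULT_VOCABULARIES)
    for name, members in raw.items():
        if name not in EXPECTED_SIZES:
            raise ValueError(f"unknown vocabulary name {name!r}")
        vocabs[name] = Vocabulary(name, tuple(str(m) for m in members))
    return vocabs
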