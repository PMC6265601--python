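"""End-to-end glue: records -> windows -> volatility labels -> features.

Convenience composition of the library modules used by the command-line
interface, the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import build_windows, filter_eligible
from .features import extract_features, features_to_frame
from .records_io import PainRecord, UserProfile
from .volatility import (
    VolatilityClassification,
    compute_volatility,
    derive_threshold,
)

__all__ = ["Dataset", "prepare_dataset"]


@dataclass(frozen=True)
class Dataset:
    """Model-ready features and outcome labels for the eligible cohort."""

    X: pd.DataFrame                      # canonical 130 columns, user_id index
    y: np.ndarray                        # outcome-window low/high labels
    classification: VolatilityClassification
    eligible: tuple[str, ...]

    @property
    def n_users(self) -> int:
        return len(self.eligible)


def prepare_dataset(
    users: Sequence[UserProfile],
    records: Sequence[PainRecord],
    seed: int | None = None,
) -> Dataset:
    """Run windowing, eligibility, thresholding and feature extraction.

    Volatility scores are computed per eligible user for both windows, the
    threshold comes from 2-means on the pooled scores, labels from applying
    the threshold per window, and features from the predictor window.
    """
    windows = build_windows(records)
    eligible = filter_eligible(users, windows)
    if not eligible:
        raise ValueError("no eligible users in cohort")
    pred_scores = {
        uid: compute_volatility(windows[uid].predictor.ratings())
        for uid in eligible
    }
    out_scores = {
        uid: compute_volatility(windows[uid].outcome.ratings())
        for uid in eligible
    }
    classification = derive_threshold(pred_scores, out_scores, seed=seed)
    by_id = {u.user_id: u for u in users}
    vectors = [
        extract_features(
            by_id[uid], windows[uid].predictor, classification.threshold
        )
        for uid in eligible
    ]
    X = features_to_frame(vectors)
    y = np.array([classification.outcome_labels[uid] for uid in eligible])
    return Dataset(
        X=X, y=y, classification=classification, eligible=tuple(eligible)
    )
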