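"""Track validation by safe per-feature thresholds or an SVM.

Each spatiotemporal feature gets one threshold, calibrated to a *safe*
value on labeled calibration tracks: walking a constant-step grid from the
minimum observed value upward, the threshold is fixed at the value that (a)
keeps every true detection in the accepted subset and (b) makes that subset
minimal on the grid. The five per-feature decisions are combined by logical
AND — rejecting any single feature rejects the track — which keeps the
thresholds independent of each other while exploiting their complementary
nature. Ties at a threshold pass, so the calibration extrema themselves are
always accepted.

Orientation is fixed per feature: a long duration is good (reject below the
threshold); high instability, shape change, edge density, and texture
variation are bad (reject above).

An SVM over the 5-feature space is provided as an alternative validator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .st_features import FEATURE_NAMES, FeatureVector

__all__ = [
    "ThresholdRule",
    "ORIENTATIONS",
    "estimate_safe_threshold",
    "calibrate_rules",
    "validate",
    "rules_to_yaml",
    "rules_from_yaml",
    "train_svm_validator",
    "svm_validator_cv_accuracy",
]

REJECT_ABOVE = "reject_above"
REJECT_BELOW = "reject_below"

ORIENTATIONS = {
    "duration": REJECT_BELOW,
    "instability": REJECT_ABOVE,
    "shape_change": REJECT_ABOVE,
    "edge_density": REJECT_ABOVE,
    "texture_variation": REJECT_ABOVE,
}


@dataclass
class ThresholdRule:
    feature: str
    orientation: str
    threshold: float
    step: float

    def passes(self, value: float) -> bool:
        """Strict rejection: values exactly at the threshold pass."""
        if self.orientation == REJECT_ABOVE:
            return not value > self.threshold
        if self.orientation == REJECT_BELOW:
            return not value < self.threshold
        raise ValueError(f"unknown orientation {self.orientation!r}")


def estimate_safe_threshold(
    tp_values: Sequence[float],
    fp_values: Sequence[float],
    orientation: str,
    step: float | None = None,
    feature: str = "",
) -> ThresholdRule:
    """Calibrate one safe threshold on a constant-step grid.

    The grid is anchored at the minimum observed value over both classes.
    For ``reject_above`` the threshold is the smallest grid value that is
    >= every true-positive value; for ``reject_below`` it is the largest
    grid value <= every true-positive value. False-positive values never
    move the threshold — they only determine how many rejections it earns.
    ``step`` defaults to 1/100 of the observed value range.
    """
    if len(tp_values) == 0:
        raise ValueError("calibration needs at least one true-positive value")
    if orientation not in (REJECT_ABOVE, REJECT_BELOW):
        raise ValueError(f"unknown orientation {orientation!r}")
    tp = np.asarray(tp_values, dtype=np.float64)
    all_vals = np.concatenate([tp, np.asarray(fp_values, dtype=np.float64)])
    lo, hi = float(all_vals.min()), float(all_vals.max())
    if step is None:
        step = (hi - lo) / 100.0 if hi > lo else 1.0
    if step <= 0:
        raise ValueError("step must be positive")
    eps = 1e-12 * max(1.0, abs(hi), abs(lo))
    if orientation == REJECT_ABOVE:
        k = math.ceil((tp.max() - lo) / step - eps)
        t = lo + max(k, 0) * step
    else:
        k = math.floor((tp.min() - lo) / step + eps)
        t = lo + max(k, 0) * step
    return ThresholdRule(feature=feature, orientation=orientation, threshold=float(t), step=float(step))


def calibrate_rules(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
    step: float | None = None,
) -> list[ThresholdRule]:
    """Safe thresholds for each feature from a labeled feature table.

    ``table`` needs one column per feature plus a boolean ``label`` column
    (True = true detection).
    """
    if "label" not in table:
        raise ValueError("feature table needs a boolean 'label' column")
    tp = table[table["label"].astype(bool)]
    fp = table[~table["label"].astype(bool)]
    if len(tp) == 0:
        raise ValueError("calibration needs at least one true detection")
    rules = []
    for name in features:
        rules.append(
            estimate_safe_threshold(
                tp[name].to_numpy(),
                fp[name].to_numpy(),
                ORIENTATIONS[name],
                step=step,
                feature=name,
            )
        )
    return rules


def validate(features: FeatureVector, rules: Sequence[ThresholdRule]) -> bool:
    """Logical-AND combination of the per-feature decisions.

    An empty rule list accepts everything (validation disabled baseline).
    """
    values = features.as_dict() if isinstance(features, FeatureVector) else dict(features)
    for rule in rules:
        if rule.feature not in values:
            raise KeyError(f"no value for configured feature {rule.feature!r}")
        if not rule.passes(values[rule.feature]):
            return False
    return True


def rules_to_yaml(rules: Sequence[ThresholdRule], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(r) for r in rules], fh, sort_keys=False)


def rules_from_yaml(path: str) -> list[ThresholdRule]:
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    return [ThresholdRule(**d) for d in docs]


def train_svm_validator(
    table: pd.DataFrame,
    kernel: str = "linear",
    features: Sequence[str] = FEATURE_NAMES,
    seed: int = 0,
):
    """Fit the alternative SVM validator on a labeled feature table."""
    if kernel not in ("linear", "rbf", "poly", "polynomial"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    kernel = "poly" if kernel == "polynomial" else kernel
    y = table["label"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = table[list(features)].to_numpy(dtype=np.float64)
    clf = make_pipeline(StandardScaler(), SVC(kernel=kernel, random_state=seed))
    clf.fit(X, y)
    return clf


def svm_validator_cv_accuracy(
    table: pd.DataFrame,
    kernel: str = "linear",
    features: Sequence[str] = FEATURE_NAMES,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified cross-validation accuracy of the SVM validator."""
    kernel = "poly" if kernel == "polynomial" else kernel
    y = table["label"].astype(int).to_numpy()
    X = table[list(features)].to_numpy(dtype=np.float64)
    folds = min(folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = make_pipeline(StandardScaler(), SVC(kernel=kernel, random_state=seed))
    return float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())
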