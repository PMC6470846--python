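"""Threshold-band fall classifier with Mann-Whitney feature selection.

The classifier keeps a per-feature [lower, upper] band learned as the
minimum and maximum of the feature over all *training falls* — the setting
that maximizes training sensitivity, which is 100% by construction.  A
slice is declared a fall only when the sensor is worn (slice minimum
temperature above the wear gate, default 27 °C) and *every* active feature
lies inside its band; one out-of-band or invalid feature vetoes the alarm.

Feature selection uses the two-sided Mann-Whitney U test between fall and
non-fall slices.  conv_rss, although discriminative, is flagged as excluded
for its computational cost on the embedded target; t_min acts as the wear
gate and is never band-tested.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES
from .io import LABEL_FALL, LABEL_NON_FALL

#: First-generation preset: the three original features.  var_rss3 is the
#: post-fall ("variance after fall") variance.
FIRST_GEN_FEATURES = ("upv", "conv_rss", "var_rss3")

#: Second-generation deployed set: the significant features minus conv_rss
#: (excluded for computational cost); t_min acts as the wear gate instead
#: of a band.
SECOND_GEN_FEATURES = (
    "upv", "lpv", "t1", "t2",
    "var_rss1", "var_rss2", "var_acc1", "var_acc2",
    "delta_mu_acc",
)

#: All band-testable features (everything except the t_min gate).
ALL_BAND_FEATURES = tuple(f for f in FEATURE_NAMES if f != "t_min")

DEFAULT_WEAR_GATE_C = 27.0

_PRESETS = {
    "first-gen": FIRST_GEN_FEATURES,
    "second-gen": SECOND_GEN_FEATURES,
    "all": ALL_BAND_FEATURES,
}

# enumeration is used when the number of group-A index subsets is below this
_ENUM_LIMIT = 200_000


def wear_gate(t_min: float, gate: float = DEFAULT_WEAR_GATE_C) -> bool:
    """Worn iff the slice minimum temperature strictly exceeds the gate.

    T <= gate (27 °C by default) means the sensor is off-body and the
    detector is switched off.
    """
    return bool(t_min > gate)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_a, p).

    The null distribution is evaluated exactly by enumerating all
    assignments of the pooled values to group A when that enumeration is
    small enough (tie-exact); via the exact no-ties distribution for
    moderate sizes without ties; and with the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    u_obs = _u_statistic(a, b)

    pooled = np.concatenate([a, b])
    if math.comb(na + nb, na) <= _ENUM_LIMIT:
        # tie-exact permutation null: every split of the pooled values
        idx = np.arange(na + nb)
        le = ge = total = 0
        ranks = stats.rankdata(pooled)
        offset = na * (na + 1) / 2.0
        for subset in combinations(idx, na):
            u = ranks[list(subset)].sum() - offset
            le += u <= u_obs + 1e-12
            ge += u >= u_obs - 1e-12
            total += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, float(p)

    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and na * nb <= 400:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact")
        return u_obs, float(res.pvalue)

    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-feature Mann-Whitney results and the deployable feature set."""

    u: dict[str, float]
    p: dict[str, float]
    significant: dict[str, bool]
    alpha: float
    excluded_for_cost: tuple[str, ...] = ("conv_rss",)

    @property
    def significant_features(self) -> list[str]:
        return [f for f in ALL_BAND_FEATURES if self.significant.get(f)]

    @property
    def deployable_features(self) -> list[str]:
        """Significant features minus those excluded for compute cost."""
        return [f for f in self.significant_features
                if f not in self.excluded_for_cost]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "features": {
                f: {"U": self.u[f], "p": self.p[f],
                    "significant": self.significant[f]}
                for f in self.u
            },
            "excluded_for_cost": list(self.excluded_for_cost),
            "deployable_features": self.deployable_features,
        }


def select_features(feature_table: pd.DataFrame, labels=None,
                    alpha: float = 0.05) -> SelectionReport:
    """Mann-Whitney test of every band feature, falls vs non-falls.

    ``labels`` defaults to the table's own ``label`` column.  Invalid (NaN)
    feature values are dropped per feature before testing; t_min is never
    tested (it is the wear gate, not a band).
    """
    if labels is None:
        if "label" not in feature_table.columns:
            raise ValueError("no labels given and no 'label' column")
        labels = feature_table["label"]
    labels = np.asarray(labels, dtype=object)
    is_fall = labels == LABEL_FALL
    if not is_fall.any() or is_fall.all():
        raise ValueError("need at least one fall and one non-fall slice")

    u, p, sig = {}, {}, {}
    for feat in ALL_BAND_FEATURES:
        col = feature_table[feat].to_numpy(dtype=float)
        a = col[is_fall & np.isfinite(col)]
        b = col[~is_fall & np.isfinite(col)]
        if len(a) == 0 or len(b) == 0:
            u[feat], p[feat], sig[feat] = float("nan"), float("nan"), False
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            # identical across both classes: no information
            u[feat], p[feat], sig[feat] = len(a) * len(b) / 2.0, 1.0, False
            continue
        u[feat], p[feat] = mann_whitney_u(a, b)
        sig[feat] = p[feat] < alpha
    return SelectionReport(u=u, p=p, significant=sig, alpha=alpha)


# ---------------------------------------------------------------------------
# threshold classifier
# ---------------------------------------------------------------------------

class ThresholdFallDetector(ClassifierMixin, BaseEstimator):
    """Per-feature threshold-band classifier with a temperature wear gate.

    ``fit`` sets each active feature's band to the (min, max) of that
    feature over the training falls, which guarantees 100% training
    sensitivity; non-fall training rows only matter through feature
    selection done beforehand.  ``predict`` declares a fall when the wear
    gate passes and every active feature lies inside its closed band.

    Parameters
    ----------
    features : str or sequence of str
        "second-gen" (default; the deployed significant set), "first-gen"
        (upv, conv_rss, var_rss3), "all", or an explicit feature list.
    wear_gate_c : float
        Wear-gate temperature in °C; the slice is treated as unworn (no
        alarm) when its minimum temperature is <= this value.  Applied only
        when the feature table has a ``t_min`` column.
    margin : float
        Optional symmetric band widening as a fraction of the band width
        (deployment slack; 0 reproduces the plain min/max rule).

    Attributes
    ----------
    bands_ : dict feature -> (lower, upper)
    active_features_ : list of str
    classes_ : ndarray, ["fall", "non-fall"]
    """

    def __init__(self, features="second-gen",
                 wear_gate_c: float = DEFAULT_WEAR_GATE_C,
                 margin: float = 0.0):
        self.features = features
        self.wear_gate_c = wear_gate_c
        self.margin = margin

    @property
    def generation(self) -> str:
        return "first" if self.features == "first-gen" else "second"

    def _resolve_features(self) -> list[str]:
        if isinstance(self.features, str):
            try:
                return list(_PRESETS[self.features])
            except KeyError:
                raise ValueError(
                    f"unknown feature preset {self.features!r}; expected one "
                    f"of {sorted(_PRESETS)} or an explicit list") from None
        feats = list(self.features)
        unknown = set(feats) - set(ALL_BAND_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature(s): {sorted(unknown)}")
        return feats

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError("X must be a per-slice feature DataFrame "
                        "(see SliceFeaturizer)")

    def fit(self, X, y=None) -> "ThresholdFallDetector":
        X = self._as_frame(X)
        if y is None:
            if "label" not in X.columns:
                raise ValueError("no labels given and no 'label' column")
            y = X["label"]
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        falls = X.loc[y == LABEL_FALL]
        if len(falls) == 0:
            raise ValueError("training data contains no fall slices")

        bands: dict[str, tuple[float, float]] = {}
        active: list[str] = []
        for feat in self._resolve_features():
            col = falls[feat].to_numpy(dtype=float)
            col = col[np.isfinite(col)]
            if len(col) == 0:
                warnings.warn(f"feature {feat!r} invalid in all training "
                              "falls; dropped from the active set",
                              stacklevel=2)
                continue
            lo, hi = float(col.min()), float(col.max())
            if self.margin:
                width = hi - lo
                lo, hi = lo - self.margin * width, hi + self.margin * width
            bands[feat] = (lo, hi)
            active.append(feat)
        if not active:
            raise ValueError("no usable feature: all active features are "
                             "invalid in every training fall")
        self.bands_ = bands
        self.active_features_ = active
        self.classes_ = np.array([LABEL_FALL, LABEL_NON_FALL], dtype=object)
        self.n_training_falls_ = int(len(falls))
        return self

    def _decision_mask(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean per-row fall decision."""
        decision = np.ones(len(X), dtype=bool)
        for feat in self.active_features_:
            col = X[feat].to_numpy(dtype=float)
            lo, hi = self.bands_[feat]
            inside = np.isfinite(col) & (col >= lo) & (col <= hi)
            decision &= inside
        if "t_min" in X.columns:
            worn = X["t_min"].to_numpy(dtype=float) > self.wear_gate_c
            decision &= worn
        return decision

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "bands_")
        X = self._as_frame(X)
        mask = self._decision_mask(X)
        return np.where(mask, LABEL_FALL, LABEL_NON_FALL).astype(object)

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "bands_")

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "bands_")
        return json.dumps({
            "generation": self.generation,
            "wear_gate_c": self.wear_gate_c,
            "margin": self.margin,
            "bands": {f: list(b) for f, b in self.bands_.items()},
            "active_features": self.active_features_,
            "provenance": {"n_training_falls": self.n_training_falls_},
        }, indent=2)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ThresholdFallDetector":
        data = json.loads(text)
        model = cls(features=list(data["active_features"]),
                    wear_gate_c=float(data["wear_gate_c"]),
                    margin=float(data.get("margin", 0.0)))
        model.bands_ = {f: (float(lo), float(hi))
                        for f, (lo, hi) in data["bands"].items()}
        model.active_features_ = list(data["active_features"])
        model.classes_ = np.array([LABEL_FALL, LABEL_NON_FALL], dtype=object)
        model.n_training_falls_ = int(
            data.get("provenance", {}).get("n_training_falls", 0))
        return model

    @classmethod
    def load(cls, path) -> "ThresholdFallDetector":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_thresholds(train_falls: pd.DataFrame,
                   active_features=SECOND_GEN_FEATURES,
                   wear_gate_c: float = DEFAULT_WEAR_GATE_C,
                   margin: float = 0.0) -> ThresholdFallDetector:
    """Fit the min/max band rule directly from a table of fall slices."""
    y = np.full(len(train_falls), LABEL_FALL, dtype=object)
    return ThresholdFallDetector(features=list(active_features),
                                 wear_gate_c=wear_gate_c,
                                 margin=margin).fit(train_falls, y)


def classify_slice(feature_row, model: ThresholdFallDetector) -> str:
    """Classify one feature vector (a mapping or one-row frame)."""
    if not isinstance(feature_row, pd.DataFrame):
        feature_row = pd.DataFrame([dict(feature_row)])
    return str(model.predict(feature_row)[0])
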