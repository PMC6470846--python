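"""Per-slice feature extraction for threshold-based fall detection.

The stream is cut into non-overlapping one-minute slices (6000 samples at
100 Hz), the unit at which ground-truth labels are assigned.  For every
slice, 15 features are computed around the slice's maximum of the
root-sum-of-squares acceleration

    RSS_ACC(t) = sqrt(ax(t)^2 + ay(t)^2 + az(t)^2) - 1 g,

which is 0 g for a motionless sensor in any orientation and -1 g in free
fall.  The maximum (UPV, upper peak value) serves as the temporal reference
point; all other windows are placed relative to it and may reach into the
neighbouring samples of the parent recording.

Feature summary (units):

=============  ======  =====================================================
upv            g       slice maximum of RSS_ACC (impact peak)
lpv            g       minimum of RSS_ACC in the 500 ms before the UPV
conv_rss       g       max of the norm-fall template convolved with RSS_ACC
t1             s       longest run with RSS_ACC in [-0.125, 0.125] g within
                       500 ms pre-UPV (quiescence before the free-fall dip)
t2             s       final ascent: last upward crossing of +0.125 g within
                       200 ms pre-UPV to the UPV
t3             s       width of the contiguous region around the UPV where
                       RSS_ACC exceeds UPV/4
t4             s       time from LPV to UPV
var_rss1..3    g^2     population variance of RSS_ACC in the pre-fall
                       [-400 ms, UPV], impact [-200 ms, +200 ms] and
                       post-fall [+1 s, +2 s] windows
var_acc1..3    g^2     per-axis population variances over the same windows,
                       combined as sqrt(vx^2 + vy^2 + vz^2)
delta_mu_acc   g       posture change: Euclidean distance between per-axis
                       300 ms mean vectors taken 1.8 s before and 0.5 s
                       after the UPV
t_min          °C      minimum temperature over the slice (wear indicator)
=============  ======  =====================================================

Window convention: half-open ``[start, stop)`` in sample indices; windows
whose text reads "... to the UPV" include the UPV sample as their last
sample.  A window truncated by the stream edge yields NaN and a cleared
validity flag; a window that exists but contains no qualifying crossing
yields a valid 0 (the measurement was made, its result is zero).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .io import SAMPLES_PER_SLICE, AccelRecording

#: Sampling interval in seconds.
DT = 0.01

#: The 15 features, in canonical table order.
FEATURE_NAMES = (
    "upv", "lpv", "conv_rss", "t1", "t2", "t3", "t4",
    "var_rss1", "var_rss2", "var_rss3",
    "var_acc1", "var_acc2", "var_acc3",
    "delta_mu_acc", "t_min",
)

# Window extents in samples (100 Hz).
LPV_WINDOW = 50          # 500 ms before the UPV
T1_WINDOW = 50           # 500 ms before the UPV
T2_WINDOW = 20           # 200 ms before the UPV
T1_BAND_G = 0.125        # quiescence band, ±0.125 g
VAR_PRE = (-40, 1)       # pre-fall variance window, ends at the UPV sample
VAR_IMPACT = (-20, 21)   # impact window, 200 ms either side of the UPV
VAR_POST = (100, 200)    # post-fall window, 1..2 s after the UPV
MU_WINDOW = 30           # 300 ms posture-mean windows
MU1_OFFSET = -180        # window starts 1.8 s before the UPV
MU2_OFFSET = 50          # window starts 0.5 s after the UPV


class ContractError(ValueError):
    """A precondition of a feature operation was violated."""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_rss(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares acceleration minus 1 g, elementwise."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ContractError("axis series must have equal length")
    return np.sqrt(ax ** 2 + ay ** 2 + az ** 2) - 1.0


@dataclass
class Slice:
    """One-minute window of a recording, with context access to its parent.

    ``start``/``stop`` bound the slice itself; feature windows placed
    relative to the UPV may read parent samples outside them.
    """

    recording: AccelRecording
    index: int
    label: Optional[str] = None

    @property
    def start(self) -> int:
        return self.index * SAMPLES_PER_SLICE

    @property
    def stop(self) -> int:
        return self.start + SAMPLES_PER_SLICE


def slice_stream(rec: AccelRecording) -> list[Slice]:
    """Cut a recording into non-overlapping one-minute slices.

    A trailing remainder shorter than one minute is dropped.  A recording
    shorter than one minute yields an empty list with a warning.
    """
    n = rec.n_slices
    if n == 0:
        warnings.warn("recording shorter than one slice (6000 samples); "
                      "no slices produced", stacklevel=2)
        return []
    return [Slice(rec, i, label=rec.slice_label(i)) for i in range(n)]


def find_upv(rss: np.ndarray, start: int, stop: int) -> tuple[int, float]:
    """Position (absolute index) and value of the maximum RSS_ACC in a slice.

    Ties break to the earliest sample.
    """
    window = rss[start:stop]
    if len(window) == 0:
        raise ContractError("empty slice")
    i = int(np.argmax(window))
    return start + i, float(window[i])


def find_lpv(rss: np.ndarray, upv_index: int) -> tuple[Optional[int], float]:
    """Minimum RSS_ACC in the 500 ms window before the UPV.

    The window ``[upv_index - 50, upv_index)`` truncates at the stream
    start; an empty window returns ``(None, nan)``.
    """
    lo = max(0, upv_index - LPV_WINDOW)
    window = rss[lo:upv_index]
    if len(window) == 0:
        return None, float("nan")
    i = int(np.argmin(window))
    return lo + i, float(window[i])


def compute_phase_times(rss: np.ndarray, upv_index: int,
                        lpv_index: Optional[int],
                        upv: float,
                        t1_mode: str = "longest_run",
                        ) -> tuple[dict[str, float], dict[str, bool]]:
    """Phase durations t1..t4 in seconds, with per-feature validity flags.

    t1_mode selects between the longest contiguous in-band run (default)
    and the total in-band time within the 500 ms pre-UPV window.
    """
    if t1_mode not in ("longest_run", "total"):
        raise ContractError(f"unknown t1_mode {t1_mode!r}")
    values: dict[str, float] = {}
    valid: dict[str, bool] = {}

    # t1 — quiescent time in the 500 ms pre-UPV window
    lo = max(0, upv_index - T1_WINDOW)
    window = rss[lo:upv_index]
    if len(window) == 0:
        values["t1"], valid["t1"] = float("nan"), False
    else:
        in_band = np.abs(window) <= T1_BAND_G
        if t1_mode == "total":
            run = int(in_band.sum())
        else:
            run = best = 0
            for flag in in_band:
                best = best + 1 if flag else 0
                run = max(run, best)
        values["t1"], valid["t1"] = run * DT, True

    # t2 — last upward crossing of +0.125 g within 200 ms pre-UPV, to UPV
    lo = max(0, upv_index - T2_WINDOW)
    t2 = 0.0
    found = False
    for i in range(upv_index - 1, lo - 1, -1):
        prev = rss[i - 1] if i > 0 else rss[i]
        if rss[i] > T1_BAND_G and prev <= T1_BAND_G:
            t2 = (upv_index - i) * DT
            found = True
            break
    if upv_index == 0:
        values["t2"], valid["t2"] = float("nan"), False
    else:
        values["t2"], valid["t2"] = (t2 if found else 0.0), True

    # t3 — width of the contiguous super-threshold region containing the UPV
    thr = upv / 4.0
    if rss[upv_index] <= thr:  # degenerate (upv <= 0): region is empty
        values["t3"], valid["t3"] = 0.0, True
    else:
        left = upv_index
        while left > 0 and rss[left - 1] > thr:
            left -= 1
        right = upv_index
        while right + 1 < len(rss) and rss[right + 1] > thr:
            right += 1
        values["t3"], valid["t3"] = (right - left + 1) * DT, True

    # t4 — LPV to UPV
    if lpv_index is None:
        values["t4"], valid["t4"] = float("nan"), False
    else:
        values["t4"], valid["t4"] = (upv_index - lpv_index) * DT, True

    return values, valid


def _window_bounds(upv_index: int, rel: tuple[int, int],
                   n: int) -> Optional[tuple[int, int]]:
    """Absolute bounds of a UPV-relative window, or None if truncated."""
    lo, hi = upv_index + rel[0], upv_index + rel[1]
    if lo < 0 or hi > n:
        return None
    return lo, hi


def phase_variances_rss(rss: np.ndarray, upv_index: int,
                        ) -> tuple[dict[str, float], dict[str, bool]]:
    """Population variance of RSS_ACC over the three phase windows."""
    values, valid = {}, {}
    for name, rel in (("var_rss1", VAR_PRE), ("var_rss2", VAR_IMPACT),
                      ("var_rss3", VAR_POST)):
        bounds = _window_bounds(upv_index, rel, len(rss))
        if bounds is None:
            values[name], valid[name] = float("nan"), False
        else:
            values[name] = float(np.var(rss[bounds[0]:bounds[1]]))
            valid[name] = True
    return values, valid


def phase_variances_axes(ax: np.ndarray, ay: np.ndarray, az: np.ndarray,
                         upv_index: int,
                         ) -> tuple[dict[str, float], dict[str, bool]]:
    """Per-axis population variances, combined per phase.

    The combination is the Euclidean norm of the three per-axis variances,
    sqrt(vx^2 + vy^2 + vz^2), in g^2.
    """
    values, valid = {}, {}
    for name, rel in (("var_acc1", VAR_PRE), ("var_acc2", VAR_IMPACT),
                      ("var_acc3", VAR_POST)):
        bounds = _window_bounds(upv_index, rel, len(ax))
        if bounds is None:
            values[name], valid[name] = float("nan"), False
        else:
            lo, hi = bounds
            v = [float(np.var(a[lo:hi])) for a in (ax, ay, az)]
            values[name] = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
            valid[name] = True
    return values, valid


def posture_change(ax: np.ndarray, ay: np.ndarray, az: np.ndarray,
                   upv_index: int) -> tuple[float, bool]:
    """Posture-change magnitude delta_mu_acc in g.

    Per-axis means over two 300 ms windows, one starting 1.8 s before the
    UPV and one starting 0.5 s after it; the feature is the Euclidean norm
    of the per-axis mean differences.  A truncated window invalidates the
    feature.
    """
    n = len(ax)
    b1 = _window_bounds(upv_index, (MU1_OFFSET, MU1_OFFSET + MU_WINDOW), n)
    b2 = _window_bounds(upv_index, (MU2_OFFSET, MU2_OFFSET + MU_WINDOW), n)
    if b1 is None or b2 is None:
        return float("nan"), False
    total = 0.0
    for a in (ax, ay, az):
        mu1 = float(np.mean(a[b1[0]:b1[1]]))
        mu2 = float(np.mean(a[b2[0]:b2[1]]))
        total += (mu1 - mu2) ** 2
    return math.sqrt(total), True


def min_temperature(temp: np.ndarray, start: int, stop: int) -> float:
    """Minimum temperature over the slice window."""
    window = temp[start:stop]
    if len(window) == 0:
        raise ContractError("empty temperature window")
    return float(np.min(window))


# ---------------------------------------------------------------------------
# norm-fall template and convolution
# ---------------------------------------------------------------------------

@dataclass
class NormFallTemplate:
    """Reference RSS_ACC waveform of a typical fall.

    Convolved against a slice's RSS_ACC; the maximum response is the
    conv_rss feature.  ``source`` records how the template was obtained:
    estimated from training falls, generated parametrically, or loaded.
    """

    values: np.ndarray
    source: str = "estimated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 1:
            raise ContractError("template must have length >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("template values must be finite")

    def save(self, path) -> None:
        """Write waveform CSV plus a JSON sidecar with metadata."""
        pd.DataFrame({"value": self.values}).to_csv(path, index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"length": len(self.values),
                       "l2_norm": float(np.linalg.norm(self.values)),
                       "source": self.source}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "NormFallTemplate":
        values = pd.read_csv(path)["value"].to_numpy()
        return cls(values=values, source="loaded")


def estimate_norm_template(fall_slices: Sequence[Slice],
                           half_width_ms: float = 400.0,
                           ) -> NormFallTemplate:
    """UPV-aligned, L2-normalized mean RSS_ACC waveform of training falls.

    Each fall slice contributes its RSS_ACC segment ±half_width_ms around
    its UPV; segments truncated by the recording edge are zero-padded.
    """
    if len(fall_slices) == 0:
        raise ContractError("need at least one fall slice")
    hw = int(round(half_width_ms / 1000.0 / DT))
    length = 2 * hw + 1
    acc = np.zeros(length)
    for sl in fall_slices:
        rec = sl.recording
        rss = compute_rss(rec.ax, rec.ay, rec.az)
        upv_index, _ = find_upv(rss, sl.start, sl.stop)
        seg = np.zeros(length)
        lo = max(0, upv_index - hw)
        hi = min(len(rss), upv_index + hw + 1)
        seg[lo - (upv_index - hw):hi - (upv_index - hw)] = rss[lo:hi]
        acc += seg
    acc /= len(fall_slices)
    norm = np.linalg.norm(acc)
    if norm == 0:
        raise ContractError("degenerate template: all-zero mean segment")
    return NormFallTemplate(values=acc / norm, source="estimated")


def parametric_norm_template(half_width_ms: float = 400.0,
                             trough_g: float = -0.9,
                             peak_g: float = 3.0) -> NormFallTemplate:
    """Stylized piecewise norm-fall waveform (free-fall trough, impact spike).

    Self-contained fallback when no training falls are available: RSS_ACC
    descends into a free-fall trough over the pre-impact half, spikes to
    ``peak_g`` at the centre and rings down as a damped oscillation.
    L2-normalized like the estimated template.
    """
    hw = int(round(half_width_ms / 1000.0 / DT))
    t = np.arange(-hw, hw + 1) * DT
    w = np.zeros_like(t)
    pre = t < 0
    # deepening free-fall trough, recovering just before impact
    w[pre] = trough_g * (1 - np.exp(t[pre] / 0.15)) * np.exp(t[pre] / 1.0)
    post = t >= 0
    w[post] = peak_g * np.exp(-t[post] / 0.05) * np.cos(
        2 * np.pi * 8.0 * t[post])
    return NormFallTemplate(values=w / np.linalg.norm(w),
                            source="parametric")


def max_convolution(rss: np.ndarray, template: NormFallTemplate) -> float:
    """Maximum of the finite convolution of RSS_ACC with the template.

    r(n) = sum_i h(i) * x(n - i) with zero-padded boundaries; the maximum
    over all n is the conv_rss feature.
    """
    rss = np.asarray(rss, dtype=float)
    if len(template.values) > len(rss):
        raise ContractError("template longer than the signal")
    return float(np.convolve(rss, template.values, mode="full").max())


# ---------------------------------------------------------------------------
# per-slice feature vector
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The 15 per-slice features plus validity flags and the UPV position."""

    values: dict[str, float]
    valid: dict[str, bool]
    upv_index: int
    slice_index: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if name not in self.values:
                raise ContractError(f"missing feature {name!r}")
            if not self.valid.get(name, False):
                self.values[name] = float("nan")

    def to_dict(self) -> dict:
        d = {"slice_index": self.slice_index}
        d.update({name: self.values[name] for name in FEATURE_NAMES})
        d["label"] = self.label
        return d


def extract_features(sl: Slice, template: NormFallTemplate,
                     rss: Optional[np.ndarray] = None,
                     t1_mode: str = "longest_run") -> FeatureVector:
    """Compute the full 15-feature vector for one slice.

    Deterministic and total: degenerate slices produce flagged NaNs, never
    exceptions.  ``rss`` may be passed in to avoid recomputation when
    extracting many slices of one recording.
    """
    rec = sl.recording
    if rss is None:
        rss = compute_rss(rec.ax, rec.ay, rec.az)
    values: dict[str, float] = {}
    valid: dict[str, bool] = {name: True for name in FEATURE_NAMES}

    upv_index, upv = find_upv(rss, sl.start, sl.stop)
    values["upv"] = upv
    lpv_index, lpv = find_lpv(rss, upv_index)
    values["lpv"] = lpv
    valid["lpv"] = lpv_index is not None

    values["conv_rss"] = max_convolution(rss[sl.start:sl.stop], template)

    tvals, tvalid = compute_phase_times(rss, upv_index, lpv_index, upv,
                                        t1_mode=t1_mode)
    values.update(tvals)
    valid.update(tvalid)

    vvals, vvalid = phase_variances_rss(rss, upv_index)
    values.update(vvals)
    valid.update(vvalid)

    avals, avalid = phase_variances_axes(rec.ax, rec.ay, rec.az, upv_index)
    values.update(avals)
    valid.update(avalid)

    values["delta_mu_acc"], valid["delta_mu_acc"] = posture_change(
        rec.ax, rec.ay, rec.az, upv_index)
    values["t_min"] = min_temperature(rec.temperature, sl.start, sl.stop)

    return FeatureVector(values=values, valid=valid, upv_index=upv_index,
                         slice_index=sl.index, label=sl.label)


def feature_table(rec: AccelRecording, template: NormFallTemplate,
                  t1_mode: str = "longest_run") -> pd.DataFrame:
    """Extract features for every slice of a recording into a DataFrame.

    Columns: ``slice_index``, the 15 features in canonical order, ``label``.
    """
    rss = compute_rss(rec.ax, rec.ay, rec.az)
    rows = [extract_features(sl, template, rss=rss, t1_mode=t1_mode).to_dict()
            for sl in slice_stream(rec)]
    columns = ["slice_index", *FEATURE_NAMES, "label"]
    return pd.DataFrame(rows, columns=columns)


class SliceFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer from recordings to per-slice feature tables.

    ``fit`` learns the norm-fall template: from the fall-labelled slices of
    the training recordings (``template="estimate"``), from the stylized
    parametric waveform (``template="parametric"``), or a pre-built
    :class:`NormFallTemplate` can be passed directly.  ``transform`` maps a
    recording (or list of recordings) to one :class:`pandas.DataFrame` row
    per slice.

    Parameters
    ----------
    template : "estimate" | "parametric" | NormFallTemplate
        Template policy.  "estimate" falls back to the parametric waveform
        when the training data contains no fall-labelled slice.
    half_width_ms : float
        Template half-width around the aligned impact peak.
    t1_mode : "longest_run" | "total"
        Convention for the t1 quiescence time.
    """

    def __init__(self, template="estimate", half_width_ms: float = 400.0,
                 t1_mode: str = "longest_run"):
        self.template = template
        self.half_width_ms = half_width_ms
        self.t1_mode = t1_mode

    @staticmethod
    def _as_recordings(X) -> list[AccelRecording]:
        if isinstance(X, AccelRecording):
            return [X]
        recs = list(X)
        if not all(isinstance(r, AccelRecording) for r in recs):
            raise TypeError("X must be an AccelRecording or a sequence "
                            "of AccelRecording")
        return recs

    def fit(self, X, y=None) -> "SliceFeaturizer":
        if isinstance(self.template, NormFallTemplate):
            self.template_ = self.template
        elif self.template == "parametric":
            self.template_ = parametric_norm_template(self.half_width_ms)
        elif self.template == "estimate":
            fall_slices = [sl for rec in self._as_recordings(X)
                           for sl in slice_stream(rec)
                           if sl.label == "fall"]
            if fall_slices:
                self.template_ = estimate_norm_template(
                    fall_slices, half_width_ms=self.half_width_ms)
            else:
                warnings.warn("no fall-labelled training slices; using the "
                              "parametric norm-fall template", stacklevel=2)
                self.template_ = parametric_norm_template(self.half_width_ms)
        else:
            raise ValueError(f"unknown template policy {self.template!r}")
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "template_"):
            raise NotFittedError("SliceFeaturizer is not fitted")
        tables = [feature_table(rec, self.template_, t1_mode=self.t1_mode)
                  for rec in self._as_recordings(X)]
        return pd.concat(tables, ignore_index=True)

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "template_")
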