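"""Synthetic 100 Hz accelerometer + temperature streams with labelled falls.

The generator makes the whole pipeline testable without sensor data: a
gravity-oriented background of activities of daily living (ADL) — walking
bouts as 2 Hz oscillation, occasional sit/stand transients up to 1.5 g
total magnitude, Gaussian sensor noise — into which stylized three-phase
fall events are spliced:

* pre-fall: the acceleration magnitude decays exponentially below 1 g
  toward free fall;
* impact: a spike reaching the configured peak magnitude at the phase
  boundary, ringing down as a damped oscillation while the orientation
  rotates toward the post-fall posture;
* post-fall: near-constant gravity along the new orientation (lying still).

Total pre-fall + impact duration is the event duration, by default drawn
uniformly from [0.45, 0.85] s.  The temperature channel follows a
first-order approach toward skin temperature (default 33 °C) while worn
and toward ambient (default 22 °C) otherwise, so the wear gate at 27 °C
separates the two plateaus.  Every minute containing an impact sample is
labelled "fall".  All randomness flows from a single seed; identical
configurations produce bit-identical streams.

The waveforms are stylized kinematics, not biomechanics; see the methods
note for what they do and do not emulate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .io import (LABEL_FALL, LABEL_NON_FALL, SAMPLE_RATE_HZ,
                 SAMPLES_PER_SLICE, AccelRecording, quantize)

DT = 1.0 / SAMPLE_RATE_HZ

#: Default fall parameter ranges (the simulated study conditions).
EVENT_DURATION_RANGE_S = (0.45, 0.85)
PREFALL_FRACTION_RANGE = (0.55, 0.75)
IMPACT_PEAK_RANGE_G = (2.5, 5.0)
POSTFALL_TILT_RANGE_DEG = (60.0, 120.0)

#: Free-fall magnitude decay time constant (s).
FREEFALL_TAU_S = 0.15
#: Impact ring-down time constant (s) and oscillation frequency (Hz).
IMPACT_TAU_S = 0.04
IMPACT_RING_HZ = 12.0
#: Quiet-posture sensor noise (g) inside fall segments.
SEGMENT_NOISE_SD_G = 0.005
#: Cross-fade length for splicing fall segments into the background.
CROSSFADE_SAMPLES = 10  # 100 ms

INITIAL_ORIENTATION = np.array([0.0, 0.0, 1.0])


@dataclass
class FallEventSpec:
    """Parameters of one simulated fall event.

    ``onset_time`` marks the start of the pre-fall phase; the impact occurs
    ``prefall_duration`` later.  ``event_duration`` covers pre-fall plus
    impact and must lie in the 0.45–0.85 s envelope typical of falls.
    """

    onset_time: float
    event_duration: float = 0.65
    prefall_fraction: float = 0.65
    impact_peak: float = 3.5
    postfall_orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.postfall_orientation = np.asarray(self.postfall_orientation,
                                               dtype=float)
        if self.onset_time < 0:
            raise ValueError("onset_time must be non-negative")
        if not (0.45 <= self.event_duration <= 0.85):
            raise ValueError("event_duration must lie in [0.45, 0.85] s")
        if not (0.0 < self.prefall_fraction < 1.0):
            raise ValueError("prefall_fraction must lie in (0, 1)")
        if self.impact_peak <= 1.0:
            raise ValueError("impact_peak must exceed 1 g")
        norm = np.linalg.norm(self.postfall_orientation)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("postfall_orientation must be a unit vector")

    @property
    def prefall_duration(self) -> float:
        return self.prefall_fraction * self.event_duration

    @property
    def onset_sample(self) -> int:
        return int(round(self.onset_time * SAMPLE_RATE_HZ))

    @property
    def impact_sample(self) -> int:
        """Absolute index of the first impact sample (the peak)."""
        return self.onset_sample + int(round(
            self.prefall_duration * SAMPLE_RATE_HZ))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["postfall_orientation"] = list(self.postfall_orientation)
        d["impact_sample"] = self.impact_sample
        return d

    @classmethod
    def random(cls, rng: np.random.Generator,
               onset_time: float) -> "FallEventSpec":
        """Draw a fall from the default study-condition distributions."""
        theta = math.radians(rng.uniform(*POSTFALL_TILT_RANGE_DEG))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        orientation = np.array([math.sin(theta) * math.cos(phi),
                                math.sin(theta) * math.sin(phi),
                                math.cos(theta)])
        return cls(
            onset_time=onset_time,
            event_duration=rng.uniform(*EVENT_DURATION_RANGE_S),
            prefall_fraction=rng.uniform(*PREFALL_FRACTION_RANGE),
            impact_peak=rng.uniform(*IMPACT_PEAK_RANGE_G),
            postfall_orientation=orientation,
        )


@dataclass
class SimConfig:
    """Configuration of one simulated recording."""

    duration_min: int = 120
    fall_specs: list[FallEventSpec] = field(default_factory=list)
    adl_intensity: float = 1.0
    noise_sd: float = 0.02
    wear_schedule: Optional[list[tuple[float, float]]] = None  # seconds
    ambient_c: float = 22.0
    skin_c: float = 33.0
    temp_tau_s: float = 120.0
    initial_c: Optional[float] = None  # None: start at ambient (warm-up)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("duration_min must be >= 1")
        end = self.duration_min * 60.0
        for spec in self.fall_specs:
            if spec.onset_time >= end:
                raise ValueError("fall onset beyond stream duration")
        if self.wear_schedule is not None:
            last = -1.0
            for start, stop in self.wear_schedule:
                if start < last or stop <= start:
                    raise ValueError("worn intervals must be disjoint and "
                                     "increasing")
                last = stop

    @property
    def n_samples(self) -> int:
        return self.duration_min * SAMPLES_PER_SLICE


def _slerp(v0: np.ndarray, v1: np.ndarray, t: float) -> np.ndarray:
    """Spherical interpolation between unit vectors."""
    dot = float(np.clip(np.dot(v0, v1), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-9:
        return v0
    s = math.sin(omega)
    return (math.sin((1 - t) * omega) * v0 + math.sin(t * omega) * v1) / s


def simulate_adl(cfg: SimConfig) -> AccelRecording:
    """Background recording of daily-living motion, all slices non-fall.

    With ``adl_intensity`` 0 and ``noise_sd`` 0 the stream is pure gravity
    (RSS_ACC identically 0 g).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) * DT

    signal = np.outer(np.ones(n), INITIAL_ORIENTATION)

    if cfg.adl_intensity > 0:
        # walking bouts: alternating active/rest periods, 2 Hz oscillation
        envelope = np.zeros(n)
        pos = 0
        active = False
        while pos < n:
            dur = int(rng.exponential(60.0 if active else 30.0)
                      * SAMPLE_RATE_HZ) + SAMPLE_RATE_HZ
            if active:
                envelope[pos:pos + dur] = 1.0
            active = not active
            pos += dur
        phase = rng.uniform(0, 2 * math.pi)
        walk = 0.15 * cfg.adl_intensity * envelope * np.sin(
            2 * math.pi * 2.0 * t + phase)
        signal[:, 2] += walk
        signal[:, 0] += 0.4 * walk

        # occasional sit/stand transients, total magnitude <= 1.5 g
        n_transients = rng.poisson(cfg.duration_min / 2.0)
        for _ in range(n_transients):
            centre = rng.integers(50, max(51, n - 50))
            width = int(rng.uniform(0.3, 0.6) * SAMPLE_RATE_HZ)
            amp = rng.uniform(0.1, 0.5) * cfg.adl_intensity
            lo = max(0, centre - width)
            hi = min(n, centre + width)
            bump = amp * np.hanning(2 * width)[:hi - lo]
            signal[lo:hi, 2] += bump

    if cfg.noise_sd > 0:
        signal += rng.normal(0.0, cfg.noise_sd, size=(n, 3))

    temperature = simulate_temperature(cfg)
    labels = np.full(cfg.duration_min, LABEL_NON_FALL, dtype=object)
    return AccelRecording(ax=signal[:, 0], ay=signal[:, 1], az=signal[:, 2],
                          temperature=temperature, labels=labels)


def simulate_fall_segment(spec: FallEventSpec, seed: int = 0,
                          lead_in_s: float = 2.0,
                          post_s: float = 3.0) -> np.ndarray:
    """One fall as an (n, 3) per-axis g array: lead-in, pre-fall, impact,
    post-fall lying.

    The first impact sample has magnitude exactly ``spec.impact_peak``
    (RSS_ACC = peak - 1); the ring-down decays from there while the
    orientation rotates toward ``spec.postfall_orientation``.
    """
    rng = np.random.default_rng(seed)
    n_lead = int(round(lead_in_s * SAMPLE_RATE_HZ))
    n_event = int(round(spec.event_duration * SAMPLE_RATE_HZ))
    n_pre = int(round(spec.prefall_duration * SAMPLE_RATE_HZ))
    n_imp = max(1, n_event - n_pre)
    n_post = int(round(post_s * SAMPLE_RATE_HZ))

    g0 = INITIAL_ORIENTATION
    g1 = spec.postfall_orientation

    parts = []
    if n_lead:
        lead = np.outer(np.ones(n_lead), g0)
        lead += rng.normal(0.0, SEGMENT_NOISE_SD_G, size=lead.shape)
        parts.append(lead)

    # pre-fall: magnitude decays toward free fall along the old orientation
    tp = np.arange(n_pre) * DT
    mag = np.exp(-tp / FREEFALL_TAU_S)
    parts.append(mag[:, None] * g0)

    # impact: peak at the first sample, damped ring-down, orientation slerp
    imp = np.empty((n_imp, 3))
    for k in range(n_imp):
        tau_frac = k / max(1, n_imp - 1) if n_imp > 1 else 1.0
        direction = _slerp(g0, g1, tau_frac)
        tk = k * DT
        mag_k = 1.0 + (spec.impact_peak - 1.0) * math.exp(
            -tk / IMPACT_TAU_S) * abs(math.cos(
                2 * math.pi * IMPACT_RING_HZ * tk))
        imp[k] = mag_k * direction
    imp[0] = spec.impact_peak * g0  # exact peak at the phase boundary
    parts.append(imp)

    if n_post:
        post = np.outer(np.ones(n_post), g1)
        post += rng.normal(0.0, SEGMENT_NOISE_SD_G, size=post.shape)
        parts.append(post)

    return np.vstack(parts)


def inject_falls(rec: AccelRecording, specs: Sequence[FallEventSpec],
                 seed: int = 0) -> AccelRecording:
    """Splice fall segments into a recording and label the impact minutes.

    Segments replace the background over their extent with a 100 ms linear
    cross-fade at both ends.  Every minute containing an impact sample is
    labelled "fall".  Events must not overlap and must fit inside the
    recording.
    """
    specs = sorted(specs, key=lambda s: s.onset_time)
    n = rec.n_samples
    signal = np.column_stack([rec.ax.copy(), rec.ay.copy(), rec.az.copy()])
    labels = (rec.labels.copy() if rec.labels is not None
              else np.full(rec.n_slices, LABEL_NON_FALL, dtype=object))

    lead_in_s, post_s = 0.2, 2.5
    prev_end = -1
    for k, spec in enumerate(specs):
        seg = simulate_fall_segment(spec, seed=seed + k,
                                    lead_in_s=lead_in_s, post_s=post_s)
        start = spec.onset_sample - int(round(lead_in_s * SAMPLE_RATE_HZ))
        stop = start + len(seg)
        if start < 0 or stop > n:
            raise ValueError(f"fall at t={spec.onset_time}s does not fit "
                             "inside the recording")
        if start < prev_end:
            raise ValueError("overlapping fall events")
        prev_end = stop

        signal[start:stop] = seg
        m = min(CROSSFADE_SAMPLES, start, len(seg))
        if m:
            w = np.linspace(0.0, 1.0, m)[:, None]
            signal[start:start + m] = ((1 - w) * rec_axis(rec, start, m)
                                       + w * seg[:m])
        m = min(CROSSFADE_SAMPLES, n - stop + 0, len(seg))
        if m and stop - m >= 0:
            w = np.linspace(1.0, 0.0, m)[:, None]
            tail_bg = rec_axis(rec, stop - m, m)
            signal[stop - m:stop] = (w * seg[len(seg) - m:]
                                     + (1 - w) * tail_bg)

        minute = spec.impact_sample // SAMPLES_PER_SLICE
        if minute < len(labels):
            labels[minute] = LABEL_FALL

    return AccelRecording(ax=signal[:, 0], ay=signal[:, 1], az=signal[:, 2],
                          temperature=rec.temperature.copy(), labels=labels,
                          start_time=rec.start_time, meta=rec.meta)


def rec_axis(rec: AccelRecording, start: int, length: int) -> np.ndarray:
    """(length, 3) view of the background signal starting at ``start``."""
    sl = slice(start, start + length)
    return np.column_stack([rec.ax[sl], rec.ay[sl], rec.az[sl]])


def simulate_temperature(cfg: SimConfig) -> np.ndarray:
    """First-order skin/ambient temperature trace for the wear schedule.

    Worn intervals pull the temperature toward ``skin_c`` with time
    constant ``temp_tau_s``; unworn spans decay toward ``ambient_c``.  A
    missing schedule means worn for the whole recording.
    """
    n = cfg.n_samples
    duration = n * DT
    schedule = (cfg.wear_schedule if cfg.wear_schedule is not None
                else [(0.0, duration)])

    # build per-sample target temperature
    target = np.full(n, cfg.ambient_c)
    for start, stop in schedule:
        i = max(0, int(round(start / DT)))
        j = min(n, int(round(stop / DT)))
        target[i:j] = cfg.skin_c

    temp = np.empty(n)
    current = cfg.initial_c if cfg.initial_c is not None else cfg.ambient_c
    # exact exponential within runs of constant target
    boundaries = np.flatnonzero(np.diff(target)) + 1
    edges = np.concatenate([[0], boundaries, [n]])
    for i, j in zip(edges[:-1], edges[1:]):
        tgt = target[i]
        tt = np.arange(j - i) * DT
        temp[i:j] = tgt + (current - tgt) * np.exp(-tt / cfg.temp_tau_s)
        current = tgt + (current - tgt) * math.exp(-(j - i) * DT
                                                   / cfg.temp_tau_s)
    return temp


def simulate_study(duration_min: int = 120, n_falls: int = 10,
                   seed: int = 0, adl_intensity: float = 1.0,
                   noise_sd: float = 0.02,
                   wear_schedule: Optional[list[tuple[float, float]]] = None,
                   quantize_output: bool = True,
                   ) -> tuple[AccelRecording, list[FallEventSpec]]:
    """End-to-end labelled recording: ADL + temperature + injected falls.

    Falls are placed in distinct interior minutes with the impact well away
    from slice edges.  With ``quantize_output`` the acceleration passes
    through the 10-bit ±8 g sensor front end.
    """
    if n_falls > max(0, duration_min - 2):
        raise ValueError("too many falls for the stream duration")
    rng = np.random.default_rng(seed)
    # recordings with no explicit schedule start mid-wear (no warm-up lag)
    initial_c = 33.0 if wear_schedule is None else None
    cfg = SimConfig(duration_min=duration_min, adl_intensity=adl_intensity,
                    noise_sd=noise_sd, wear_schedule=wear_schedule,
                    initial_c=initial_c, seed=int(rng.integers(2 ** 31)))
    rec = simulate_adl(cfg)

    minutes = rng.choice(np.arange(1, duration_min - 1), size=n_falls,
                         replace=False)
    specs = [FallEventSpec.random(rng, onset_time=float(m) * 60.0
                                  + rng.uniform(5.0, 40.0))
             for m in sorted(minutes)]
    rec = inject_falls(rec, specs, seed=int(rng.integers(2 ** 31)))
    if quantize_output:
        rec = quantize(rec)
    return rec, specs


def events_manifest(specs: Sequence[FallEventSpec]) -> str:
    """JSON manifest of injected events (sample-resolution ground truth)."""
    return json.dumps({"events": [s.to_dict() for s in specs]}, indent=2)
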