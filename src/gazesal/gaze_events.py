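"""Blink / saccade / fixation segmentation of 1 kHz gaze traces.

Positions are low-pass filtered with a zero-phase FIR whose half-power
(-3 dB) point sits at 30 Hz, velocity and acceleration come from a
two-point (central) difference, and samples are then segmented:

* blinks: maximal runs of pupil = 0, padded by +/-25 ms to absorb
  lid-closure artifacts; positions there are invalid;
* saccades: runs where speed exceeds 30 deg/s for at least 8 ms, extended
  outward until speed falls below 10 deg/s;
* fixations: the remaining valid epochs of at least 50 ms.

The velocity thresholds are standard eye-tracking values, exposed in
``DetectionParams``. Saccades with amplitude strictly greater than one
degree are classed ``regular``, the rest ``micro``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import firwin, freqz

from .synthetic_data import GazeTrial

GAIN_3DB = 10 ** (-3 / 20)  # ~0.70795


@dataclass(frozen=True)
class DetectionParams:
    """Filter and segmentation settings (sampling rate fixed at 1 kHz)."""

    f3db_hz: float = 30.0
    numtaps: int = 51
    v_onset: float = 30.0     # deg/s; speed must exceed this to open a saccade
    v_offset: float = 10.0    # deg/s; hysteresis bound for saccade extension
    min_saccade_ms: int = 8
    min_fixation_ms: int = 50
    blink_pad_ms: int = 25
    central_difference: bool = True  # False: forward difference


DEFAULT_DETECTION = DetectionParams()


@lru_cache(maxsize=8)
def design_lowpass(f3db_hz: float = 30.0, numtaps: int = 51,
                   fs: float = 1000.0) -> np.ndarray:
    """Windowed-sinc FIR taps with gain exactly 10^(-3/20) at ``f3db_hz``.

    ``firwin`` places the half-amplitude point at its cutoff, so the cutoff
    is solved numerically to pin the -3 dB point instead. DC gain is 1 by
    construction (scaled window method).
    """

    def gain_at(fc):
        taps = firwin(numtaps, fc, fs=fs)
        _, h = freqz(taps, worN=[f3db_hz], fs=fs)
        return float(np.abs(h[0])) - GAIN_3DB

    fc = brentq(gain_at, f3db_hz * 0.5, f3db_hz * 3.0, xtol=1e-6)
    return firwin(numtaps, fc, fs=fs)


@dataclass
class FilteredTrace:
    """Smoothed positions with velocity/acceleration and validity mask."""

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    valid: np.ndarray
    pupil: np.ndarray


def _zero_phase_filter(sig: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with no phase shift (centered convolution,
    edge-replicated padding)."""
    half = len(taps) // 2
    padded = np.concatenate([np.full(half, sig[0]), sig, np.full(half, sig[-1])])
    return np.convolve(padded, taps, mode="valid")


def _runs(mask: np.ndarray):
    """Start/stop (inclusive) indices of maximal True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask) - 1)
    return list(zip(starts, stops))


def blink_mask(pupil: np.ndarray, pad_ms: int) -> np.ndarray:
    """True over pupil = 0 runs extended by ``pad_ms`` on both sides."""
    m = pupil <= 0
    out = m.copy()
    for a, b in _runs(m):
        out[max(0, a - pad_ms):b + pad_ms + 1] = True
    return out


def smooth(trial: GazeTrial, params: DetectionParams = DEFAULT_DETECTION) -> FilteredTrace:
    """Low-pass filter positions (zero phase, unit DC gain).

    Blink samples (pupil = 0, padded) are linearly interpolated before
    filtering so the gaps do not leak NaNs into neighbouring samples; the
    returned ``valid`` mask marks them invalid regardless.
    """
    t = np.asarray(trial.time_ms)
    if len(t) < 3 or (np.diff(t) != 1).any():
        raise ValueError("expected a contiguous 1 kHz trace (1 ms samples)")
    invalid = blink_mask(np.asarray(trial.pupil, float), params.blink_pad_ms)
    invalid |= ~np.isfinite(trial.x) | ~np.isfinite(trial.y)
    taps = design_lowpass(params.f3db_hz, params.numtaps)

    def prep(sig):
        sig = np.asarray(sig, float).copy()
        if invalid.all():
            return np.zeros_like(sig)
        if invalid.any():
            good = ~invalid
            sig[invalid] = np.interp(t[invalid], t[good], sig[good])
        return _zero_phase_filter(sig, taps)

    x, y = prep(trial.x), prep(trial.y)
    trace = FilteredTrace(t, x, y, np.zeros_like(x), np.zeros_like(x),
                          np.zeros_like(x), np.zeros_like(x), ~invalid,
                          np.asarray(trial.pupil, float))
    return differentiate(trace, params)


def differentiate(trace: FilteredTrace,
                  params: DetectionParams = DEFAULT_DETECTION) -> FilteredTrace:
    """Two-point difference velocity and acceleration (deg/s, deg/s^2).

    Central (+/-1 sample) by default; forward difference available via
    ``params.central_difference = False``. Endpoints use one-sided
    differences either way.
    """
    if len(trace.x) < 3:
        raise ValueError("trace too short to differentiate")
    dt = 1e-3

    def diff(p):
        v = np.empty_like(p)
        if params.central_difference:
            v[1:-1] = (p[2:] - p[:-2]) / (2 * dt)
        else:
            v[:-1] = (p[1:] - p[:-1]) / dt
        v[0] = (p[1] - p[0]) / dt
        v[-1] = (p[-1] - p[-2]) / dt
        return v

    trace.vx = diff(trace.x)
    trace.vy = diff(trace.y)
    trace.speed = np.hypot(trace.vx, trace.vy)
    trace.accel = np.hypot(diff(trace.vx), diff(trace.vy))
    return trace


@dataclass
class Saccade:
    onset: int
    offset: int
    x0: float
    y0: float
    x1: float
    y1: float
    klass: str = ""  # "regular" | "micro"

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))


@dataclass
class EventList:
    """Non-overlapping blink/saccade/fixation events for one trial.

    Onsets/offsets are in ms (inclusive). Samples not claimed by any event
    are unclassified margins (too-short fixations, trace edges).
    """

    blinks: list[tuple[int, int]] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    fixations: list[tuple[int, int]] = field(default_factory=list)
    image_id: str = ""
    subject_id: str = ""

    def regular_saccades(self) -> list[Saccade]:
        return [s for s in self.saccades if s.klass == "regular"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in self.blinks:
            rows.append({"event": "blink", "onset": a, "offset": b})
        for s in self.saccades:
            rows.append({"event": "saccade", "onset": s.onset, "offset": s.offset,
                         "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1,
                         "amplitude": s.amplitude, "class": s.klass})
        for a, b in self.fixations:
            rows.append({"event": "fixation", "onset": a, "offset": b})
        frame = pd.DataFrame(rows, columns=["event", "onset", "offset", "x0", "y0",
                                            "x1", "y1", "amplitude", "class"])
        frame.insert(0, "subject_id", self.subject_id)
        frame.insert(1, "image_id", self.image_id)
        return frame.sort_values("onset", kind="stable").reset_index(drop=True)


def segment(trace: FilteredTrace,
            params: DetectionParams = DEFAULT_DETECTION) -> EventList:
    """Segment a filtered trace into blinks, saccades, and fixations."""
    n = len(trace.speed)
    blinks = _runs(~trace.valid)
    claimed = ~trace.valid.copy()

    saccades = []
    fast = (trace.speed > params.v_onset) & trace.valid
    slow_bound = trace.speed < params.v_offset
    for a, b in _runs(fast):
        if b - a + 1 < params.min_saccade_ms:
            continue
        while a > 0 and trace.valid[a - 1] and not slow_bound[a - 1] and not claimed[a - 1]:
            a -= 1
        while b < n - 1 and trace.valid[b + 1] and not slow_bound[b + 1] and not claimed[b + 1]:
            b += 1
        if claimed[a:b + 1].any():
            continue
        claimed[a:b + 1] = True
        saccades.append(
            Saccade(int(a), int(b), float(trace.x[a]), float(trace.y[a]),
                    float(trace.x[b]), float(trace.y[b]))
        )

    fixations = [
        (a, b) for a, b in _runs(~claimed) if b - a + 1 >= params.min_fixation_ms
    ]
    events = EventList(blinks=[(int(a), int(b)) for a, b in blinks],
                       saccades=saccades, fixations=fixations)
    return classify_saccades(events)


def classify_saccades(events: EventList, threshold_deg: float = 1.0) -> EventList:
    """Amplitude split: strictly greater than one degree -> ``regular``,
    otherwise ``micro`` (so exactly 1.0 deg is micro)."""
    for s in events.saccades:
        s.klass = "regular" if s.amplitude > threshold_deg else "micro"
    return events


def detect_events(trial: GazeTrial,
                  params: DetectionParams = DEFAULT_DETECTION) -> EventList:
    """Full per-trial pipeline: smooth -> differentiate -> segment ->
    classify."""
    events = segment(smooth(trial, params), params)
    events.image_id = trial.image_id
    events.subject_id = trial.subject_id
    return events


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------


def read_trial_csv(path, image_id: str = "", subject_id: str = "") -> GazeTrial:
    """Read a per-trial CSV (columns time_ms, x_deg, y_deg, pupil)."""
    return GazeTrial.load_csv(path, image_id=image_id, subject_id=subject_id)


def read_asc_samples(path_or_buffer, image_id: str = "",
                     subject_id: str = "") -> GazeTrial:
    """Read an EyeLink-ASC-like sample stream.

    Tab- or whitespace-separated lines ``timestamp  x  y  pupil`` (x/y in
    degrees here); ``MSG``/``**`` and other non-numeric lines are ignored,
    and missing-data markers ('.') become blink samples (pupil 0).
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    times, xs, ys, ps = [], [], [], []
    for line in io.StringIO(text):
        parts = line.split()
        if len(parts) < 4:
            continue
        try:
            t = int(float(parts[0]))
        except ValueError:
            continue  # MSG, EVENTS, comments ...
        def num(tok):
            try:
                return float(tok)
            except ValueError:
                return np.nan  # '.' = track loss
        x, y, p = num(parts[1]), num(parts[2]), num(parts[3])
        if not np.isfinite(x) or not np.isfinite(y):
            x, y, p = np.nan, np.nan, 0.0
        times.append(t)
        xs.append(x)
        ys.append(y)
        ps.append(p if np.isfinite(p) else 0.0)
    times = np.asarray(times)
    times = times - times[0]
    return GazeTrial(times, np.asarray(xs), np.asarray(ys), np.asarray(ps),
                     image_id=image_id, subject_id=subject_id)
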