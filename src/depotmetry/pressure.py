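"""Pressure-trace analysis.

Insulin pumps deliver the basal rate as discrete impulses (strokes), each
visible as a short transient spike in the tubing pressure.  Two other event
families matter clinically: sustained step-wise elevations (an occlusion of
the infusion set holds pressure high for tens of minutes without triggering
a pump alarm) and shorter elevations that coincide with an air bubble
leaving the cannula into the tissue.

Detection uses a two-scale decomposition of the trace:

* impulses are peaks of the high-pass residual (trace minus a rolling
  median whose window is much wider than an impulse but much narrower than
  a step);
* step elevations are intervals where the rolling median itself stays a
  minimum amplitude above the pre-interval baseline for a minimum duration.

Both detectors work on baseline-relative quantities, so adding a constant
to the whole trace changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import ConfigError, FormatError

#: Default event-detection parameters (exposed because the protocol states none).
IMPULSE_PROMINENCE_MBAR = 10.0
IMPULSE_SEPARATION_S = 60.0
HIGHPASS_WINDOW_S = 60.0
STEP_MIN_AMPLITUDE_MBAR = 50.0
STEP_MIN_DURATION_S = 600.0
STEP_BASELINE_WINDOW_S = 300.0
OCCLUSION_MIN_DURATION_S = 1800.0


@dataclass
class PressureTrace:
    """Sampled in-line pressure signal."""

    time_s: np.ndarray
    pressure_mbar: np.ndarray
    sampling_hz: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_mbar = np.asarray(self.pressure_mbar, dtype=float)
        if self.time_s.shape != self.pressure_mbar.shape:
            raise FormatError("time and pressure arrays differ in length")
        if self.time_s.size == 0:
            raise FormatError("empty pressure trace")
        if np.any(np.diff(self.time_s) <= 0):
            raise FormatError("time_s must be strictly increasing")
        if np.any(~np.isfinite(self.pressure_mbar)):
            raise FormatError("pressure trace contains NaN/inf")
        if self.sampling_hz <= 0:
            raise ConfigError("sampling_hz must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PressureTrace":
        df = pd.read_csv(path)
        if not {"time_s", "pressure_mbar"} <= set(df.columns):
            raise FormatError(
                "pressure CSV needs columns time_s,pressure_mbar")
        t = df["time_s"].to_numpy(dtype=float)
        hz = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        return cls(time_s=t,
                   pressure_mbar=df["pressure_mbar"].to_numpy(dtype=float),
                   sampling_hz=hz)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "time_s": self.time_s,
            "pressure_mbar": self.pressure_mbar,
        }).to_csv(path, index=False, float_format="%.6g")


@dataclass
class StepEvent:
    """A sustained step-wise pressure elevation."""

    start_s: float
    duration_s: float
    peak_mbar: float
    amplitude_mbar: float
    occlusion: bool = False

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class PressureEvents:
    """Detected impulses, step elevations and the bubble sync table."""

    impulse_times_s: list[float] = field(default_factory=list)
    steps: list[StepEvent] = field(default_factory=list)
    sync_table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "impulse_times_s": list(map(float, self.impulse_times_s)),
            "steps": [asdict(s) for s in self.steps],
            "sync_table": self.sync_table,
        }


def _odd_window(seconds: float, hz: float) -> int:
    n = max(3, int(round(seconds * hz)))
    return n + 1 - n % 2


def rolling_median(p: np.ndarray, window_s: float, hz: float) -> np.ndarray:
    """Centered rolling median; the low-pass half of the decomposition."""
    return ndimage.median_filter(p, size=_odd_window(window_s, hz),
                                 mode="nearest")


def detect_impulses(
    trace: PressureTrace,
    min_prominence_mbar: float = IMPULSE_PROMINENCE_MBAR,
    min_separation_s: float = IMPULSE_SEPARATION_S,
    highpass_window_s: float = HIGHPASS_WINDOW_S,
    smooth_window_s: float = 1.0,
) -> list[float]:
    """Times (s) of pump impulses: prominent peaks of the high-pass residual.

    The residual is averaged over ``smooth_window_s`` (roughly matched to
    the sub-second rise of a pump stroke) before peak picking, which
    suppresses sample-level sensor noise without displacing the peaks.
    """
    p = trace.pressure_mbar
    residual = p - rolling_median(p, highpass_window_s, trace.sampling_hz)
    w = max(1, int(round(smooth_window_s * trace.sampling_hz)))
    if w > 1:
        residual = ndimage.uniform_filter1d(residual, w, mode="nearest")
    distance = max(1, int(round(min_separation_s * trace.sampling_hz)))
    peaks, _ = signal.find_peaks(
        residual, prominence=min_prominence_mbar,
        height=min_prominence_mbar / 2.0, distance=distance)
    return [float(trace.time_s[i]) for i in peaks]


def detect_step_elevations(
    trace: PressureTrace,
    baseline_window_s: float = STEP_BASELINE_WINDOW_S,
    min_amplitude_mbar: float = STEP_MIN_AMPLITUDE_MBAR,
    min_duration_s: float = STEP_MIN_DURATION_S,
    smooth_window_s: float = HIGHPASS_WINDOW_S,
    occlusion_min_duration_s: float = OCCLUSION_MIN_DURATION_S,
) -> list[StepEvent]:
    """Detect sustained step-wise elevations of the low-pass component.

    Candidate intervals are maximal runs where the rolling median exceeds
    the global (median) baseline by ``min_amplitude_mbar``; each candidate
    is then re-validated against a local baseline estimated from the
    ``baseline_window_s`` of low-pass signal immediately preceding its
    onset, and kept if it stays elevated for at least ``min_duration_s``.
    Transient impulses never qualify: they are removed by the rolling
    median as long as ``min_duration_s`` far exceeds the impulse width.
    """
    p = trace.pressure_mbar
    hz = trace.sampling_hz
    smooth = rolling_median(p, smooth_window_s, hz)
    global_base = float(np.median(smooth))

    elevated = (smooth - global_base) >= min_amplitude_mbar
    labels, n = ndimage.label(elevated)
    events: list[StepEvent] = []
    for k in range(1, n + 1):
        idx = np.nonzero(labels == k)[0]
        i0, i1 = int(idx[0]), int(idx[-1])
        nbase = max(1, int(round(baseline_window_s * hz)))
        pre = smooth[max(0, i0 - nbase):i0]
        base = float(np.median(pre)) if pre.size else global_base
        peak = float(np.max(smooth[i0:i1 + 1]))
        amplitude = peak - base
        if amplitude < min_amplitude_mbar:
            continue
        duration = float(trace.time_s[i1] - trace.time_s[i0]) + 1.0 / hz
        if duration < min_duration_s:
            continue
        events.append(StepEvent(
            start_s=float(trace.time_s[i0]),
            duration_s=duration,
            peak_mbar=peak,
            amplitude_mbar=amplitude,
            occlusion=duration >= occlusion_min_duration_s,
        ))
    return events


def match_elevations_to_bubbles(
    steps: Sequence[StepEvent],
    frame_times_min: Sequence[float],
    bubble_flags: Sequence[bool],
    frame_interval_min: Optional[float] = None,
) -> list[dict]:
    """Match each elevation onset to the frame interval containing it.

    For every step the table reports the 1-based frame whose acquisition
    interval contains the onset and whether an air bubble was present in
    the cannula during the *previous* frame (elevations are expected to
    follow the bubble's arrival in the tissue within one 5-min interval).
    Onsets outside the session window are reported unmatched.
    """
    times = np.asarray(frame_times_min, dtype=float)
    flags = list(bubble_flags)
    if times.size != len(flags):
        raise FormatError("frame_times_min and bubble_flags differ in length")
    if frame_interval_min is None:
        frame_interval_min = float(np.median(np.diff(times))) \
            if times.size > 1 else 5.0

    table = []
    for s in steps:
        onset_min = s.start_s / 60.0
        j = int(np.searchsorted(times, onset_min + 1e-9) - 1)
        in_session = 0 <= j < times.size and \
            onset_min < times[-1] + frame_interval_min
        entry = {
            "onset_s": s.start_s,
            "onset_min": onset_min,
            "frame_index": j + 1 if in_session else None,
            "bubble_in_prior_frame": bool(flags[j - 1])
            if in_session and j >= 1 else False,
            "matched": bool(flags[j - 1]) if in_session and j >= 1 else False,
        }
        table.append(entry)
    return table


def summarize_sync(table: Sequence[dict]) -> dict:
    matched = sum(1 for e in table if e["matched"])
    return {"n_elevations": len(table), "matched": matched,
            "unmatched": len(table) - matched}
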