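"""Per-cycle impedance estimation and intra-breath resistance sampling.

The processing chain for one recording is:

1. ``separate_components`` — split the measured signals into a low-frequency
   breathing flow (< 2 Hz) and the oscillatory pressure/flow around the
   forcing frequency (2-8 Hz band), with zero-phase filters on both channels.
2. ``estimate_impedance_series`` — estimate the complex impedance at the
   forcing frequency in short sliding windows (default one forcing cycle) by
   least-squares projection of both channels onto {sin, cos}; resistance is
   the real part, reactance the imaginary part.
3. ``segment_breaths`` — delimit breaths by hysteresis zero-crossings of the
   breathing flow; inspiration is the positive-flow phase.
4. ``reject_artifacts`` — flag breaths contaminated by flow spikes, leaks
   (collapsed oscillatory pressure), non-physical resistance values, or too
   many low-quality windows.
5. ``breath_resistance`` — average the per-window resistance over the full
   breath, the full inspiration, and the central 20-80% of inspiration
   (mid-inspiratory sampling).

All indices are 0-based with half-open intervals; times are seconds from
recording start; inspiratory flow is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from ._signal import bandpass, lowpass
from .recording import Recording


class ProcessingError(ValueError):
    """Recording unusable for resistance estimation."""


class RejectReason(str, Enum):
    NONE = "none"
    DURATION = "duration"
    INSP_FRACTION = "insp_fraction"
    FLOW_SPIKE = "flow_spike"
    LEAK = "leak"
    NON_PHYSICAL_R = "non_physical_R"
    LOW_QUALITY = "low_quality"


@dataclass
class ProcessingConfig:
    """Thresholds of the processing chain (all tunable)."""

    forcing_freq: float = 5.0  # Hz
    lowpass_hz: float = 2.0  # breathing-flow cutoff
    band_hz: tuple[float, float] = (2.0, 8.0)  # oscillatory pass band
    window_cycles: int = 1  # demodulation window, forcing cycles
    hop_cycles: int = 1
    q_amp_floor: float = 0.02  # L/s; below -> low-quality window
    flow_limit: float = 3.0  # L/s; above -> flow spike
    leak_fraction: float = 0.5  # of recording-median oscillatory P amplitude
    r_min: float = 0.0  # cmH2O·s/L, exclusive lower bound
    r_max: float = 20.0  # cmH2O·s/L
    max_lowq_fraction: float = 0.2  # per breath
    breath_duration_s: tuple[float, float] = (1.5, 15.0)
    insp_fraction_bounds: tuple[float, float] = (0.2, 0.8)
    hysteresis_fraction: float = 0.05  # of recording flow amplitude
    hysteresis_window_s: float = 0.2
    mid_insp_window: tuple[float, float] = (0.2, 0.8)  # fraction of inspiration
    min_phase_samples: int = 2


@dataclass
class BreathSegment:
    """One detected breath: [start, end) samples, inspiration [start, insp_end)."""

    start: int
    insp_end: int
    end: int
    accepted: bool = True
    reason: RejectReason = RejectReason.NONE

    def __post_init__(self) -> None:
        if not self.start < self.insp_end <= self.end:
            raise ProcessingError(
                f"invalid breath bounds {self.start} < {self.insp_end} <= {self.end}"
            )

    def duration(self, fs: float) -> float:
        return (self.end - self.start) / fs

    def insp_fraction(self) -> float:
        return (self.insp_end - self.start) / (self.end - self.start)


@dataclass
class BreathResistance:
    """Per-breath resistance under the three intra-breath sampling schemes."""

    breath: int
    R_full_breath: float
    R_full_insp: float
    R_mid_insp: float


# ---------------------------------------------------------------------------
# component separation


def separate_components(
    rec: Recording, config: ProcessingConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a recording into breathing flow and oscillatory pressure/flow.

    Breathing flow is a zero-phase low-pass of the measured flow; the
    oscillatory components are zero-phase band-passed around the forcing
    frequency.  Zero-phase filtering on both channels guarantees no group
    delay between pressure and flow, which would bias the phase (reactance).
    """
    config = config or ProcessingConfig()
    fs = rec.sampling_rate
    min_len = int(10 * fs / config.lowpass_hz)  # ~10 filter lengths
    if rec.n_samples < min_len:
        raise ProcessingError(
            f"recording too short for filtering ({rec.n_samples} < {min_len} samples)"
        )
    q_breath = lowpass(rec.flow, fs, config.lowpass_hz)
    p_osc = bandpass(rec.pressure, fs, config.band_hz)
    q_osc = bandpass(rec.flow, fs, config.band_hz)
    return q_breath, p_osc, q_osc


# ---------------------------------------------------------------------------
# impedance estimation


def _lsq_phasors(x: np.ndarray, cosw: np.ndarray, sinw: np.ndarray,
                 idx: np.ndarray) -> np.ndarray:
    """Complex amplitude of x at the forcing frequency per window.

    Solves, for each window, the 2x2 normal equations of the least-squares
    fit x(t) ~ a·cos(w t) + b·sin(w t); the phasor is a - i·b so that
    x(t) = Re[(a - i b)·e^{i w t}].
    """
    c = cosw[idx]
    s = sinw[idx]
    xw = x[idx]
    cc = np.einsum("ij,ij->i", c, c)
    ss = np.einsum("ij,ij->i", s, s)
    cs = np.einsum("ij,ij->i", c, s)
    bx1 = np.einsum("ij,ij->i", c, xw)
    bx2 = np.einsum("ij,ij->i", s, xw)
    det = cc * ss - cs * cs
    a = (ss * bx1 - cs * bx2) / det
    b = (cc * bx2 - cs * bx1) / det
    return a - 1j * b


def estimate_impedance_series(
    p_osc: np.ndarray,
    q_osc: np.ndarray,
    fs: float,
    config: ProcessingConfig | None = None,
) -> pd.DataFrame:
    """Windowed single-frequency impedance estimates.

    Returns a DataFrame with one row per window: ``t_center`` (s), ``R`` and
    ``X`` (cmH2O·s/L), ``p_amp``/``q_amp`` (oscillatory amplitudes) and a
    boolean ``quality`` flag.  Windows whose oscillatory flow amplitude falls
    below the configured floor are flagged low-quality and their R/X withheld
    (NaN) — a near-zero denominator makes the ratio meaningless.
    """
    config = config or ProcessingConfig()
    f0 = config.forcing_freq
    w = int(round(fs * config.window_cycles / f0))
    hop = int(round(fs * config.hop_cycles / f0))
    n = len(p_osc)
    if len(q_osc) != n:
        raise ProcessingError("pressure and flow arrays must have equal length")
    if n < w:
        raise ProcessingError("recording shorter than one demodulation window")
    n_win = (n - w) // hop + 1
    idx = np.arange(w)[None, :] + hop * np.arange(n_win)[:, None]

    t = np.arange(n) / fs
    wrad = 2 * np.pi * f0
    cosw = np.cos(wrad * t)
    sinw = np.sin(wrad * t)
    P = _lsq_phasors(p_osc, cosw, sinw, idx)
    Q = _lsq_phasors(q_osc, cosw, sinw, idx)

    q_amp = np.abs(Q)
    quality = q_amp >= config.q_amp_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(quality, P / np.where(q_amp > 0, Q, np.nan), np.nan)
    t_center = (idx[:, 0] + (w - 1) / 2) / fs
    return pd.DataFrame(
        {
            "t_center": t_center,
            "R": np.real(Z),
            "X": np.imag(Z),
            "p_amp": np.abs(P),
            "q_amp": q_amp,
            "quality": quality,
        }
    )


# ---------------------------------------------------------------------------
# breath segmentation


def _validated_crossings(
    flow: np.ndarray, fs: float, amp: float, config: ProcessingConfig, rising: bool
) -> np.ndarray:
    """Zero-crossing indices with hysteresis validation.

    A crossing counts only if the signal genuinely swings past ±hysteresis
    within ``hysteresis_window_s`` on both sides — tiny oscillations around
    zero are ignored.
    """
    s = flow if rising else -flow
    cand = list(np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0)) + 1)
    win = max(1, int(round(config.hysteresis_window_s * fs)))
    thr = config.hysteresis_fraction * amp
    # a recording that starts right at a phase onset has no preceding
    # opposite-sign samples; admit index 0 when it sits near zero and rises
    if abs(s[0]) <= thr and (not cand or cand[0] != 0):
        cand.insert(0, 0)
    keep = []
    for i in cand:
        after = s[i : i + win]
        before = s[max(0, i - win) : i]
        before_ok = before.min() <= -thr if before.size else i == 0
        if after.size and after.max() >= thr and before_ok:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def segment_breaths(
    q_breath: np.ndarray, fs: float, config: ProcessingConfig | None = None
) -> list[BreathSegment]:
    """Delimit breaths on the low-passed breathing flow.

    Breath onsets are negative-to-positive zero crossings (inspiration start);
    the inspiratory phase ends at the subsequent positive-to-negative
    crossing.  Breaths with implausible duration or inspiratory fraction are
    kept but marked rejected with a reason.

    Raises
    ------
    ProcessingError
        If fewer than 3 complete breaths are detected (recording unusable).
    """
    config = config or ProcessingConfig()
    amp = float(np.percentile(np.abs(q_breath), 98))
    if amp < 1e-9:
        raise ProcessingError("no breathing detected (flat flow signal)")
    ups = _validated_crossings(q_breath, fs, amp, config, rising=True)
    downs = _validated_crossings(q_breath, fs, amp, config, rising=False)
    if len(ups) < 2:
        raise ProcessingError("fewer than 3 breaths detected")

    segments: list[BreathSegment] = []
    lo_d, hi_d = config.breath_duration_s
    lo_f, hi_f = config.insp_fraction_bounds
    for s0, s1 in zip(ups[:-1], ups[1:]):
        mid = downs[(downs > s0) & (downs < s1)]
        if mid.size == 0:
            continue
        seg = BreathSegment(start=int(s0), insp_end=int(mid[0]), end=int(s1))
        if not lo_d <= seg.duration(fs) <= hi_d:
            seg.accepted = False
            seg.reason = RejectReason.DURATION
        elif not lo_f <= seg.insp_fraction() <= hi_f:
            seg.accepted = False
            seg.reason = RejectReason.INSP_FRACTION
        segments.append(seg)
    if len(segments) < 3:
        raise ProcessingError("fewer than 3 breaths detected")
    return segments


# ---------------------------------------------------------------------------
# artifact rejection


def reject_artifacts(
    segments: list[BreathSegment],
    samples: pd.DataFrame,
    rec: Recording,
    config: ProcessingConfig | None = None,
) -> list[BreathSegment]:
    """Flag artifact-contaminated breaths (flags only; nothing is dropped).

    A breath is rejected when any of: absolute flow exceeds the spike limit;
    its median oscillatory-pressure amplitude falls below half the recording
    median (leak); any resistance sample is non-physical (<= 0 or above the
    ceiling); or more than the allowed fraction of its windows is low-quality.
    """
    config = config or ProcessingConfig()
    fs = rec.sampling_rate
    p_med = float(np.nanmedian(samples["p_amp"]))
    t_c = samples["t_center"].to_numpy()
    r_vals = samples["R"].to_numpy()
    p_amp = samples["p_amp"].to_numpy()
    quality = samples["quality"].to_numpy()

    out: list[BreathSegment] = []
    for seg in segments:
        seg = BreathSegment(seg.start, seg.insp_end, seg.end, seg.accepted, seg.reason)
        if seg.accepted:
            t0, t1 = seg.start / fs, seg.end / fs
            in_breath = (t_c >= t0) & (t_c < t1)
            if np.max(np.abs(rec.flow[seg.start : seg.end])) > config.flow_limit:
                seg.accepted, seg.reason = False, RejectReason.FLOW_SPIKE
            elif (
                in_breath.any()
                and np.median(p_amp[in_breath]) < config.leak_fraction * p_med
            ):
                seg.accepted, seg.reason = False, RejectReason.LEAK
            elif np.any(
                (r_vals[in_breath & quality] <= config.r_min)
                | (r_vals[in_breath & quality] > config.r_max)
            ):
                seg.accepted, seg.reason = False, RejectReason.NON_PHYSICAL_R
            elif (
                in_breath.any()
                and np.mean(~quality[in_breath]) > config.max_lowq_fraction
            ):
                seg.accepted, seg.reason = False, RejectReason.LOW_QUALITY
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# intra-breath sampling


def breath_resistance(
    segment: BreathSegment,
    samples: pd.DataFrame,
    fs: float,
    config: ProcessingConfig | None = None,
) -> BreathResistance:
    """Average resistance over the three intra-breath sampling schemes.

    Mid-inspiration is defined on the TIME fraction of inspiration: windows
    whose centre lies in [t_insp_start + 0.2·T_insp, t_insp_start + 0.8·T_insp).
    Each scheme requires at least ``min_phase_samples`` good windows,
    otherwise its value is NaN.
    """
    config = config or ProcessingConfig()
    t_c = samples["t_center"].to_numpy()
    r = samples["R"].to_numpy()
    good = samples["quality"].to_numpy() & np.isfinite(r)

    t0, t_ie, t1 = segment.start / fs, segment.insp_end / fs, segment.end / fs
    t_insp = t_ie - t0
    lo_f, hi_f = config.mid_insp_window
    windows = {
        "full_breath": (t0, t1),
        "full_insp": (t0, t_ie),
        "mid_insp": (t0 + lo_f * t_insp, t0 + hi_f * t_insp),
    }
    vals: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        sel = good & (t_c >= lo) & (t_c < hi)
        vals[name] = (
            float(np.mean(r[sel])) if sel.sum() >= config.min_phase_samples else np.nan
        )
    return BreathResistance(
        breath=0,
        R_full_breath=vals["full_breath"],
        R_full_insp=vals["full_insp"],
        R_mid_insp=vals["mid_insp"],
    )


# ---------------------------------------------------------------------------
# per-recording orchestration


def process_recording(
    rec: Recording, config: ProcessingConfig | None = None
) -> pd.DataFrame:
    """Run the full chain on one recording.

    Returns the per-breath table with columns ``subject, day, breath,
    accepted, reason, R_full_breath, R_full_insp, R_mid_insp``; resistance
    values are present only for accepted breaths.
    """
    config = config or ProcessingConfig()
    q_breath, p_osc, q_osc = separate_components(rec, config)
    samples = estimate_impedance_series(p_osc, q_osc, rec.sampling_rate, config)
    segments = segment_breaths(q_breath, rec.sampling_rate, config)
    segments = reject_artifacts(segments, samples, rec, config)

    rows = []
    for k, seg in enumerate(segments):
        if seg.accepted:
            br = breath_resistance(seg, samples, rec.sampling_rate, config)
            r_fb, r_fi, r_mi = br.R_full_breath, br.R_full_insp, br.R_mid_insp
        else:
            r_fb = r_fi = r_mi = np.nan
        rows.append(
            {
                "subject": rec.subject_id,
                "day": rec.day_index,
                "breath": k,
                "t_start": seg.start / rec.sampling_rate,
                "t_end": seg.end / rec.sampling_rate,
                "accepted": seg.accepted,
                "reason": seg.reason.value,
                "R_full_breath": r_fb,
                "R_full_insp": r_fi,
                "R_mid_insp": r_mi,
            }
        )
    return pd.DataFrame(rows)
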