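"""Zero-phase spectral filtering shared by the simulator and the processor.

Both channels of a recording must pass through identical zero-phase filters so
that no group delay is introduced between pressure and flow — any relative
delay would alias directly into the estimated reactance.  Filtering is done in
the frequency domain with raised-cosine transition bands: the response is
exactly zero phase by construction, and for recordings spanning whole numbers
of forcing and breathing cycles (2 min at 5 Hz) the separation is exact, with
no start-up transient.
"""

from __future__ import annotations

import numpy as np


def _smooth_step(f: np.ndarray, edge: float, width: float) -> np.ndarray:
    """Raised-cosine 0 -> 1 transition centred on ``edge``, total span ``width``."""
    z = np.clip((f - edge) / width + 0.5, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * z))


def _apply_response(x: np.ndarray, fs: float, response: np.ndarray) -> np.ndarray:
    return np.fft.irfft(np.fft.rfft(x) * response, len(x))


def lowpass(
    x: np.ndarray, fs: float, cutoff_hz: float, transition_hz: float = 1.0
) -> np.ndarray:
    """Zero-phase low-pass: unity below the cutoff, raised-cosine roll-off."""
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    return _apply_response(x, fs, 1.0 - _smooth_step(f, cutoff_hz, transition_hz))


def bandpass(
    x: np.ndarray,
    fs: float,
    band_hz: tuple[float, float],
    transition_hz: float = 1.0,
) -> np.ndarray:
    """Zero-phase band-pass with raised-cosine edges at the band limits."""
    lo, hi = band_hz
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    resp = _smooth_step(f, lo, transition_hz) * (
        1.0 - _smooth_step(f, hi, 2.0 * transition_hz)
    )
    return _apply_response(x, fs, resp)
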