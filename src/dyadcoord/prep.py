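"""Per-participant signal preparation.

Pupil diameter from a wearable eye tracker is dominated by blink loss and
measurement spikes; the cleaning pipeline here applies, in order, a
confidence gate, an absolute diameter gate, a rolling-standard-deviation
gate, single-sample spike removal, removal of short valid clusters, linear
interpolation across the resulting gaps, and zero-phase low-pass filtering.
Brightness-driven pupil changes are removed by regressing diameter on screen
luminance.  Head motion is summarized as motion energy: squared velocity
integrated over a trailing sliding window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import SignalTrace

log = logging.getLogger(__name__)


@dataclass
class PupilCleanConfig:
    """Thresholds for the pupil-cleaning steps.

    Defaults follow pupillometry conventions: samples below 0.6 tracker
    confidence or outside 1.5-9 mm are physiologically implausible; the
    rolling-SD and spike gates catch partial-blink artifacts; valid clusters
    shorter than ~1/12 s between gaps are tracker noise; 4 Hz retains the
    pupil's autonomic band.
    """

    confidence_min: float = 0.6
    diameter_range: tuple[float, float] = (1.5, 9.0)
    sd_gate: float = 3.0
    spike_gate: float = 0.1  # max |delta| per sample, mm
    min_cluster: float = 1.0 / 12.0  # seconds
    lowpass_cutoff: float = 4.0  # Hz
    lowpass_order: int = 3
    sd_window: float = 1.0  # seconds, rolling-SD gate window

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range
        if not lo < hi:
            raise ValueError("diameter_range must satisfy min < max")
        for name in ("confidence_min", "sd_gate", "spike_gate", "min_cluster", "lowpass_cutoff"):
            if getattr(self, name) <= 0 and name != "confidence_min":
                raise ValueError(f"{name} must be > 0")


@dataclass
class CleanResult:
    trace: SignalTrace
    interpolated: np.ndarray  # mask of samples filled by interpolation
    low_quality: bool
    invalid_fraction: float


def _drop_short_clusters(valid: np.ndarray, min_len: int) -> np.ndarray:
    """Invalidate runs of valid samples shorter than ``min_len``."""
    if min_len <= 1 or not valid.any():
        return valid
    out = valid.copy()
    idx = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start < min_len:
            out[start:stop] = False
    return out


def clean_pupil(
    trace: SignalTrace,
    confidence: SignalTrace,
    config: PupilCleanConfig | None = None,
) -> CleanResult:
    """Run the full pupil-cleaning cascade.

    Returns a fully valid trace (gaps linearly interpolated, then low-pass
    filtered) plus the mask of interpolated samples.  If more than half of
    the samples are invalidated by the gates the result is flagged
    low-quality but still returned, so the caller can decide whether the
    session contributes to pupil coordination.
    """
    config = config or PupilCleanConfig()
    if len(trace) == 0:
        raise ValueError("empty pupil trace")
    if len(confidence) != len(trace) or not np.allclose(confidence.t, trace.t):
        raise ValueError("pupil and confidence traces must share timestamps")

    x = trace.values.astype(float).copy()
    valid = trace.valid.copy()

    # 1. confidence gate
    valid &= confidence.values >= config.confidence_min
    # 2. absolute diameter gate
    lo, hi = config.diameter_range
    with np.errstate(invalid="ignore"):
        valid &= (x >= lo) & (x <= hi) & np.isfinite(x)

    # 3. rolling-SD gate (centered window; invalid samples excluded)
    win = max(3, int(round(config.sd_window * trace.rate_hint)) | 1)
    s = pd.Series(np.where(valid, x, np.nan))
    roll = s.rolling(win, center=True, min_periods=3)
    mu, sd = roll.mean().to_numpy(), roll.std().to_numpy()
    with np.errstate(invalid="ignore"):
        outlier = np.abs(x - mu) > config.sd_gate * sd
    valid &= ~np.where(np.isfinite(sd) & (sd > 0), outlier, False)

    # 4. spike removal: jumps larger than spike_gate per sample on both flanks
    if x.size >= 3:
        d_prev = np.abs(np.diff(x, prepend=x[0]))
        d_next = np.abs(np.diff(x, append=x[-1]))
        valid &= ~((d_prev > config.spike_gate) & (d_next > config.spike_gate))

    # 5. drop short valid clusters
    min_len = max(1, int(round(config.min_cluster * trace.rate_hint)))
    valid = _drop_short_clusters(valid, min_len)

    invalid_fraction = 1.0 - valid.mean() if valid.size else 1.0
    low_quality = invalid_fraction > 0.5
    if low_quality:
        log.warning("pupil trace low-quality: %.0f%% samples invalid", 100 * invalid_fraction)

    # 6. linear interpolation across gaps
    interpolated = ~valid
    if valid.any():
        y = np.interp(trace.t, trace.t[valid], x[valid])
    else:
        y = np.zeros_like(x)

    # 7. zero-phase low-pass
    nyq = trace.rate_hint / 2.0
    if 0 < config.lowpass_cutoff < nyq and y.size > 3 * (config.lowpass_order + 1):
        sos = sps.butter(config.lowpass_order, config.lowpass_cutoff / nyq, output="sos")
        y = sps.sosfiltfilt(sos, y)

    out = SignalTrace(trace.t.copy(), y, trace.rate_hint)
    return CleanResult(out, interpolated, low_quality, float(invalid_fraction))


def regress_out_brightness(pupil: SignalTrace, luminance: SignalTrace) -> SignalTrace:
    """Remove the luminance-driven component of pupil diameter by OLS.

    Residuals of ``pupil ~ 1 + luminance`` are returned; they are exactly
    uncorrelated with luminance.  A constant luminance series makes the
    slope unidentifiable, in which case the mean-centered pupil is returned.
    """
    if len(pupil) != len(luminance) or not np.allclose(pupil.t, luminance.t):
        raise ValueError("pupil and luminance must be aligned on the same timestamps")
    y = pupil.values
    x = luminance.values
    if np.ptp(x) == 0:
        log.info("constant luminance: brightness regression degenerate, mean-centering")
        resid = y - y.mean()
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
    return SignalTrace(pupil.t.copy(), resid, pupil.rate_hint, pupil.valid.copy())


def motion_energy(velocity: SignalTrace, window: float = 6.0, step: int = 1) -> SignalTrace:
    """Motion energy: squared velocity integrated over a trailing window.

    Each output sample k is ``sum(v[k : k + w]**2) * dt`` for a window of
    ``w = round(window * rate)`` samples, advanced by ``step`` samples, so a
    trace of n samples yields ``n - w + 1`` energy values (step 1).  Output
    timestamps mark the window end.
    """
    rate = velocity.rate_hint
    w = int(round(window * rate))
    if len(velocity) < w:
        raise ValueError(f"trace shorter than one {window} s window")
    dt = 1.0 / rate
    v2 = velocity.values.astype(float) ** 2
    csum = np.concatenate(([0.0], np.cumsum(v2)))
    e = (csum[w:] - csum[:-w]) * dt
    t = velocity.t[w - 1 :]
    if step > 1:
        e, t = e[::step], t[::step]
    return SignalTrace(t.copy(), e, rate / step)
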