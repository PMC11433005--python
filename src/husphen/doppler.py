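"""Renal pulse-wave Doppler indices and cortical morphometrics.

Extracts the peak systolic velocity (PSV), end-diastolic velocity (EDV),
cycle-mean velocity (MV) and velocity-time integral (VTI) from an arterial
velocity trace and derives the resistive index RI = (PSV - EDV)/PSV and the
pulsatility index PI = (PSV - EDV)/MV, averaging over three to four cardiac
cycles.

EDV is read at the foot of each systolic upstroke (true end-diastole), so a
trace whose diastolic run-off dips below the pre-upstroke velocity still
yields the intended EDV. Noisy spectra are low-pass filtered with a
period-scaled moving average before feature extraction (engaged
automatically when the sample-to-sample residual indicates noise, and
bypassed entirely on clean traces so noiseless extraction stays exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .errors import (
    DomainError,
    ExtractionError,
    InsufficientCyclesError,
    MissingDataError,
    ValidationError,
)

#: Minimum peak separation as a fraction of the expected cardiac period.
MIN_PEAK_SEP_FRAC = 0.6

#: Cycles entering the averaged indices: min(4, detected), at least 3.
MIN_CYCLES = 3
MAX_CYCLES = 4

#: Systolic peaks must rise above this fraction of the trace's full
#: excursion (arterial peaks span the whole amplitude; diastolic noise
#: bumps do not).
PEAK_PROMINENCE_FRAC = 0.5

#: Upstroke-foot detector: a sample belongs to the upstroke while its local
#: slope exceeds this fraction of the steepest slope before the peak.
FOOT_SLOPE_FRAC = 0.25

#: The upstroke foot is searched within this fraction of the period before
#: each peak, so a steep late-diastolic recovery limb is never mistaken for
#: the systolic upsweep.
FOOT_SEARCH_FRAC = 0.20

#: Smoothing window as a fraction of the cardiac period, and the relative
#: noise level (vs peak-to-peak amplitude) above which smoothing engages.
SMOOTH_PERIOD_FRAC = 0.02
NOISE_REL_THRESHOLD = 0.005

#: Moving-maximum envelope window (samples) for spectral-envelope input.
ENVELOPE_WINDOW = 5


@dataclass
class DopplerTrace:
    """A uniformly sampled velocity trace (s, mm/s)."""

    time: np.ndarray
    velocity: np.ndarray
    hr_hint: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.velocity.shape:
            raise ValidationError("time and velocity must be equal-length 1-D")
        if len(self.time) < 4:
            raise ValidationError("trace too short")
        dt = np.diff(self.time)
        if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValidationError("time must be a uniform, increasing grid")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass(frozen=True)
class CycleSet:
    """Detected systolic peaks and the peak-to-peak cycle windows."""

    peaks: np.ndarray               # sample indices of systolic peaks
    windows: list[tuple[int, int]]  # [start, end) peak-to-peak spans

    @property
    def n_cycles(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class DopplerIndices:
    psv: float
    edv: float
    mv: float
    vti: float
    ri: float
    pi: float
    n_cycles_used: int


@dataclass(frozen=True)
class RenalMorphometry:
    cortical_thickness: float   # mm
    bw: float                   # g
    crt_bw: float               # mm/g
    cortex_mean_echo: float | None = None
    cortex_echo_change_from_baseline: float | None = None


def _dominant_hr(trace: DopplerTrace) -> float:
    """Heart rate (bpm) from the dominant spectral peak in 2-20 Hz."""
    v = trace.velocity - trace.velocity.mean()
    freqs = np.fft.rfftfreq(len(v), d=1.0 / trace.sampling_rate)
    power = np.abs(np.fft.rfft(v)) ** 2
    band = (freqs >= 2.0) & (freqs <= 20.0)
    if not band.any() or power[band].max() == 0:
        raise InsufficientCyclesError("no pulsatile component in 2-20 Hz")
    return 60.0 * float(freqs[band][np.argmax(power[band])])


def _noise_sigma(v: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD of diff / sqrt 2)."""
    return 1.4826 * float(np.median(np.abs(np.diff(v)))) / np.sqrt(2.0)


def _prepare(trace: DopplerTrace, envelope: str
             ) -> tuple[np.ndarray, int, float]:
    """Optionally envelope + denoise the trace; returns (v, window, period_s)."""
    v = trace.velocity
    if np.ptp(v) == 0:
        raise InsufficientCyclesError("constant-velocity trace has no cycles")
    # gauge noise on the raw trace: enveloping flattens the residual and
    # would blind the detector
    sigma = _noise_sigma(v)
    if envelope == "movmax":
        v = maximum_filter1d(v, size=ENVELOPE_WINDOW, mode="nearest")
    hr = trace.hr_hint if trace.hr_hint else _dominant_hr(trace)
    period_s = 60.0 / hr
    window = 1
    if sigma > NOISE_REL_THRESHOLD * np.ptp(v):
        window = int(round(SMOOTH_PERIOD_FRAC * period_s
                           * trace.sampling_rate))
        window = max(window + (window + 1) % 2, 3)   # odd, >= 3
        v = uniform_filter1d(v, size=window, mode="nearest")
    return v, window, period_s


def _find_peaks(v: np.ndarray, period_s: float, fs: float) -> np.ndarray:
    distance = max(1, int(round(MIN_PEAK_SEP_FRAC * period_s * fs)))
    prominence = PEAK_PROMINENCE_FRAC * np.ptp(v)
    peaks, _ = signal.find_peaks(v, distance=distance, prominence=prominence)
    if len(peaks) < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"detected {len(peaks)} cycles; at least {MIN_CYCLES} required")
    return peaks


def detect_cycles(trace: DopplerTrace, envelope: str = "raw") -> CycleSet:
    """Locate systolic peaks and the peak-to-peak cycle windows.

    Peaks are local maxima separated by at least ``MIN_PEAK_SEP_FRAC`` of
    the expected cardiac period (heart rate from ``hr_hint`` or the dominant
    spectral peak). Fewer than three peaks raises
    :class:`~husphen.errors.InsufficientCyclesError`.
    """
    v, _, period_s = _prepare(trace, envelope)
    peaks = _find_peaks(v, period_s, trace.sampling_rate)
    windows = [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]
    return CycleSet(np.asarray(peaks), windows)


def _upstroke_foot(v: np.ndarray, peak: int, lo: int, lag: int = 1) -> int:
    """Index of the foot of the systolic upstroke ending at ``peak``.

    Walks backward from the peak while the lag-``lag`` slope stays above
    ``FOOT_SLOPE_FRAC`` of the steepest such slope in the search span, which
    separates the rapid systolic upsweep from any gentle late-diastolic
    recovery or hold preceding it. The lag matches the denoising window so
    the slope estimate stays noise-robust (lag 1 on clean traces).
    """
    lo = max(lo, 0)
    if peak - lo < lag:
        return peak
    idx = np.arange(lo + lag, peak + 1)
    lag_slopes = v[idx] - v[idx - lag]
    max_up = lag_slopes.max()
    if max_up <= 0:
        return peak
    thresh = FOOT_SLOPE_FRAC * max_up
    # anchor mid-upstroke (maximum-slope point) and descend: anchoring at
    # the detected peak is fragile, since noise can shift the peak onto the
    # flat crest where the walk never starts
    i = int(lo + lag + np.argmax(lag_slopes))
    while i - lag >= lo and v[i] - v[i - lag] > thresh:
        i -= 1
    return i


def doppler_indices(
    trace: DopplerTrace,
    envelope: str = "raw",
    mv_mode: str = "median_cycle",
) -> DopplerIndices:
    """Extract PSV, EDV, MV, VTI and the RI/PI indices from a trace.

    PSV and EDV are averaged over min(4, detected) cycles; MV and VTI come
    from one representative (median-PSV) cycle by default, or from all
    complete cycles with ``mv_mode="all"``. ``envelope="movmax"`` applies a
    5-sample moving-maximum envelope for spectral-envelope input.
    """
    if envelope not in ("raw", "movmax"):
        raise ValidationError("envelope must be 'raw' or 'movmax'")
    if mv_mode not in ("median_cycle", "all"):
        raise ValidationError("mv_mode must be 'median_cycle' or 'all'")
    v, window, period_s = _prepare(trace, envelope)
    fs = trace.sampling_rate
    all_peaks = _find_peaks(v, period_s, fs)
    windows_all = list(zip(all_peaks[:-1], all_peaks[1:]))
    dt = 1.0 / fs
    peaks = all_peaks[:MAX_CYCLES]
    n_used = len(peaks)

    psv = float(v[peaks].mean())
    period = int(round(np.median(np.diff(all_peaks))))
    search = int(round(FOOT_SEARCH_FRAC * period))
    edvs = []
    for j, p in enumerate(peaks):
        lo = all_peaks[j - 1] if j > 0 else max(0, p - period)
        lo = max(int(lo), int(p) - search)
        foot = _upstroke_foot(v, int(p), lo, lag=window)
        # read end-diastole clear of the smoothed foot corner; the median
        # over the pre-upstroke span keeps a mis-stopped walk from
        # contaminating the read when a denoising window is active
        b = max(lo + 1, foot - window + 2)
        a = lo if window > 1 else max(lo, foot - 1)
        edvs.append(float(np.median(v[a:b])))
    edv = float(np.mean(edvs))
    if edv > psv:
        raise ExtractionError(f"extracted EDV {edv:.3g} exceeds PSV {psv:.3g}")

    # Representative windows for MV/VTI (peak-to-peak spans cover one period).
    if mv_mode == "all":
        spans = windows_all
    else:
        starts = all_peaks[:-1]
        med = np.argsort(v[starts])[len(starts) // 2]
        spans = [windows_all[int(med)]]
    mvs, vtis = [], []
    for a, b in spans:
        mvs.append(float(v[a:b].mean()))
        vtis.append(float(np.trapezoid(v[a : b + 1], dx=dt)))
    mv = float(np.mean(mvs))
    vti = float(np.mean(vtis))
    return indices_from_features(psv, edv, mv, vti, n_used)


def indices_from_features(psv: float, edv: float, mv: float,
                          vti: float = float("nan"),
                          n_cycles_used: int = 0) -> DopplerIndices:
    """RI and PI from already-extracted waveform features.

    RI = (PSV - EDV)/PSV, PI = (PSV - EDV)/MV; a flat systole (PSV = EDV)
    gives RI = PI = 0 by construction.
    """
    if psv <= 0:
        raise DomainError("PSV must be > 0 for RI/PI")
    ri = (psv - edv) / psv
    if psv == edv:
        pi = 0.0
    else:
        if mv == 0:
            raise DomainError("MV is zero; PI undefined")
        pi = (psv - edv) / mv
    return DopplerIndices(psv, edv, mv, vti, ri, pi, n_cycles_used)


def crt_bw(thickness_mm: float, bw_g: float) -> float:
    """Renal cortical thickness normalized to body weight (mm/g)."""
    if thickness_mm <= 0 or bw_g <= 0:
        raise DomainError("thickness and body weight must be > 0")
    return thickness_mm / bw_g


def cortex_echo_change(series, value_col: str = "cortex_mean_echo",
                       age_col: str = "age_weeks"):
    """Change of renal-cortex echogenicity from the baseline timepoint.

    ``series`` holds one row per timepoint for a single mouse (or is grouped
    upstream); the earliest age is the baseline. Returns the input with a
    ``change_from_baseline`` column; a missing baseline raises
    :class:`~husphen.errors.MissingDataError`.
    """
    import pandas as pd

    if not isinstance(series, pd.DataFrame) or series.empty:
        raise MissingDataError("empty series; baseline timepoint missing")
    out = series.sort_values(age_col).copy()
    baseline = out[value_col].iloc[0]
    if np.isnan(baseline):
        raise MissingDataError("baseline cortex echogenicity is missing")
    out["change_from_baseline"] = out[value_col] - baseline
    return out
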