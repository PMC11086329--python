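"""Heart rate and SpO2 estimation from tri-wavelength PPG.

Conventions follow standard reflectance pulse oximetry practice: the green
channel (most sensitive to superficial, pulsatile blood volume) drives beat
detection and heart rate; the red and infrared channels drive oxygen
saturation through the ratio-of-ratios

    R = (AC_red / DC_red) / (AC_ir / DC_ir),

mapped to percent saturation by the empirical calibration line
SpO2 = 110 - 25 R (slope/intercept replaceable via :class:`SpO2Calibration`).
AC is measured per 5-second window as the RMS of the band-passed component
in a narrow band around the cardiac fundamental; DC as the raw window mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpO2Calibration",
    "VitalsResult",
    "detect_beats",
    "estimate_hr",
    "estimate_spo2",
    "paired_error_table",
    "estimate_vitals",
    "ratio_for_spo2",
]

HR_UNDEFINED = float("nan")


@dataclass(frozen=True)
class SpO2Calibration:
    """Linear ratio-of-ratios calibration SpO2 = intercept + slope * R."""

    intercept: float = 110.0
    slope: float = -25.0
    clamp: tuple[float, float] = (70.0, 100.0)

    def spo2(self, r: float | np.ndarray) -> float | np.ndarray:
        return np.clip(self.intercept + self.slope * np.asarray(r), *self.clamp)

    def ratio(self, spo2: float) -> float:
        """Inverse of the calibration line (used by the simulator)."""
        return (spo2 - self.intercept) / self.slope


DEFAULT_CALIBRATION = SpO2Calibration()


def ratio_for_spo2(spo2: float, calibration: SpO2Calibration = DEFAULT_CALIBRATION) -> float:
    return calibration.ratio(spo2)


@dataclass
class VitalsResult:
    hr_bpm: float
    spo2_pct: float
    n_beats: int
    quality_flags: list[str] = field(default_factory=list)


def detect_beats(
    green: np.ndarray,
    fs: float,
    refractory_s: float = 0.33,
    prominence_frac: float = 0.5,
    flags: list[str] | None = None,
) -> np.ndarray:
    """Detect systolic peak indices in a filtered, baseline-removed signal.

    A refractory period of 0.33 s caps detectable rate at ~180 bpm; the
    prominence threshold adapts to the signal as a fraction of its rolling
    peak-to-peak amplitude (2 s blocks, median across blocks).  The 0.5
    default fraction rejects dicrotic waves (relative amplitude <= 0.5 of
    the systolic peak) at any heart rate.
    """
    x = np.asarray(green, dtype=float)
    if flags is None:
        flags = []
    if x.size == 0 or np.ptp(x) < 1e-12:
        flags.append("flat_signal")
        return np.zeros(0, dtype=int)
    block = max(int(2.0 * fs), 1)
    n_blocks = max(x.size // block, 1)
    amps = [np.ptp(x[i * block:(i + 1) * block]) for i in range(n_blocks)]
    rolling_amp = float(np.median(amps))
    if rolling_amp < 1e-12:
        flags.append("flat_signal")
        return np.zeros(0, dtype=int)
    peaks, _ = sps.find_peaks(
        x,
        distance=max(int(refractory_s * fs), 1),
        prominence=prominence_frac * rolling_amp,
    )
    if peaks.size == 0:
        flags.append("no_beats")
    return peaks


def estimate_hr(peaks: np.ndarray, fs: float, flags: list[str] | None = None) -> float:
    """Heart rate as 60 / median inter-beat interval, in bpm.

    The median makes the estimate robust to a single missed or spurious
    peak.  Fewer than two peaks yields a NaN sentinel.
    """
    if flags is None:
        flags = []
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        flags.append("hr_undefined")
        return HR_UNDEFINED
    ibi = np.diff(peaks) / fs
    return 60.0 / float(np.median(ibi))


def _cardiac_band_rms(window: np.ndarray, fs: float, f0: float,
                      half_width_hz: float = 0.25) -> float:
    """RMS of the component within ``f0 +/- half_width_hz`` (Fourier bins)."""
    spec = np.fft.rfft(window)
    freqs = np.fft.rfftfreq(window.size, 1.0 / fs)
    band = np.abs(freqs - f0) <= half_width_hz
    power = np.sum(np.abs(spec[band]) ** 2) * 2.0 / window.size ** 2
    return float(np.sqrt(power))


def _ac_dc(red_bp, ir_bp, red, ir, fs: float, window_s: float):
    """Per-window AC and DC for both channels.

    AC is the RMS of the band-passed component in a narrow band around the
    cardiac fundamental (located on the IR spectrum within 0.7-3.5 Hz);
    restricting to the pulse line makes the measure robust to broadband
    artifacts while leaving the red/IR ratio of a clean recording exactly
    unchanged (both channels carry the same waveform up to scale).  DC is
    the raw window mean.
    """
    w = max(int(window_s * fs), 1)
    n_win = max(len(red) // w, 1)
    ac_r = np.empty(n_win)
    ac_i = np.empty(n_win)
    dc_r = np.empty(n_win)
    dc_i = np.empty(n_win)
    for k in range(n_win):
        seg = slice(k * w, (k + 1) * w)
        win_ir = ir_bp[seg]
        freqs = np.fft.rfftfreq(win_ir.size, 1.0 / fs)
        spec_ir = np.abs(np.fft.rfft(win_ir))
        cardiac = (freqs >= 0.7) & (freqs <= 3.5)
        if not np.any(cardiac) or np.all(spec_ir[cardiac] == 0):
            f0 = 1.25  # fall back to a typical resting pulse rate
        else:
            f0 = float(freqs[cardiac][np.argmax(spec_ir[cardiac])])
        ac_r[k] = _cardiac_band_rms(red_bp[seg], fs, f0)
        ac_i[k] = _cardiac_band_rms(win_ir, fs, f0)
        dc_r[k] = np.mean(red[seg])
        dc_i[k] = np.mean(ir[seg])
    return ac_r, dc_r, ac_i, dc_i


def estimate_spo2(
    red: np.ndarray,
    ir: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    calibration: SpO2Calibration = DEFAULT_CALIBRATION,
    flags: list[str] | None = None,
) -> float:
    """SpO2 (percent) from raw red and infrared channels.

    Ratio-of-ratios per window, median across windows, mapped through the
    calibration line and clamped to the physiological range.
    """
    if flags is None:
        flags = []
    from .preprocess import FilterSpec, apply_filter

    red = np.asarray(red, dtype=float)
    ir = np.asarray(ir, dtype=float)
    if red.shape != ir.shape:
        raise ValueError("red and ir channels must have the same length")
    spec = FilterSpec.default_chebyshev2()
    red_bp = apply_filter(red, spec, fs)
    ir_bp = apply_filter(ir, spec, fs)
    ac_r, dc_r, ac_i, dc_i = _ac_dc(red_bp, ir_bp, red, ir, fs, window_s)
    if np.any(np.abs(dc_r) < 1e-12) or np.any(np.abs(dc_i) < 1e-12):
        flags.append("zero_dc")
        raise ZeroDivisionError("zero DC level in red or infrared channel")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac_r / dc_r) / (ac_i / dc_i)
    r = r[np.isfinite(r)]
    if r.size == 0:
        flags.append("spo2_undefined")
        return float("nan")
    return float(calibration.spo2(float(np.median(r))))


def paired_error_table(
    device: list[float], reference: list[float]
) -> tuple[list[int], int]:
    """Per-pair rounded percent errors against a reference instrument.

    error_i = round(|device_i - reference_i| / reference_i * 100) as an
    integer percent; returns the list and its maximum.
    """
    if len(device) != len(reference):
        raise ValueError("device and reference lists must have equal length")
    errors = []
    for d, r in zip(device, reference):
        if r == 0:
            raise ZeroDivisionError("reference reading of zero")
        errors.append(int(round(abs(d - r) / r * 100.0)))
    return errors, max(errors)


def estimate_vitals(record, filtered_green: np.ndarray | None = None) -> VitalsResult:
    """Full vitals report for one :class:`~ppgrehab.synth.PpgRecord`."""
    from .preprocess import FilterSpec, apply_filter, remove_baseline_spline

    flags: list[str] = []
    green = filtered_green
    if green is None:
        green = apply_filter(record.green, FilterSpec.default_chebyshev2(), record.fs)
        green = remove_baseline_spline(green, record.fs)
    peaks = detect_beats(green, record.fs, flags=flags)
    hr = estimate_hr(peaks, record.fs, flags=flags)
    if np.isfinite(hr) and not (20.0 <= hr <= 250.0):
        flags.append("hr_out_of_range")
    spo2 = estimate_spo2(record.red, record.ir, record.fs, flags=flags)
    return VitalsResult(hr_bpm=hr, spo2_pct=spo2, n_beats=int(peaks.size), quality_flags=flags)
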