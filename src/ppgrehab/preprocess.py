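"""PPG preprocessing: band-pass filtering, baseline removal, SNR, windowing.

The primary filter is a zero-phase Chebyshev Type II band-pass (monotone
passband, equiripple stopband) designed from a band template; smoothing
filters (Gaussian, Savitzky-Golay, moving average) are provided for
comparison.  Residual baseline offset after filtering is removed by a cubic
spline through per-beat valley anchors.  The module's SNR convention is the
ratio of periodogram power inside the pulse band to power outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal as sps
from scipy.interpolate import CubicSpline

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "WindowSet",
    "design_chebyshev2",
    "apply_filter",
    "remove_baseline_spline",
    "compute_snr",
    "segment_windows",
]

FAMILIES = ("chebyshev2", "gaussian", "savitzky_golay", "moving_average")


@dataclass(frozen=True)
class FilterSpec:
    """Family/band/attenuation description of a preprocessing filter.

    For ``chebyshev2`` the band edges define a band-pass template
    (stopband low < passband low < passband high < stopband high) with the
    order chosen by the standard minimum-order design.  Smoothing families
    use ``aux`` parameters: ``sigma_s`` (Gaussian), ``window_s`` and
    ``polyorder`` (Savitzky-Golay), ``window_s`` (moving average).
    """

    family: str = "chebyshev2"
    order: int | None = None
    passband_hz: tuple[float, float] = (0.5, 10.0)
    stopband_hz: tuple[float, float] = (0.2, 15.0)
    stopband_atten_db: float = 40.0
    passband_ripple_db: float = 1.0
    aux: dict = field(default_factory=dict)

    @classmethod
    def default_chebyshev2(cls) -> "FilterSpec":
        return cls()

    @classmethod
    def default_gaussian(cls) -> "FilterSpec":
        return cls(family="gaussian", aux={"sigma_s": 0.05})

    @classmethod
    def default_savitzky_golay(cls) -> "FilterSpec":
        return cls(family="savitzky_golay", aux={"window_s": 0.31, "polyorder": 3})

    @classmethod
    def default_moving_average(cls) -> "FilterSpec":
        return cls(family="moving_average", aux={"window_s": 0.15})

    def validate(self, fs: float) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.stopband_atten_db <= 0:
            raise ValueError("stopband_atten_db must be positive")
        if self.family == "chebyshev2":
            sl, sh = self.stopband_hz
            pl, ph = self.passband_hz
            if not (0 < sl < pl < ph < sh < fs / 2):
                raise ValueError(
                    "band edges must satisfy 0 < stop_lo < pass_lo < pass_hi "
                    f"< stop_hi < fs/2; got stop={self.stopband_hz}, "
                    f"pass={self.passband_hz}, fs={fs}"
                )
        if self.order is not None and self.order < 1:
            raise ValueError("order must be >= 1")


def design_chebyshev2(spec: FilterSpec, fs: float) -> np.ndarray:
    """Realize the Chebyshev Type II band-pass as second-order sections.

    Order comes from the minimum-order design for the band template unless
    the spec pins it.  The realization is checked for stability and for
    meeting the stopband attenuation; a violated template raises rather
    than returning silently.
    """
    spec.validate(fs)
    if spec.family != "chebyshev2":
        raise ValueError("design_chebyshev2 requires a chebyshev2 spec")
    if spec.order is None:
        order, wn = sps.cheb2ord(
            spec.passband_hz, spec.stopband_hz,
            gpass=spec.passband_ripple_db, gstop=spec.stopband_atten_db, fs=fs,
        )
    else:
        order, wn = spec.order, spec.stopband_hz
    sos = sps.cheby2(order, spec.stopband_atten_db, wn, btype="bandpass",
                     output="sos", fs=fs)
    # stability: all poles strictly inside the unit circle
    z, p, k = sps.sos2zpk(sos)
    if np.any(np.abs(p) >= 1.0):
        raise ArithmeticError("unstable Chebyshev II realization")
    return sos


def _effective_length(sos: np.ndarray) -> int:
    # sosfiltfilt's default pad length
    return 3 * (2 * sos.shape[0] + 1)


def apply_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply the spec'd filter; same output length as input.

    The Chebyshev band-pass runs forward-backward (zero phase), which
    preserves systolic/dicrotic timing; smoothing families are symmetric
    FIR kernels and are zero phase by construction.
    """
    x = np.asarray(x, dtype=float)
    spec.validate(fs)
    if spec.family == "chebyshev2":
        sos = design_chebyshev2(spec, fs)
        pad = _effective_length(sos)
        if x.size <= pad:
            raise ValueError(
                f"signal length {x.size} too short for filter pad length {pad}"
            )
        return sps.sosfiltfilt(sos, x)
    if spec.family == "gaussian":
        sigma = spec.aux.get("sigma_s", 0.05) * fs
        return ndimage.gaussian_filter1d(x, sigma=sigma, mode="nearest")
    if spec.family == "savitzky_golay":
        win = int(round(spec.aux.get("window_s", 0.31) * fs)) | 1  # odd
        poly = int(spec.aux.get("polyorder", 3))
        if x.size < win:
            raise ValueError(f"signal length {x.size} shorter than window {win}")
        return sps.savgol_filter(x, win, poly)
    if spec.family == "moving_average":
        win = max(int(round(spec.aux.get("window_s", 0.15) * fs)), 1)
        if x.size < win:
            raise ValueError(f"signal length {x.size} shorter than window {win}")
        kernel = np.full(win, 1.0 / win)
        return np.convolve(x, kernel, mode="same")
    raise ValueError(f"unknown filter family {spec.family!r}")


def remove_baseline_spline(
    x: np.ndarray, fs: float, anchor_strategy: str = "valleys"
) -> np.ndarray:
    """Subtract a cubic spline through baseline anchors.

    ``valleys`` anchors at the minimum between successive systolic peaks
    (plus the record endpoints); ``fixed`` anchors at 1-second intervals.
    With fewer than 4 anchors the function falls back to mean subtraction
    and logs a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    if anchor_strategy == "valleys":
        # peaks are located on a linearly detrended copy so a strong ramp
        # cannot mask the beats; anchors still index the original signal
        n = np.arange(x.size)
        xd = x - np.polyval(np.polyfit(n, x, 1), n) if x.size > 1 else x
        peaks, _ = sps.find_peaks(xd, distance=max(int(0.33 * fs), 1),
                                  prominence=0.5 * max(np.ptp(xd), 1e-12))
        anchors = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            anchors.append(a + int(np.argmin(x[a:b])))
        anchors = np.asarray(anchors, dtype=int)
    elif anchor_strategy == "fixed":
        anchors = np.arange(0, x.size, max(int(fs), 1))
    else:
        raise ValueError(f"unknown anchor strategy {anchor_strategy!r}")
    # include endpoints so the spline spans the record
    anchors = np.unique(np.concatenate([[0], anchors, [x.size - 1]]))
    if anchors.size < 4:
        log.warning("fewer than 4 baseline anchors; falling back to mean subtraction")
        return x - x.mean()
    spline = CubicSpline(anchors, x[anchors])
    return x - spline(np.arange(x.size))


def compute_snr(
    x: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (0.5, 10.0),
) -> float:
    """Signal-to-noise ratio in dB: 10 log10(P_in_band / P_out_of_band).

    Powers are integrated from the periodogram; "in band" is the pulse
    passband (default 0.5-10 Hz, the Chebyshev template's passband).  Zero
    out-of-band power returns +inf.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4 or not np.all(np.isfinite(x)):
        raise ValueError("compute_snr requires a finite signal of length >= 4")
    if np.ptp(x) < 1e-15:
        raise ValueError("compute_snr requires a non-constant signal")
    f, pxx = sps.periodogram(x, fs=fs)
    in_band = (f >= band_hz[0]) & (f <= band_hz[1])
    p_in = float(np.sum(pxx[in_band]))
    p_out = float(np.sum(pxx[~in_band]))
    if p_out <= 0.0:
        log.warning("zero out-of-band power; SNR is +inf")
        return float("inf")
    return 10.0 * np.log10(p_in / p_out)


@dataclass
class WindowSet:
    """Fixed-length, z-scored model input windows with provenance."""

    windows: np.ndarray  # (n_windows, 3, window_len)
    labels: np.ndarray   # stage string per window
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.windows.ndim != 3:
            if self.windows.size == 0:
                self.windows = self.windows.reshape(0, 3, 0)
            else:
                raise ValueError("windows must be (n, 3, window_len)")
        if not (len(self.windows) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("windows/labels/subject_ids lengths differ")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]


def segment_windows(
    records,
    window_s: float,
    overlap_frac: float = 0.0,
    normalize: bool = True,
) -> WindowSet:
    """Cut records into fixed windows with optional overlap.

    Each window is per-channel z-scored; the label is inherited from the
    subject.  Windows longer than a record skip that record with a warning.
    """
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must lie in [0, 1)")
    windows, labels, subjects = [], [], []
    for rec in records:
        win = int(round(window_s * rec.fs))
        if abs(win - window_s * rec.fs) > 1e-9:
            raise ValueError("window_s * fs must be an integer sample count")
        if win > rec.n_samples:
            log.warning("window longer than record %s; skipping", rec.subject_id)
            continue
        step = max(int(round(win * (1.0 - overlap_frac))), 1)
        chans = rec.channels()
        for start in range(0, rec.n_samples - win + 1, step):
            w = chans[:, start:start + win]
            if normalize:
                mu = w.mean(axis=1, keepdims=True)
                sd = w.std(axis=1, keepdims=True)
                w = (w - mu) / np.maximum(sd, 1e-12)
            windows.append(w)
            labels.append(rec.stage)
            subjects.append(rec.subject_id)
    if not windows:
        return WindowSet(np.zeros((0, 3, 0)), np.asarray(labels), np.asarray(subjects))
    return WindowSet(np.stack(windows), np.asarray(labels), np.asarray(subjects))
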