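"""Synthetic tri-wavelength PPG generator.

Emulates finger photoplethysmography recorded simultaneously at green
(~527 nm), red (~660 nm) and infrared (~880 nm) wavelengths at a fixed
sampling rate.  Each heartbeat is modelled as the sum of two Gaussian
bumps — a systolic peak and a later, smaller dicrotic wave — so that the
impaired-vasculature morphology seen in stroke patients (attenuation up
to disappearance of the dicrotic wave) is controlled by a single relative
amplitude per Brunnstrom stage.

Three noise classes are superimposed on the clean pulse train:

* random noise — additive white Gaussian noise;
* low-frequency noise — respiration-locked sinusoidal baseline drift plus
  a slow random walk (baseline wander);
* high-frequency noise — a mains sinusoid plus sparse spike artifacts.

The red/infrared AC/DC perfusion ratios are solved from the inverse of the
pulse-oximetry calibration line used by :mod:`ppgrehab.vitals`, so a
noise-free record round-trips its target SpO2 through the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np

__all__ = [
    "STAGES",
    "SynthConfig",
    "PpgRecord",
    "beat_template",
    "generate_record",
    "generate_dataset",
]

#: Brunnstrom stages handled by the package; "VII" denotes healthy subjects.
STAGES = ("V", "VI", "VII")


@dataclass(frozen=True)
class SynthConfig:
    """All generator parameters for a synthetic cohort.

    Amplitudes are in arbitrary intensity units (the acquisition hardware
    defines no physical unit); perfusion is expressed through AC/DC ratios.
    """

    subjects_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"V": 4, "VI": 4, "VII": 8}
    )
    duration_s: float = 1800.0
    fs: float = 100.0
    hr_mean_bpm: float = 75.0
    hr_sd_bpm: float = 8.0
    hrv_jitter_frac: float = 0.03
    resp_rate_hz: float = 0.25
    target_spo2_pct: float = 97.0
    spo2_sd_pct: float = 1.0
    dicrotic_amp_by_stage: Mapping[str, float] = field(
        default_factory=lambda: {"V": 0.05, "VI": 0.25, "VII": 0.5}
    )
    # channel intensity scaling (arbitrary units)
    dc_green: float = 100.0
    dc_red: float = 80.0
    dc_ir: float = 90.0
    ac_dc_green: float = 0.05
    ac_dc_ir: float = 0.02
    # noise parameters
    noise_random_sd: float = 0.5
    drift_amp: float = 5.0
    spike_rate_per_s: float = 0.5
    spike_amp: float = 10.0
    mains_hz: float = 50.0
    mains_amp: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_s < 0:
            raise ValueError(f"duration_s must be >= 0, got {self.duration_s}")
        if not (70.0 <= self.target_spo2_pct <= 100.0):
            raise ValueError(
                f"target_spo2_pct must lie in [70, 100], got {self.target_spo2_pct}"
            )
        d = self.dicrotic_amp_by_stage
        missing = [s for s in STAGES if s not in d]
        if missing:
            raise ValueError(f"dicrotic_amp_by_stage missing stages: {missing}")
        # severity ordering: stage V (most impaired) <= VI <= VII (healthy)
        if not (d["V"] <= d["VI"] <= d["VII"]):
            raise ValueError(
                "dicrotic amplitudes must be nonincreasing with severity "
                f"(V<=VI<=VII), got {dict(d)}"
            )
        for s, n in self.subjects_per_class.items():
            if s not in STAGES:
                raise ValueError(f"unknown stage label {s!r}")
            if n < 0:
                raise ValueError(f"negative subject count for stage {s}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subjects_per_class"] = dict(self.subjects_per_class)
        d["dicrotic_amp_by_stage"] = dict(self.dicrotic_amp_by_stage)
        return d

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class PpgRecord:
    """One subject's synchronized tri-wavelength recording."""

    subject_id: str
    stage: str
    fs: float
    green: np.ndarray
    red: np.ndarray
    ir: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage label {self.stage!r}")
        n = len(self.green)
        if len(self.red) != n or len(self.ir) != n:
            raise ValueError("green/red/ir channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.green)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channels(self) -> np.ndarray:
        """Stack channels as a (3, n_samples) array ordered green, red, ir."""
        return np.stack([self.green, self.red, self.ir])


def beat_template(
    phase_grid: np.ndarray,
    systolic_amp: float = 1.0,
    dicrotic_amp: float = 0.5,
    systolic_center: float = 0.3,
    systolic_width: float = 0.08,
    dicrotic_center: float = 0.65,
    dicrotic_width: float = 0.1,
) -> np.ndarray:
    """Evaluate one beat's waveform on a grid of beat-phase fractions.

    The waveform is the sum of a systolic Gaussian bump and a dicrotic
    Gaussian bump; ``dicrotic_amp`` is relative to ``systolic_amp`` and
    setting it to zero yields a single-mode beat.
    """
    phase = np.asarray(phase_grid, dtype=float)
    if phase.ndim == 1 and phase.size > 1 and np.any(np.diff(phase) < 0):
        raise ValueError("phase_grid must be non-decreasing")
    if not (0.0 < systolic_center < 1.0 and 0.0 < dicrotic_center < 1.0):
        raise ValueError("bump centers must lie in (0, 1)")
    if systolic_width <= 0 or dicrotic_width <= 0:
        raise ValueError("bump widths must be positive")
    if dicrotic_center <= systolic_center:
        raise ValueError("dicrotic_center must exceed systolic_center")
    return _beat_waveform(phase, systolic_amp, dicrotic_amp, systolic_center,
                          systolic_width, dicrotic_center, dicrotic_width)


def _beat_waveform(phase, systolic_amp, dicrotic_amp, systolic_center,
                   systolic_width, dicrotic_center, dicrotic_width):
    # unchecked evaluator: also used on the sawtooth phase signal of a
    # whole pulse train, where phase resets at each beat boundary
    sys_bump = np.exp(-0.5 * ((phase - systolic_center) / systolic_width) ** 2)
    dic_bump = np.exp(-0.5 * ((phase - dicrotic_center) / dicrotic_width) ** 2)
    return systolic_amp * (sys_bump + dicrotic_amp * dic_bump)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # per-subject stream keyed by (seed, counter): subject k is reproducible
    # independently of cohort size
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def _pulse_train(
    duration_s: float,
    fs: float,
    hr_bpm: float,
    jitter_frac: float,
    dicrotic_amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lay down jittered beats; returns the unit-amplitude pulse waveform."""
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    period = 60.0 / hr_bpm
    # enough beats to cover the record even under negative jitter
    n_beats = int(np.ceil(duration_s / period * 1.5)) + 2
    jitter = 1.0 + jitter_frac * rng.standard_normal(n_beats)
    periods = period * np.clip(jitter, 0.5, 1.5)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) / fs
    idx = np.searchsorted(starts, t, side="right") - 1
    phase = (t - starts[idx]) / periods[idx]
    return _beat_waveform(phase, 1.0, dicrotic_amp, 0.3, 0.08, 0.65, 0.1)


def generate_record(
    stage: str,
    config: SynthConfig,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> PpgRecord:
    """Generate one subject's tri-wavelength record for a given stage.

    Channel composition: ``channel = DC + (AC/DC ratio) * DC * pulse`` with
    the zero-mean unit pulse shared across wavelengths, then the three noise
    classes are added independently per channel.  The red AC/DC ratio is set
    so the ratio-of-ratios implied by red/IR matches the subject's target
    SpO2 under the vitals calibration line.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage label {stage!r}")
    config.validate()
    n = int(round(config.duration_s * config.fs))

    hr = float(np.clip(
        config.hr_mean_bpm + config.hr_sd_bpm * rng.standard_normal(), 40.0, 180.0
    ))
    spo2 = float(np.clip(
        config.target_spo2_pct + config.spo2_sd_pct * rng.standard_normal(), 70.0, 100.0
    ))
    dic_amp = float(config.dicrotic_amp_by_stage[stage])

    pulse = _pulse_train(
        config.duration_s, config.fs, hr, config.hrv_jitter_frac, dic_amp, rng
    )
    if n:
        pulse = pulse - pulse.mean()  # zero-mean AC component

    # perfusion ratios: IR fixed, red solved from the calibration inverse
    from .vitals import ratio_for_spo2  # local import avoids a cycle at import time

    r = ratio_for_spo2(spo2)
    m_green = config.ac_dc_green
    m_ir = config.ac_dc_ir
    m_red = r * m_ir

    t = np.arange(n) / config.fs
    channels = {}
    for name, dc, m in (
        ("green", config.dc_green, m_green),
        ("red", config.dc_red, m_red),
        ("ir", config.dc_ir, m_ir),
    ):
        x = dc + m * dc * pulse
        x = x + _noise(n, t, config, rng)
        channels[name] = x

    return PpgRecord(
        subject_id=subject_id, stage=stage, fs=config.fs,
        green=channels["green"], red=channels["red"], ir=channels["ir"],
    )


def _noise(n: int, t: np.ndarray, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one channel's worth of the three noise classes."""
    if n == 0:
        return np.zeros(0)
    out = np.zeros(n)
    # low-frequency: respiration sinusoid + slow random walk through spline knots
    if config.drift_amp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        out += config.drift_amp * np.sin(2 * np.pi * config.resp_rate_hz * t + phi)
        knot_step = 5.0  # seconds between wander knots
        n_knots = max(int(np.ceil(t[-1] / knot_step)) + 2, 4)
        knots_t = np.arange(n_knots) * knot_step
        knots_v = np.cumsum(rng.standard_normal(n_knots))
        knots_v -= knots_v.mean()
        scale = max(np.abs(knots_v).max(), 1e-12)
        out += 0.3 * config.drift_amp * np.interp(t, knots_t, knots_v / scale)
    # random: white Gaussian
    if config.noise_random_sd > 0:
        out += config.noise_random_sd * rng.standard_normal(n)
    # high-frequency: mains sinusoid + sparse spikes
    if config.mains_amp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        out += config.mains_amp * np.sin(2 * np.pi * config.mains_hz * t + phi)
    if config.spike_rate_per_s > 0 and config.spike_amp > 0:
        n_spikes = rng.poisson(config.spike_rate_per_s * t[-1] if n > 1 else 0.0)
        if n_spikes:
            pos = rng.integers(0, n, n_spikes)
            sign = rng.choice([-1.0, 1.0], n_spikes)
            np.add.at(out, pos, sign * config.spike_amp)
    return out


def generate_dataset(config: SynthConfig) -> list[PpgRecord]:
    """Generate the whole cohort: one record per synthetic subject.

    Subjects are numbered in stage order (V, VI, VII); each gets an
    independent RNG stream derived from ``config.seed`` and its index, so
    subject *k* reproduces identically regardless of cohort composition.
    """
    config.validate()
    total = sum(config.subjects_per_class.get(s, 0) for s in STAGES)
    if total < 1:
        raise ValueError("subjects_per_class must sum to at least 1")
    records = []
    k = 0
    for stage in STAGES:
        for _ in range(int(config.subjects_per_class.get(stage, 0))):
            rng = _subject_rng(config.seed, k)
            records.append(
                generate_record(stage, config, rng, subject_id=f"S{k:03d}")
            )
            k += 1
    return records
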