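"""The package's standard separable synthetic benchmark.

A small three-class cohort whose classes differ only in dicrotic-wave
amplitude (stage V 0.05, VI 0.25, VII 0.5) under low noise — the single
documented separability axis.  Problem sizes (3 subjects per class, 60 s
records, 2 s windows) and the reduced model configuration are the
package's own desk-scale choices; both are deliberately small so a full
10-fold cross-validation finishes in seconds-to-minutes on one CPU.
"""

from __future__ import annotations

from .model import ModelConfig
from .preprocess import FilterSpec, WindowSet, apply_filter, segment_windows
from .synth import PpgRecord, SynthConfig, generate_dataset

__all__ = ["benchmark_synth_config", "benchmark_model_config", "make_benchmark"]


def benchmark_synth_config(seed: int = 0, subjects_per_class: int = 3,
                           duration_s: float = 60.0) -> SynthConfig:
    """Low-noise, strongly separable three-class cohort configuration."""
    return SynthConfig(
        subjects_per_class={"V": subjects_per_class, "VI": subjects_per_class,
                            "VII": subjects_per_class},
        duration_s=duration_s,
        noise_random_sd=0.1,
        drift_amp=0.5,
        spike_rate_per_s=0.05,
        spike_amp=2.0,
        mains_amp=0.1,
        seed=seed,
    )


def benchmark_model_config(window_len: int = 200, epochs: int = 15,
                           seed: int = 0) -> ModelConfig:
    """Reduced network sized for the benchmark windows (2 s at 100 Hz)."""
    return ModelConfig(
        window_len=window_len,
        shallow_branch=(15, 1, 8),
        deep_branch=(5, 2, 16),
        pool_width=3,
        lstm_hidden=32,
        lstm_layers=1,
        attention_dim=32,
        fc_sizes=(32,),
        dropout_p=0.3,
        epochs=epochs,
        batch_size=16,
        learning_rate=3e-3,
        seed=seed,
    )


def make_benchmark(seed: int = 0, subjects_per_class: int = 3,
                   duration_s: float = 60.0, window_s: float = 2.0) -> WindowSet:
    """Simulate, filter and window the benchmark cohort."""
    config = benchmark_synth_config(seed, subjects_per_class, duration_s)
    records = generate_dataset(config)
    spec = FilterSpec.default_chebyshev2()
    filtered = [
        PpgRecord(
            subject_id=r.subject_id, stage=r.stage, fs=r.fs,
            green=apply_filter(r.green, spec, r.fs),
            red=apply_filter(r.red, spec, r.fs),
            ir=apply_filter(r.ir, spec, r.fs),
        )
        for r in records
    ]
    return segment_windows(filtered, window_s=window_s)
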