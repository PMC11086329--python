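"""End-to-end pipeline: simulate -> preprocess -> window -> train/evaluate.

One root seed fans out to per-stage seeds through ``SeedSequence([root,
stage_index])`` (stage order: synth=0, model=1, eval=2), so each stage is
reproducible in isolation and identical configurations yield identical
manifests.  Every intermediate artifact is written to the output
directory together with ``manifest.json`` carrying the configuration, its
hash, and a content digest per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluate import EvalReport, crossvalidate
from .io import config_hash, file_sha256, write_cohort, write_record_csv
from .model import ModelConfig, save_model, train
from .preprocess import FilterSpec, apply_filter, segment_windows
from .synth import PpgRecord, SynthConfig, generate_dataset
from .vitals import estimate_vitals

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGE_INDEX = {"synth": 0, "model": 1, "eval": 2}


def derive_seed(root_seed: int, stage: str) -> int:
    """Documented per-stage seed derivation from the root seed."""
    return int(
        np.random.SeedSequence([int(root_seed), _STAGE_INDEX[stage]])
        .generate_state(1)[0] % (2**31)
    )


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec.default_chebyshev2)
    window_s: float = 5.0
    overlap_frac: float = 0.0
    model: ModelConfig = field(default_factory=ModelConfig)
    eval_k: int = 10
    eval_grouping: str = "window"
    architecture: str = "mcnn_lstm_attention"
    seed: int = 0
    out_dir: str = "ppgrehab_out"

    def validate(self) -> None:
        self.synth.validate()
        self.filter.validate(self.synth.fs)
        self.model.validate()
        if self.eval_k < 2:
            raise ValueError("eval_k must be >= 2")
        expected = int(round(self.window_s * self.synth.fs))
        if expected != self.model.window_len:
            raise ValueError(
                f"window_s*fs = {expected} does not match model window_len "
                f"{self.model.window_len}"
            )

    def to_dict(self) -> dict:
        return {
            "synth": self.synth.to_dict(),
            "filter": dataclasses.asdict(self.filter),
            "window_s": self.window_s,
            "overlap_frac": self.overlap_frac,
            "model": self.model.to_dict(),
            "eval_k": self.eval_k,
            "eval_grouping": self.eval_grouping,
            "architecture": self.architecture,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        synth = dict(d.get("synth", {}))
        model = dict(d.get("model", {}))
        filt = dict(d.get("filter", {}))
        for key in ("passband_hz", "stopband_hz"):
            if key in filt and filt[key] is not None:
                filt[key] = tuple(filt[key])
        for key in ("shallow_branch", "deep_branch", "fc_sizes"):
            if key in model:
                model[key] = tuple(model[key])
        return cls(
            synth=SynthConfig(**synth),
            filter=FilterSpec(**filt),
            window_s=d.get("window_s", 5.0),
            overlap_frac=d.get("overlap_frac", 0.0),
            model=ModelConfig(**model),
            eval_k=d.get("eval_k", 10),
            eval_grouping=d.get("eval_grouping", "window"),
            architecture=d.get("architecture", "mcnn_lstm_attention"),
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir", "ppgrehab_out"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _array_digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Execute the full assessment flow and write all artifacts.

    Stages: cohort simulation, per-channel filtering, vitals reports,
    windowing, k-fold cross-validation of the configured architecture, and
    a final checkpoint trained on the full window set.  Any stage failure
    aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # the hash identifies the computation, not where it is written
    digest = config_hash({k: v for k, v in cfg_dict.items() if k != "out_dir"})
    manifest = {"config": cfg_dict, "config_hash": digest, "files": {}}

    def record_file(path: Path, logical_digest: str | None = None) -> None:
        manifest["files"][str(path.relative_to(out))] = (
            logical_digest or file_sha256(path)
        )

    stage = "simulate"
    try:
        synth_cfg = config.synth.with_(seed=derive_seed(config.seed, "synth"))
        records = generate_dataset(synth_cfg)
        log.info("simulate: %d records, %d samples each, config %s",
                 len(records), records[0].n_samples if records else 0, digest)
        raw_dir = out / "raw"
        raw_dir.mkdir(exist_ok=True)
        for rec in records:
            p = write_record_csv(rec, raw_dir / f"{rec.subject_id}.csv", digest)
            record_file(p)
            record_file(p.with_suffix(p.suffix + ".meta.json"))
        cohort_path = write_cohort(records, out / "cohort.npz", cfg_dict)
        record_file(cohort_path, _array_digest(*[r.channels() for r in records]))

        stage = "preprocess"
        filt_dir = out / "filtered"
        filt_dir.mkdir(exist_ok=True)
        filtered = []
        for rec in records:
            frec = PpgRecord(
                subject_id=rec.subject_id, stage=rec.stage, fs=rec.fs,
                green=apply_filter(rec.green, config.filter, rec.fs),
                red=apply_filter(rec.red, config.filter, rec.fs),
                ir=apply_filter(rec.ir, config.filter, rec.fs),
            )
            filtered.append(frec)
            p = write_record_csv(frec, filt_dir / f"{frec.subject_id}.csv", digest)
            record_file(p)
            record_file(p.with_suffix(p.suffix + ".meta.json"))
        log.info("preprocess: filtered %d records with %s",
                 len(filtered), config.filter.family)

        stage = "vitals"
        vitals = {}
        for raw, filt in zip(records, filtered):
            v = estimate_vitals(raw, filtered_green=filt.green)
            vitals[raw.subject_id] = {
                "hr_bpm": None if not np.isfinite(v.hr_bpm) else round(v.hr_bpm, 2),
                "spo2_pct": None if not np.isfinite(v.spo2_pct) else round(v.spo2_pct, 2),
                "n_beats": v.n_beats,
                "flags": v.quality_flags,
                "stage": raw.stage,
            }
        vitals_path = out / "vitals.json"
        vitals_path.write_text(json.dumps(vitals, indent=2, sort_keys=True))
        record_file(vitals_path)

        stage = "segment"
        windows = segment_windows(filtered, config.window_s, config.overlap_frac)
        log.info("segment: %d windows of %d samples", len(windows),
                 windows.window_len)
        win_path = out / "windows.npz"
        np.savez_compressed(win_path, windows=windows.windows,
                            labels=windows.labels, subject_ids=windows.subject_ids)
        record_file(win_path, _array_digest(windows.windows))

        stage = "evaluate"
        report = crossvalidate(
            windows, config.model, config.architecture, k=config.eval_k,
            seed=derive_seed(config.seed, "eval"), grouping=config.eval_grouping,
        )
        report_csv = out / "report.csv"
        report.to_frame().to_csv(report_csv, float_format="%.6f")
        record_file(report_csv)
        cm_csv = out / "confusion.csv"
        report.confusion.to_frame().to_csv(cm_csv)
        record_file(cm_csv)
        summary_txt = out / "report.txt"
        lines = [f"architecture: {config.architecture}",
                 f"k: {config.eval_k}  grouping: {config.eval_grouping}"]
        lines += [f"{k}: {v:.4f}" for k, v in report.summary().items()]
        summary_txt.write_text("\n".join(lines) + "\n")
        record_file(summary_txt)

        stage = "train_final"
        final_cfg = config.model.with_(seed=derive_seed(config.seed, "model"))
        final_model = train(windows.windows, windows.labels, final_cfg,
                            config.architecture)
        ckpt = out / "model.npz"
        save_model(final_model, ckpt)
        record_file(ckpt, _array_digest(*[
            layer.params[k]
            for layer in final_model.network._all_layers()
            for k in sorted(layer.params)
        ]))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", manifest_path)
    return report
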