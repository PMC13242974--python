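"""End-to-end orchestration: phantom -> preprocess -> train -> segment ->
stiffness -> statistics, as one reproducible run.

A run is described by a single :class:`RunConfig` (one YAML file) with a
global seed from which every stage seed is derived deterministically. Every
intermediate artifact is written to disk so any stage can be re-run in
isolation, and a JSON manifest records versions, seeds, a config hash and
per-stage metrics; re-running the same config reproduces the CSV outputs
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomech import AirJetProtocol, quantify_series, force
from .phantom import PhantomConfig, generate_series, make_segmentation_dataset
from .preprocess import gaussian_denoise, save_series, save_mask_stack
from .segmentation import (TrainConfig, split_dataset, build_unet, train,
                           evaluate, predict_stack, save_model)
from .stats import analysis_report, synthetic_stiffness_table

log = logging.getLogger("octstiff")


@dataclass
class RunConfig:
    """One-file description of a full phantom-to-statistics run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    protocol: AirJetProtocol = field(default_factory=AirJetProtocol)
    train: TrainConfig = field(default_factory=TrainConfig)
    split_ratios: tuple = (0.6, 0.2, 0.2)
    n_train_images: int = 160
    denoise_sigma_px: float = 1.0
    sweep_k_n_per_mm: tuple = (0.5, 1.0, 1.5, 2.0, 2.5)
    sweep_replicates: int = 1
    n_stat_subjects: int = 14
    seed: int = 0
    output_dir: str = "octstiff_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "phantom":
                v = PhantomConfig(**v)
            elif f.name == "protocol":
                v = AirJetProtocol(**v)
            elif f.name == "train":
                v = TrainConfig(**v)
            elif f.name in ("split_ratios", "sweep_k_n_per_mm"):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"] = asdict(self.phantom)
        d["protocol"] = asdict(self.protocol)
        d["train"] = asdict(self.train)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 1009 + stage * 9973) % (2 ** 31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S")
    run_id = config.config_hash()
    manifest = {"version": __version__, "run_id": run_id,
                "config_hash": run_id, "seed": config.seed,
                "config": config.to_dict(), "stages": {}}
    t_start = time.time()

    def stage_done(name, **metrics):
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t_start, 2),
                                    **metrics}
        log.info("run %s: stage %s done %s", run_id, name, metrics)

    try:
        # 1. phantom training data + recovery sweep series -------------------
        size = config.train.input_size_px
        images, masks, patient_of = make_segmentation_dataset(
            config.n_train_images, image_size_px=size,
            axial_pitch_um=config.phantom.axial_pitch_um,
            seed=_stage_seed(config.seed, 1))
        save_mask_stack(masks, out / "train_masks.tiff")
        np.save(out / "train_images.npy", images)
        sweep = []
        for rep in range(config.sweep_replicates):
            for i, k in enumerate(config.sweep_k_n_per_mm):
                cfg = dataclasses.replace(
                    config.phantom, image_height_px=size, image_width_px=size,
                    k_true_n_per_mm=float(k),
                    seed=_stage_seed(config.seed, 100 + 10 * rep + i))
                series, truth = generate_series(cfg, config.protocol)
                sdir = out / "sweep" / f"k{k}_rep{rep}"
                save_series(series, sdir / "series.tiff", protocol=config.protocol)
                save_mask_stack(truth.masks, sdir / "truth_masks.tiff")
                sweep.append((k, rep, series, truth))
        stage_done("phantom", n_train_images=len(images), n_sweep=len(sweep))

        # 2. preprocessing ----------------------------------------------------
        if config.denoise_sigma_px > 0:
            images = np.stack([gaussian_denoise(f, config.denoise_sigma_px)
                               for f in images])
        stage_done("preprocess", sigma_px=config.denoise_sigma_px)

        # 3. split + training -------------------------------------------------
        split = split_dataset(list(range(len(images))), patient_of,
                              config.split_ratios,
                              seed=_stage_seed(config.seed, 2))
        model = build_unet(config.train)
        model, history = train(model, split, images, masks, config.train)
        save_model(model, config.train, out / "model.npz")
        (out / "history.json").write_text(json.dumps(history, indent=1))
        seg = evaluate(model, images[split.test_ids], masks[split.test_ids],
                       config.train.threshold)
        pd.DataFrame([asdict(seg)]).to_csv(out / "segmentation_metrics.csv",
                                           index=False)
        stage_done("train", epochs=len(history["train_loss"]),
                   test_dice=seg.dice, test_iou=seg.iou,
                   test_pixel_accuracy=seg.pixel_accuracy)

        # 4+5. segment sweep series and quantify stiffness --------------------
        rows = []
        for k, rep, series, truth in sweep:
            frames = series.frames
            if config.denoise_sigma_px > 0:
                frames = np.stack([gaussian_denoise(f, config.denoise_sigma_px)
                                   for f in frames])
            pred = predict_stack(model, frames, config.train.threshold)
            save_mask_stack(pred, out / "sweep" / f"k{k}_rep{rep}" /
                            "pred_masks.tiff")
            res = quantify_series(series, pred, config.protocol)
            rows.append({"source_id": series.source_id, "k_true_n_per_mm": k,
                         "replicate": rep,
                         "baseline_mm": res.baseline_depth_mm,
                         "max_mm": res.max_depth_mm,
                         "delta_d_mm": res.delta_d_mm,
                         "force_n": res.force_n,
                         "k_n_per_mm": res.k_n_per_mm,
                         "delta_d_true_mm": truth.delta_d_true_mm})
        results = pd.DataFrame(rows)
        results.to_csv(out / "results.csv", index=False)
        med_err = float(np.median(np.abs(results.k_n_per_mm -
                                         results.k_true_n_per_mm) /
                                  results.k_true_n_per_mm))
        stage_done("stiffness", n_series=len(rows),
                   median_rel_error=med_err, force_n=force(config.protocol))

        # 6. statistics -------------------------------------------------------
        table = synthetic_stiffness_table(config.n_stat_subjects,
                                          seed=_stage_seed(config.seed, 3))
        table.to_csv(out / "stiffness_table.csv", index=False)
        report = analysis_report(table)
        for name, df in report.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"stats_{name}.csv", index=False)
        stage_done("stats", n_warnings=len(report["warnings"]))
    except Exception as exc:  # partial artifacts stay on disk for inspection
        failed = [s for s in ("phantom", "preprocess", "train", "stiffness",
                              "stats") if s not in manifest["stages"]]
        stage = failed[0] if failed else "unknown"
        log.error("run %s aborted at stage %s: %s", run_id, stage, exc)
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
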