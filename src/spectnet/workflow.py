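"""End-to-end pipeline orchestration: simulate -> preprocess -> train ->
evaluate -> dream, driven by one YAML-able configuration dict.

Each stage writes its artifact under the run's output directory; a
manifest records the configuration hash, seeds, package versions, SHA-256
checksums of every produced file and per-stage wall time, so a run can be
reproduced and verified file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, models
from .containers import FrameSet
from .evaluation import run_experiments
from .interpret import DreamConfig, class_difference, dream
from .spectrogram import FrameNormalizer, build_frameset
from .synthetic import (BurstSpec, ClassRecipe, EEGSynthConfig,
                        OscillationRecipe, default_recipes,
                        generate_class_frameset, generate_eeg_cohort)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "evaluate", "dream")


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed or is missing an upstream artifact."""


@dataclass
class RunConfig:
    """Parsed pipeline configuration (one block per stage)."""

    stages: list[str]
    seed: int = 0
    output_dir: str = "spectnet-run"
    run_id: str = "run"
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    dream: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "stages" not in raw or not raw["stages"]:
            raise ConfigError("config needs a non-empty 'stages' list")
        unknown = set(raw["stages"]) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}; "
                              f"valid: {list(STAGES)}")
        fields = {k: raw[k] for k in
                  ("stages", "seed", "output_dir", "run_id",
                   "simulate", "preprocess", "train", "evaluate", "dream")
                  if k in raw}
        return cls(**fields)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(raw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict[str, str]
    stage_seconds: dict[str, float] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _recipes_from_config(block: dict) -> list[ClassRecipe]:
    if "recipes" not in block:
        return default_recipes()
    out = []
    for r in block["recipes"]:
        specs = [BurstSpec(**s) for s in r.get("burst_specs", [])]
        out.append(ClassRecipe(label=r["label"], burst_specs=specs,
                               background_noise_sd=r.get(
                                   "background_noise_sd", 0.25),
                               channels=r.get("channels")))
    return out


def _build_model(block: dict, seed: int):
    arch = block.get("arch", "dcnn")
    params = dict(block.get("params", {}))
    params.setdefault("random_state", seed)
    builders = {"dcnn": models.build_dcnn, "rnn": models.build_rnn,
                "shallow": models.build_shallow}
    if arch not in builders:
        raise ConfigError(f"unknown architecture {arch!r}")
    return builders[arch](**params)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in canonical order; halt on failure
    with a stage-named error. Returns the written manifest."""
    outdir = Path(config.output_dir) / config.run_id
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seed = {s: int(rng.integers(0, 2 ** 31)) for s in STAGES}
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str)
            .encode()).hexdigest(),
        seed=config.seed,
        versions={"spectnet": __version__, "numpy": np.__version__})

    def record(stage: str, paths: list[Path], t0: float):
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        for p in paths:
            manifest.artifacts[str(p.relative_to(outdir))] = _sha256(p)

    frames_path = outdir / "frames.h5"
    ordered = [s for s in STAGES if s in config.stages]

    for stage in ordered:
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)
        try:
            if stage == "simulate":
                blk = config.simulate
                mode = blk.get("mode", "frames")
                if mode == "frames":
                    fs = generate_class_frameset(
                        _recipes_from_config(blk),
                        n_subjects_per_class=blk.get(
                            "n_subjects_per_class", 10),
                        frames_per_subject=blk.get("frames_per_subject", 148),
                        rng_seed=stage_seed["simulate"],
                        frame_shape=tuple(blk.get("frame_shape",
                                                  (1, 21, 20))))
                    io.save_frameset(fs, frames_path)
                    record(stage, [frames_path], t0)
                elif mode == "eeg":
                    cfg_kwargs = dict(blk.get("eeg", {}))
                    if "recipes" in cfg_kwargs:
                        cfg_kwargs["recipes"] = {
                            k: OscillationRecipe(**v)
                            for k, v in cfg_kwargs["recipes"].items()}
                    eeg_cfg = EEGSynthConfig(**cfg_kwargs)
                    recs = generate_eeg_cohort(
                        eeg_cfg, blk.get("n_subjects_per_class", 5),
                        stage_seed["simulate"])
                    paths = []
                    for rec in recs:
                        p = outdir / f"eeg_{rec.subject_id}.h5"
                        io.save_recording(rec, p)
                        paths.append(p)
                    record(stage, paths, t0)
                else:
                    raise ConfigError(f"unknown simulate mode {mode!r}")
            elif stage == "preprocess":
                recs = sorted(outdir.glob("eeg_*.h5"))
                if not recs:
                    raise StageError(
                        "preprocess: no eeg_*.h5 recordings found; run the "
                        "simulate stage in 'eeg' mode or place recordings "
                        f"in {outdir}")
                recordings = [io.load_recording(p) for p in recs]
                fs = build_frameset(
                    recordings,
                    max_frames=config.preprocess.get("max_frames", 148))
                io.save_frameset(fs, frames_path)
                record(stage, [frames_path], t0)
            elif stage == "train":
                if not frames_path.exists():
                    raise StageError(
                        "train: missing frames.h5; run simulate/preprocess "
                        "first")
                fs = io.load_frameset(frames_path)
                norm = FrameNormalizer().fit(fs.frames)
                fs_norm = FrameSet(norm.transform(fs.frames),
                                   fs.subject_ids, fs.labels, fs.freq_axis,
                                   fs.channel_labels)
                model = _build_model(config.train, stage_seed["train"])
                model.fit(fs_norm)
                ckpt = outdir / "model.h5"
                models.save_model(model, ckpt)
                np.savez(outdir / "normalization.npz",
                         mean=norm.mean_, sd=norm.sd_)
                record(stage, [ckpt, ckpt.with_suffix(".h5.json"),
                               outdir / "normalization.npz"], t0)
            elif stage == "evaluate":
                if not frames_path.exists():
                    raise StageError("evaluate: missing frames.h5")
                fs = io.load_frameset(frames_path)
                blk = config.evaluate
                summary = run_experiments(
                    fs, lambda s: _build_model(blk, s),
                    n_experiments=blk.get("n_experiments", 10),
                    rng_seed=stage_seed["evaluate"])
                spath = outdir / "summary.json"
                spath.write_text(json.dumps(summary.to_dict(), indent=2,
                                            sort_keys=True))
                fpath = outdir / "folds.csv"
                summary.folds_frame().to_csv(fpath, index=False)
                record(stage, [spath, fpath], t0)
            elif stage == "dream":
                ckpt = outdir / "model.h5"
                if not ckpt.exists():
                    raise StageError("dream: missing model.h5; run the "
                                     "train stage first")
                model = models.load_model(ckpt)
                blk = config.dream
                images = {}
                for cls_idx in range(len(model.classes_)):
                    img = dream(model, DreamConfig(
                        target_class=cls_idx,
                        n_steps=blk.get("n_steps", 500),
                        step_size=blk.get("step_size", 0.1),
                        seed=stage_seed["dream"] + cls_idx))
                    images[cls_idx] = img
                diff = class_difference(images[0], images[1]) \
                    if len(images) >= 2 else None
                dpath = outdir / "dreams.h5"
                import h5py
                with h5py.File(dpath, "w") as f:
                    for cls_idx, img in images.items():
                        g = f.create_group(f"class{cls_idx}")
                        g.create_dataset("values", data=img.values)
                        g.attrs["achieved_score"] = img.achieved_score
                    if diff is not None:
                        f.create_dataset("difference", data=diff.values)
                    f.create_dataset("freq_axis",
                                     data=images[0].freq_axis)
                record(stage, [dpath], t0)
        except (ConfigError, StageError):
            raise
        except Exception as err:
            raise StageError(f"stage {stage!r} failed: {err}") from err
        logger.info("stage %s done in %.2f s", stage,
                    manifest.stage_seconds[stage])

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
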