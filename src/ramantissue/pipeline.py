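"""End-to-end pipeline: simulate -> preprocess -> split -> train -> evaluate.

A single :class:`PipelineConfig` drives every stage. One global seed fans
out to per-stage seeds through fixed ``numpy`` seed-sequence spawn keys,
so any stage can be re-run in isolation and reproduce its part of a full
run. Every artifact written into the run directory is derivable from the
config snapshot plus the seed alone; ``metrics.json`` carries no
timestamps, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import yaml

from . import io as rio
from .evaluation import (
    TissueOntology,
    clinical_alert,
    confusion_matrix,
    per_class_metrics,
    precision_recall,
)
from .nn.resnet import (
    ResNetConfig,
    build_model,
    count_parameters,
    reduced_block_plan,
)
from .preprocess import PreprocessConfig, preprocess_dataset
from .simulate import (
    default_profiles,
    generate_dataset,
    table1_counts,
    table1_scaled,
)
from .spectra import LabeledDataset
from .training import TrainConfig, stratified_split, train

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "stage_seed",
    "scaled_down_config",
]

# Fixed spawn keys: stage name -> child index of the global seed sequence.
STAGE_KEYS = {"simulate": 0, "preprocess": 1, "split": 2, "train": 3, "evaluate": 4}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGE_KEYS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SimulateSection:
    preset: str = "table1_scaled"
    factor: float = 0.01
    counts: Optional[Dict[str, int]] = None  # explicit counts override preset

    def resolve_counts(self) -> Dict[str, int]:
        if self.counts is not None:
            return dict(self.counts)
        if self.preset == "table1":
            return table1_counts()
        if self.preset == "table1_scaled":
            return table1_scaled(self.factor)
        raise PipelineError(f"stage 'simulate': unknown preset {self.preset!r}")


@dataclass
class PipelineConfig:
    """Sections mirror the per-stage config types; round-trips through YAML."""

    seed: int = 0
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: Optional[ResNetConfig] = None  # input_length filled after preprocess
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": dataclasses.asdict(self.simulate),
            "preprocess": {
                **{k: v for k, v in dataclasses.asdict(self.preprocess).items()},
                "skip_stages": list(self.preprocess.skip_stages),
            },
            "model": self.model.to_dict() if self.model else None,
            "train": self.train.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "model" not in d:
            raise PipelineError("config validation: missing 'model' section")
        pp = dict(d.get("preprocess", {}))
        if "skip_stages" in pp:
            pp["skip_stages"] = tuple(pp["skip_stages"])
        return cls(
            seed=int(d.get("seed", 0)),
            simulate=SimulateSection(**d.get("simulate", {})),
            preprocess=PreprocessConfig(**pp),
            model=ResNetConfig.from_dict(d["model"]) if d["model"] else None,
            train=TrainConfig(**d.get("train", {})),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def scaled_down_config(seed: int = 0, per_class: int = 250,
                       epochs: int = 10) -> PipelineConfig:
    """CPU-scale study configuration: ``per_class`` spectra per tissue class
    (80/20 stratified split), the reduced-width network (16/32/64 channels),
    and a short training budget. Generator noise and profiles stay at their
    defaults; only the problem size and model width shrink."""
    from .simulate import TISSUE_CLASSES

    return PipelineConfig(
        seed=seed,
        simulate=SimulateSection(counts={c: per_class for c in TISSUE_CLASSES}),
        model=ResNetConfig(stem_channels=16, block_plan=reduced_block_plan()),
        train=TrainConfig(epochs=epochs, batch_size=32),
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: PipelineConfig, out_dir: Union[str, Path],
                 dataset: Optional[LabeledDataset] = None,
                 log: bool = True) -> Path:
    """Execute the full pipeline and populate a run directory.

    Writes ``config.yaml`` (snapshot), ``metrics.json``,
    ``confusion_matrix.csv``, ``clinical_alert.json``, ``history.csv``,
    ``pr_curves/<class>.csv`` and a JSON-lines ``log.jsonl``. When
    ``dataset`` is given the simulate stage is skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "log.jsonl"
    log_fh = open(log_path, "a") if log else None

    def emit(stage: str, **fields) -> None:
        if log_fh is not None:
            rec = {"ts": time.time(), "stage": stage, **fields}
            log_fh.write(json.dumps(rec, default=_json_default) + "\n")
            log_fh.flush()

    ontology = TissueOntology.default()
    try:
        # -- simulate -----------------------------------------------------
        if dataset is None:
            try:
                counts = cfg.simulate.resolve_counts()
                rng = np.random.default_rng(stage_seed(cfg.seed, "simulate"))
                dataset = generate_dataset(default_profiles(), counts, rng)
                emit("simulate", n_spectra=len(dataset), counts=counts)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

        # -- preprocess ---------------------------------------------------
        try:
            processed = preprocess_dataset(dataset, cfg.preprocess)
            emit("preprocess", n_channels=processed.intensities.shape[1])
        except Exception as exc:
            raise PipelineError(f"stage 'preprocess' failed: {exc}") from exc

        # -- split --------------------------------------------------------
        try:
            train_set, test_set = stratified_split(
                processed, cfg.train.split_fraction,
                seed=stage_seed(cfg.seed, "split"),
            )
            emit("split", n_train=len(train_set), n_test=len(test_set))
        except Exception as exc:
            raise PipelineError(f"stage 'split' failed: {exc}") from exc

        # -- train --------------------------------------------------------
        try:
            model_cfg = cfg.model
            if model_cfg is None:
                raise PipelineError("config validation: missing 'model' section")
            if model_cfg.input_length != processed.intensities.shape[1]:
                model_cfg = dataclasses.replace(
                    model_cfg, input_length=processed.intensities.shape[1]
                )
            train_cfg = cfg.train
            if train_cfg.seed == 0:
                train_cfg = dataclasses.replace(
                    train_cfg, seed=stage_seed(cfg.seed, "train")
                )
            model = build_model(dataclasses.replace(
                model_cfg, seed=stage_seed(cfg.seed, "train")
            ))
            classes = list(ontology.classes)
            model, history = train(model, train_set, train_cfg, classes=classes)
            emit("train", epochs=len(history.train_loss),
                 selected_epoch=history.selected_epoch,
                 parameters=count_parameters(model))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'train' failed: {exc}") from exc

        # -- evaluate -----------------------------------------------------
        try:
            scores = model.predict_proba(test_set.intensities)
            pred_idx = scores.argmax(axis=1)
            y_pred = np.array([classes[i] for i in pred_idx])
            y_true = test_set.labels
            cm = confusion_matrix(y_true, y_pred, ontology)
            metrics = per_class_metrics(cm)
            ca = clinical_alert(cm, ontology)
            curves = precision_recall(scores, y_true, classes)
            emit("evaluate", accuracy=metrics.accuracy, overall_ca=ca.overall_ca)
        except Exception as exc:
            raise PipelineError(f"stage 'evaluate' failed: {exc}") from exc
    finally:
        if log_fh is not None:
            log_fh.close()

    # -- artifacts (deterministic: no timestamps) -------------------------
    cfg.to_yaml(out_dir / "config.yaml")

    header = "," + ",".join(cm.classes)
    rows = [header] + [
        cls + "," + ",".join(str(v) for v in cm.counts[i])
        for i, cls in enumerate(cm.classes)
    ]
    (out_dir / "confusion_matrix.csv").write_text("\n".join(rows) + "\n")

    metrics_doc = {
        "accuracy": metrics.accuracy,
        "weighted": metrics.weighted,
        "per_class": metrics.per_class,
        "degenerate": metrics.degenerate,
        "clinical_alert": {
            "per_class": ca.per_class,
            "overall_ca": ca.overall_ca,
            "overall_ca_macro": ca.overall_ca_macro,
        },
        "average_precision": {
            cls: curves[cls]["average_precision"] for cls in curves
        },
        "selected_epoch": history.selected_epoch,
        "n_train": len(train_set),
        "n_test": len(test_set),
        "seed": cfg.seed,
    }
    (out_dir / "metrics.json").write_text(
        json.dumps(metrics_doc, indent=2, sort_keys=True, default=_json_default)
        + "\n"
    )
    (out_dir / "clinical_alert.json").write_text(
        json.dumps(metrics_doc["clinical_alert"], indent=2, sort_keys=True,
                   default=_json_default) + "\n"
    )

    hist_lines = ["epoch,train_loss,val_loss"] + [
        f"{i},{tl!r},{vl!r}"
        for i, (tl, vl) in enumerate(zip(history.train_loss, history.val_loss))
    ]
    (out_dir / "history.csv").write_text("\n".join(hist_lines) + "\n")

    curve_dir = out_dir / "pr_curves"
    curve_dir.mkdir(exist_ok=True)
    for cls, c in curves.items():
        n = len(c["precision"])
        lines = ["threshold,precision,recall"]
        thr = list(c["thresholds"]) + [""]
        for t, p, r in zip(thr, c["precision"], c["recall"]):
            lines.append(f"{t},{p!r},{r!r}")
        (curve_dir / f"{cls}.csv").write_text("\n".join(lines) + "\n")

    return out_dir
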