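"""End-to-end experiment matrix: pretexts x reduction levels x seeds.

For every master-seed replicate the pipeline generates one phantom dataset,
cleans it, splits it 70/20/10, pretrains one encoder per pretext task on
the full (unreduced) training images, and then, for every reduction level,
performs transfer surgery and fine-tunes on the reduced train/val
partitions.  Each cell is scored on the fixed held-out test partition
(accuracy, metric battery, AUC, FGSM/PGD attack effects), on an
out-of-distribution blob set (overconfidence score), and on a
distribution-shifted second domain.

Per-cell seeds derive from the master seed through ``SeedSequence`` spawn
keys indexed by (stage, task, reduction, replicate), so cells are
independent and insensitive to execution order; a resumed run therefore
reproduces exactly what a single pass would have produced.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .models import (autoencoder_spec, encoder_spec, simclr_model,
                     build_model, transfer_surgery)
from .preprocessing import preprocess_set
from .pretext import (LossSpec, make_noise_pretext, make_reconstruction_pretext,
                      make_rotation_pretext, make_simclr_views)
from .robustness import AttackParams, attack_effect, ood_score
from .stats import build_report, confusion_from_predictions, confusion_metrics, roc_auc
from .synthetic import (NoiseConfig, PhantomConfig, generate_dataset,
                        generate_ood_set, generate_shifted_dataset)
from .training import SplitPlan, TrainConfig, split_dataset, accuracy

__all__ = [
    "ExperimentConfig",
    "desk_config",
    "run_experiment",
    "resume",
    "load_cells",
    "protocol_summary",
]

TASKS = ("noise", "rotation", "reconstruction", "simclr")


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tasks: tuple[str, ...] = TASKS
    reductions: tuple[float, ...] = (0.0, 0.2, 0.5, 0.7)
    n_seeds: int = 1
    master_seed: int = 0
    pretext_epochs: int = 10
    downstream_epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 32
    noise_factor: float = 0.01
    attack: AttackParams = field(default_factory=AttackParams)
    ood_n: int = 100
    domain_shift: float = 1.0
    output_dir: str = "runs/experiment"

    def __post_init__(self):
        if not self.tasks or not self.reductions or self.n_seeds < 1:
            raise ValueError("tasks, reductions and n_seeds must be non-empty")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            if isinstance(ph.get("noise"), dict):
                ph["noise"] = NoiseConfig(**ph["noise"])
            d["phantom"] = PhantomConfig(**ph)
        if isinstance(d.get("attack"), dict):
            d["attack"] = AttackParams(**d["attack"])
        for key in ("tasks", "reductions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def desk_config(master_seed: int = 0, output_dir: str = "runs/desk",
                tasks: tuple[str, ...] = TASKS,
                reductions: tuple[float, ...] = (0.0, 0.2, 0.5, 0.7),
                n_seeds: int = 1, n_per_class: int = 200) -> ExperimentConfig:
    """Desk-scale profile: 32 px phantoms, rescaled schedule and noise factor.

    At 32 px with a few hundred images per class an epoch is only a handful
    of optimizer steps, so the learning rate is raised to 5e-4 and the
    downstream schedule lengthened to 40 epochs to reach the same converged
    regime the full-scale settings (1e-4, 20 epochs) reach on real-size
    data.  The pretext noise factor is likewise raised to 0.05: a 32 px
    image carries ~32x fewer pixels of evidence for the noise-detection
    pretext than a 180 px image, so the desk task needs a stronger per-pixel
    signal to be learnable at all.
    """
    return ExperimentConfig(
        phantom=PhantomConfig(image_size=32, n_per_class=n_per_class),
        tasks=tasks, reductions=reductions, n_seeds=n_seeds,
        master_seed=master_seed, pretext_epochs=10, downstream_epochs=40,
        learning_rate=5e-4, noise_factor=0.05, output_dir=output_dir)


def _seed(cfg: ExperimentConfig, *key: int) -> int:
    ss = np.random.SeedSequence(cfg.master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


_STAGE = {"data": 0, "ood": 1, "shift": 2, "pretext": 3, "surgery": 4,
          "downstream": 5, "attack": 6}
_TASK_INDEX = {t: i for i, t in enumerate(TASKS)}


def _prepare_data(cfg: ExperimentConfig, rep: int):
    phantom = PhantomConfig(**{**asdict(cfg.phantom),
                               "noise": cfg.phantom.noise,
                               "seed": _seed(cfg, _STAGE["data"], rep),
                               "domain_shift": 0.0})
    data = preprocess_set(generate_dataset(phantom))
    ood = preprocess_set(generate_ood_set(
        cfg.ood_n, phantom.image_size, _seed(cfg, _STAGE["ood"], rep)))
    shifted_cfg = PhantomConfig(**{**asdict(phantom), "noise": phantom.noise,
                                   "seed": _seed(cfg, _STAGE["shift"], rep),
                                   "domain_shift": cfg.domain_shift})
    shifted = preprocess_set(generate_shifted_dataset(shifted_cfg))
    return data, ood, shifted


def _pretrain(cfg: ExperimentConfig, task: str, train_images, rep: int):
    from .training import train_pretext  # local import avoids cycle at init

    size = cfg.phantom.image_size
    seed = _seed(cfg, _STAGE["pretext"], _TASK_INDEX[task], rep)
    shape = (size, size, 3)
    if task in ("noise", "rotation"):
        model = build_model(encoder_spec(shape), seed=seed)
        maker = make_noise_pretext if task == "noise" else make_rotation_pretext
        if task == "noise":
            dataset = maker(train_images, noise_factor=cfg.noise_factor,
                            seed=seed + 1)
        else:
            dataset = maker(train_images, seed=seed + 1)
        loss = LossSpec("bce")
    elif task == "reconstruction":
        model = build_model(autoencoder_spec(shape), seed=seed)
        dataset = make_reconstruction_pretext(train_images)
        loss = LossSpec("mse")
    else:
        model = simclr_model(encoder_spec(shape), seed=seed)
        dataset = make_simclr_views(train_images, seed=seed + 1)
        loss = LossSpec("nt_xent")
    tc = TrainConfig(batch_size=cfg.batch_size, epochs=cfg.pretext_epochs,
                     learning_rate=cfg.learning_rate, loss=loss, seed=seed + 2)
    model, log = train_pretext(dataset, model, tc)
    return model, log


def _run_cell(cfg: ExperimentConfig, task: str, reduction: float, rep: int,
              data, ood, shifted, pretext_model, run_dir: str) -> dict:
    from .training import train_downstream

    red_idx = int(round(reduction * 10))
    plan = SplitPlan(reduction=reduction, seed=_seed(cfg, _STAGE["data"], rep))
    train, val, test = split_dataset(data, plan)
    sseed = _seed(cfg, _STAGE["surgery"], _TASK_INDEX[task], red_idx, rep)
    model = transfer_surgery(pretext_model, seed=sseed)
    tc = TrainConfig(batch_size=cfg.batch_size, epochs=cfg.downstream_epochs,
                     learning_rate=cfg.learning_rate, loss=LossSpec("bce"),
                     seed=_seed(cfg, _STAGE["downstream"], _TASK_INDEX[task],
                                red_idx, rep))
    model, log = train_downstream(model, train, val, tc)
    frame = log.to_frame()

    scores = model.predict(test.images)
    counts = confusion_from_predictions(test.labels, scores)
    metrics = confusion_metrics(counts)
    auc, _ = roc_auc(scores, test.labels)
    attack = AttackParams(**{**asdict(cfg.attack),
                             "seed": _seed(cfg, _STAGE["attack"], rep)})
    rob = attack_effect(model, test.images, test.labels, attack)
    rob.ood_score = ood_score(model, ood.images)
    shifted_scores = model.predict(shifted.images)
    shifted_acc = accuracy(shifted.labels, shifted_scores)
    shifted_auc, _ = roc_auc(shifted_scores, shifted.labels)

    cell = {
        "task": task, "reduction": reduction, "seed": rep,
        "n_train": len(train), "n_val": len(val), "n_test": len(test),
        "train_acc": float(frame["train_acc"].iloc[-1]) if len(frame) else np.nan,
        "val_acc": float(frame["val_acc"].iloc[-1]) if len(frame) else np.nan,
        "train_loss": float(frame["train_loss"].iloc[-1]) if len(frame) else np.nan,
        "val_loss": float(frame["val_loss"].iloc[-1]) if len(frame) else np.nan,
        "test_acc": accuracy(test.labels, scores),
        "clean_acc": rob.clean_accuracy,
        "fgsm_acc": rob.adv_accuracy["fgsm"],
        "pgd_acc": rob.adv_accuracy["pgd"],
        "fgsm_drop": rob.accuracy_drop["fgsm"],
        "pgd_drop": rob.accuracy_drop["pgd"],
        "fgsm_category": rob.category["fgsm"],
        "pgd_category": rob.category["pgd"],
        "ood_score": rob.ood_score,
        "shifted_acc": shifted_acc,
        "shifted_auc": shifted_auc,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "precision": metrics.precision,
        "f_score": metrics.f_score,
        "auc": auc,
        "weights_checksum": model.checksum(),
    }
    cell_dir = os.path.join(run_dir, "cells", _cell_name(task, reduction, rep))
    os.makedirs(cell_dir, exist_ok=True)
    frame.to_csv(os.path.join(cell_dir, "downstream_log.csv"), index=False)
    with open(os.path.join(cell_dir, "report.json"), "w") as fh:
        json.dump(cell, fh, indent=2, sort_keys=True)
    return cell


def _cell_name(task: str, reduction: float, rep: int) -> str:
    return f"{task}_r{int(round(reduction * 100)):02d}_s{rep}"


def _ledger_append(run_dir: str, record: dict) -> None:
    with open(os.path.join(run_dir, "ledger.jsonl"), "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def _done_cells(run_dir: str) -> set[str]:
    path = os.path.join(run_dir, "ledger.jsonl")
    done = set()
    if os.path.exists(path):
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                if rec.get("status") == "done":
                    done.add(rec["cell"])
    return done


def run_experiment(cfg: ExperimentConfig,
                   skip_done: bool = False) -> str:
    """Execute the matrix; returns the run directory.

    With ``skip_done=True`` cells already marked done in the ledger are not
    recomputed (used by :func:`resume`).  Failures are recorded in the
    ledger and do not stop the remaining cells.
    """
    run_dir = cfg.output_dir
    os.makedirs(run_dir, exist_ok=True)
    cfg_path = os.path.join(run_dir, "config.yaml")
    if os.path.exists(cfg_path):
        existing = ExperimentConfig.from_yaml(cfg_path)
        if existing.config_hash() != cfg.config_hash():
            raise ValueError(
                "run directory holds a different configuration "
                f"(hash {existing.config_hash()} != {cfg.config_hash()})")
    else:
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    done = _done_cells(run_dir) if skip_done else set()

    cells = []
    for rep in range(cfg.n_seeds):
        wanted = [(t, r) for t in cfg.tasks for r in cfg.reductions
                  if _cell_name(t, r, rep) not in done]
        if not wanted:
            continue
        data, ood, shifted = _prepare_data(cfg, rep)
        plan0 = SplitPlan(reduction=0.0, seed=_seed(cfg, _STAGE["data"], rep))
        train0, _, _ = split_dataset(data, plan0)
        pretext_cache: dict[str, object] = {}
        for task, reduction in wanted:
            name = _cell_name(task, reduction, rep)
            try:
                if task not in pretext_cache:
                    model, plog = _pretrain(cfg, task, train0.images, rep)
                    pretext_cache[task] = model
                    pdir = os.path.join(run_dir, "cells", f"{task}_pretext_s{rep}")
                    os.makedirs(pdir, exist_ok=True)
                    plog.to_frame().to_csv(
                        os.path.join(pdir, "pretext_log.csv"), index=False)
                cell = _run_cell(cfg, task, reduction, rep, data, ood,
                                 shifted, pretext_cache[task], run_dir)
                cells.append(cell)
                _ledger_append(run_dir, {"cell": name, "status": "done",
                                         "config_hash": cfg.config_hash(),
                                         "checksum": cell["weights_checksum"]})
            except Exception as exc:  # noqa: BLE001 - cell isolation
                _ledger_append(run_dir, {"cell": name, "status": "failed",
                                         "config_hash": cfg.config_hash(),
                                         "error": repr(exc)})
    _write_report(run_dir)
    return run_dir


def resume(run_dir: str) -> str:
    """Complete only the missing cells of a partial run."""
    cfg = ExperimentConfig.from_yaml(os.path.join(run_dir, "config.yaml"))
    cfg = ExperimentConfig.from_dict({**cfg.to_dict(), "output_dir": run_dir})
    return run_experiment(cfg, skip_done=True)


def load_cells(run_dir: str) -> pd.DataFrame:
    """Collect all finished cell reports into one tidy frame."""
    rows = []
    cells_dir = os.path.join(run_dir, "cells")
    if os.path.isdir(cells_dir):
        for name in sorted(os.listdir(cells_dir)):
            path = os.path.join(cells_dir, name, "report.json")
            if os.path.exists(path):
                with open(path) as fh:
                    rows.append(json.load(fh))
    return pd.DataFrame(rows)


def _write_report(run_dir: str) -> None:
    cells = load_cells(run_dir)
    report_dir = os.path.join(run_dir, "report")
    os.makedirs(report_dir, exist_ok=True)
    if cells.empty:
        return
    report = build_report(cells)
    report["summary"].to_csv(os.path.join(report_dir, "summary.csv"),
                             index=False)
    report["metrics"].to_csv(os.path.join(report_dir, "metrics.csv"),
                             index=False)
    with open(os.path.join(report_dir, "stats.json"), "w") as fh:
        json.dump(report["stats"], fh, indent=2, sort_keys=True, default=float)


def protocol_summary(cells: pd.DataFrame) -> dict:
    """Across-seed medians of the headline quantities per (task, reduction)."""
    out: dict = {}
    for (task, reduction), grp in cells.groupby(["task", "reduction"]):
        key = f"{task}_r{int(round(reduction * 100)):02d}"
        out[key] = {
            "val_acc": float(grp["val_acc"].median()),
            "test_acc": float(grp["test_acc"].median()),
            "fgsm_drop": float(grp["fgsm_drop"].median()),
            "pgd_drop": float(grp["pgd_drop"].median()),
            "ood_score": float(grp["ood_score"].median()),
            "auc": float(grp["auc"].median()),
            "shifted_acc": float(grp["shifted_acc"].median()),
        }
    return out
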