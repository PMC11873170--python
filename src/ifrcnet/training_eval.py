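"""Training loop, five-round cross-validation driver, and the ablation runner.

Defaults follow the training recipe the networks were designed around: batch
size 2, Adam with learning rate 1e-4, cross-entropy losses, model selection on
the evaluation subset (Dice for segmentation, accuracy for classification),
with test metrics computed exactly once per round. Desk-scale presets
(`desk_scale_config`) use batch 8 and a higher learning rate so the synthetic
benchmarks converge within minutes on a CPU.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data_pipeline import FoldPlan, make_fold_plan
from .errors import ConfigError
from .if_rcnet import FusionConfig, build_ifrcnet
from .metrics import ClsReport, SegReport, cls_metrics, seg_metrics
from .nn import Tensor
from .rca_net import ClsNetConfig, cls_loss
from .rca_unet import RCAUNet, SegNetConfig, seg_loss

__all__ = ["TrainConfig", "CVResult", "train", "evaluate", "cross_validate",
           "run_ablation", "desk_scale_config"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 2
    lr: float = 1e-4
    optimizer: str = "adam"     # or "sgd"
    epochs: int = 50
    seed: int = 0
    device: str = "cpu"
    patience: int = 10          # early stopping on the eval metric
    max_steps: int | None = None

    def __post_init__(self):
        if self.device != "cpu":
            raise ConfigError("this backend runs on CPU only (device='cpu')")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")


def desk_scale_config(**overrides) -> TrainConfig:
    """Small-sample CPU preset: batch 8, lr 1e-3, few epochs."""
    base = dict(batch_size=8, lr=1e-3, optimizer="adam", epochs=10, patience=5)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class CVResult:
    per_round: list                 # 5 reports (ClsReport or SegReport)
    mean_report: dict               # field-wise arithmetic means

    def to_dict(self) -> dict:
        return {"per_round": [r.to_dict() for r in self.per_round],
                "mean": self.mean_report}


def _image_tensor(samples) -> np.ndarray:
    """Stack standardized samples into an (N, 3, H, W) float32 batch array."""
    return np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)


def _forward(model, x: Tensor):
    out = model(x)
    return out.logits if hasattr(out, "logits") else out


def _score(model, samples, task: str):
    """Evaluate `model` on `samples`; returns (metric, report)."""
    model.eval()
    xs = _image_tensor(samples)
    preds, masks, labels, truths = [], [], [], []
    bs = 8
    for i in range(0, len(samples), bs):
        chunk = samples[i:i + bs]
        with nn.no_grad():
            out = model(Tensor(xs[i:i + bs]))
        if task == "seg":
            masks.extend(list(out.mask))
            truths.extend([s.mask for s in chunk])
        else:
            logits = out.logits if hasattr(out, "logits") else out
            preds.extend(list(logits.data.argmax(axis=1)))
            labels.extend([s.label for s in chunk])
    model.train()
    if task == "seg":
        report = seg_metrics(masks, truths)
        return report.dice, report
    report = cls_metrics(preds, labels)
    return report.accuracy, report


def evaluate(model, samples, task: str):
    """Public scoring helper; returns a SegReport or ClsReport."""
    return _score(model, samples, task)[1]


def train(model, samples, split, cfg: TrainConfig, task: str):
    """Train on `split[0]` with model selection on `split[1]`.

    Returns a history dict: per-epoch train loss and eval metric, the ids the
    optimizer saw, and the number of optimizer steps; the model ends loaded
    with the best-eval checkpoint.
    """
    if task not in ("seg", "cls"):
        raise ValueError(f"unknown task {task!r}")
    train_ids, eval_ids = list(split[0]), list(split[1])
    by_id = {s.id: s for s in samples}
    train_samples = [by_id[i] for i in train_ids]
    eval_samples = [by_id[i] for i in eval_ids]
    params = list(model.classifier_parameters()
                  if hasattr(model, "classifier_parameters") else model.parameters())
    opt = nn.build_optimizer(cfg.optimizer, params, cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    xs = _image_tensor(train_samples)
    if task == "seg":
        ys = np.stack([s.mask for s in train_samples])
    else:
        ys = np.array([s.label for s in train_samples], dtype=np.int64)

    model.train()
    history = {"epochs": [], "steps": 0, "trained_ids": sorted(train_ids)}
    best_metric, best_state, since_best = -np.inf, None, 0
    stop = False
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = _forward(model, Tensor(xs[idx]))
            loss = (seg_loss(logits, ys[idx]) if task == "seg"
                    else cls_loss(logits, ys[idx]))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            history["steps"] += 1
            if cfg.max_steps is not None and history["steps"] >= cfg.max_steps:
                stop = True
                break
        metric, _ = _score(model, eval_samples, task) if eval_samples else (0.0, None)
        history["epochs"].append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)) if losses else None,
             "eval_metric": metric})
        log.info("epoch %d: loss=%.4f eval=%.4f", epoch,
                 history["epochs"][-1]["train_loss"] or float("nan"), metric)
        if metric > best_metric:
            best_metric, since_best = metric, 0
            best_state = copy.deepcopy(model.state_dict())
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        if stop:
            break
    if best_state is not None and eval_samples:
        model.load_state_dict(best_state)
    return history


def cross_validate(samples, model_builder, cfg: TrainConfig, task: str,
                   plan: FoldPlan | None = None) -> CVResult:
    """Five rounds: fresh model per round, train/select/test, then average."""
    ids = [s.id for s in samples]
    labels = [s.label for s in samples] if all(
        s.label is not None for s in samples) else None
    plan = plan or make_fold_plan(ids, cfg.seed, labels=labels)
    by_id = {s.id: s for s in samples}
    reports = []
    for r, (train_ids, test_ids, eval_ids) in enumerate(plan.rounds):
        round_seed = cfg.seed * 1000 + r
        model = model_builder(round_seed, (train_ids, test_ids, eval_ids))
        round_cfg = TrainConfig(**{**asdict(cfg), "seed": round_seed})
        train(model, samples, (train_ids, eval_ids), round_cfg, task)
        reports.append(evaluate(model, [by_id[i] for i in test_ids], task))
    return CVResult(per_round=reports, mean_report=_mean_report(reports, task))


def _mean_report(reports, task: str) -> dict:
    if task == "seg":
        return {k: float(np.mean([getattr(r, k) for r in reports]))
                for k in ("miou", "dice", "mhd")}
    return {k: float(np.mean([getattr(r, k) for r in reports]))
            for k in ("accuracy", "f1")}


def run_ablation(samples, cfg: TrainConfig,
                 seg_cfg: SegNetConfig | None = None,
                 cls_cfg: ClsNetConfig | None = None,
                 fusion_cfg: FusionConfig | None = None,
                 seg_epochs: int | None = None) -> dict:
    """Table-shaped ablation: baseline / +mixed / +fusion / +both on shared folds.

    The segmentation network is trained once per round and shared by the three
    configurations that need it; classifier seeds are identical across
    configurations within a round.
    """
    ids = [s.id for s in samples]
    labels = [s.label for s in samples]
    plan = make_fold_plan(ids, cfg.seed, labels=labels)
    by_id = {s.id: s for s in samples}
    seg_nets = []
    seg_train_cfg = TrainConfig(**{**asdict(cfg),
                                   "epochs": seg_epochs or cfg.epochs})
    for r, (train_ids, test_ids, eval_ids) in enumerate(plan.rounds):
        seg_net = RCAUNet(seg_cfg or SegNetConfig(), seed=cfg.seed * 1000 + r)
        train(seg_net, samples,
              (train_ids, eval_ids),
              TrainConfig(**{**asdict(seg_train_cfg), "seed": cfg.seed * 1000 + r}),
              "seg")
        seg_net.eval()
        seg_nets.append(seg_net)

    results: dict[str, CVResult] = {}
    for ablation in ("base", "mixed", "fusion", "both"):
        reports = []
        for r, (train_ids, test_ids, eval_ids) in enumerate(plan.rounds):
            round_seed = cfg.seed * 1000 + r
            model = build_ifrcnet(seg_nets[r], ablation, cls_cfg=cls_cfg,
                                  fusion_cfg=fusion_cfg, seed=round_seed)
            round_cfg = TrainConfig(**{**asdict(cfg), "seed": round_seed})
            train(model, samples, (train_ids, eval_ids), round_cfg, "cls")
            reports.append(evaluate(model, [by_id[i] for i in test_ids], "cls"))
        results[ablation] = CVResult(per_round=reports,
                                     mean_report=_mean_report(reports, "cls"))
    return results


def ablation_table(results: dict) -> str:
    """Render ablation results as a small text table."""
    lines = [f"{'configuration':<12} {'accuracy':>9} {'f1':>9}"]
    for name in ("base", "mixed", "fusion", "both"):
        m = results[name].mean_report
        lines.append(f"{name:<12} {m['accuracy']:>9.4f} {m['f1']:>9.4f}")
    return "\n".join(lines)


def results_to_json(results: dict, **kwargs) -> str:
    return json.dumps({k: v.to_dict() for k, v in results.items()},
                      sort_keys=True, **kwargs)
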