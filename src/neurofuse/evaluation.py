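"""Classification metrics (accuracy, macro recall/F1/AUC) and the ablation
harness that trains every model variant on identical splits.

Averaging is macro (unweighted class mean) throughout; classes absent from
the evaluated labels are excluded from macro means and reported as warnings.
AUC is the one-vs-rest rank statistic with midrank handling of tied scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import (
    FusionModel,
    ModelConfig,
    ValidationError,
    count_parameters,
    estimate_flops,
)
from .synthetic import SynthSpec, generate, holdout_split
from .training import (
    AblationSpec,
    ArrayDataset,
    TrainConfig,
    build_ablation,
    train,
)

__all__ = [
    "MetricReport",
    "classification_metrics",
    "predict_dataset",
    "evaluate_model",
    "run_ablation_suite",
]


@dataclass
class MetricReport:
    accuracy: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    per_class: pd.DataFrame
    n_parameters: Optional[int] = None
    flops: Optional[int] = None
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
        }
        if self.n_parameters is not None:
            out["n_parameters"] = self.n_parameters
        if self.flops is not None:
            out["flops"] = self.flops
        return out


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-statistic AUC with midranks for ties."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)
    return (ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def classification_metrics(probs: np.ndarray, labels: np.ndarray) -> MetricReport:
    """Compute the metric suite from predicted probabilities.

    ``probs``: (N, C) rows summing to 1; ``labels``: length-N integers.
    Argmax ties break toward the lower class index.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValidationError("probs must be (N, C) aligned with labels")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1")
    N, C = probs.shape
    pred = np.argmax(probs, axis=1)
    accuracy = float(np.mean(pred == labels))

    rows = []
    warnings: list[str] = []
    for cls in range(C):
        is_cls = labels == cls
        tp = int(np.sum(is_cls & (pred == cls)))
        fn = int(np.sum(is_cls & (pred != cls)))
        fp = int(np.sum(~is_cls & (pred == cls)))
        if not is_cls.any():
            warnings.append(f"class {cls} absent from labels; excluded from macros")
            rows.append(
                {"class": cls, "recall": np.nan, "precision": np.nan,
                 "f1": np.nan, "auc": np.nan, "support": 0}
            )
            continue
        recall = tp / (tp + fn)
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        if is_cls.all():
            warnings.append(f"class {cls} has no negatives; AUC undefined")
            auc = np.nan
        else:
            auc = _binary_auc(probs[:, cls], is_cls)
        rows.append(
            {"class": cls, "recall": recall, "precision": precision,
             "f1": f1, "auc": auc, "support": int(is_cls.sum())}
        )
    per_class = pd.DataFrame(rows)
    present = per_class["support"] > 0
    macro_recall = float(per_class.loc[present, "recall"].mean())
    macro_f1 = float(per_class.loc[present, "f1"].mean())
    auc_vals = per_class.loc[present, "auc"].dropna()
    macro_auc = float(auc_vals.mean()) if len(auc_vals) else float("nan")
    return MetricReport(
        accuracy=accuracy,
        macro_recall=macro_recall,
        macro_f1=macro_f1,
        macro_auc=macro_auc,
        per_class=per_class,
        warnings=warnings,
    )


def predict_dataset(
    model: FusionModel, data: ArrayDataset, batch_size: int = 128
) -> np.ndarray:
    """Per-sequence class probabilities (N, C); per-step heads are averaged
    over time."""
    out = []
    for start in range(0, len(data), batch_size):
        sl = slice(start, min(start + batch_size, len(data)))
        probs = model.forward(
            None if data.eeg is None else data.eeg[sl],
            None if data.frames is None else data.frames[sl],
            None if data.features is None else data.features[sl],
            train=False,
        ).data
        if probs.ndim == 3:
            probs = probs.mean(axis=1)
        out.append(probs)
    return np.concatenate(out, axis=0)


def evaluate_model(model: FusionModel, data: ArrayDataset) -> MetricReport:
    probs = predict_dataset(model, data)
    report = classification_metrics(probs, data.labels[:, 0])
    report.n_parameters = model.num_parameters()
    report.flops = estimate_flops(model.cfg, data.labels.shape[1], model.variant)
    return report


def run_ablation_suite(
    spec: SynthSpec,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seeds: list[int],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    variants: tuple[str, ...] = ("full", "no_cross_modal", "no_adaptive_attention", "no_eeg_stream"),
) -> pd.DataFrame:
    """Train every variant on identical per-seed splits, report medians/IQRs.

    Returns one row per variant with median and IQR columns per metric plus
    parameter/FLOP counts; failed trainings are recorded and skipped.
    """
    if len(seeds) < 3:
        raise ValidationError("need at least 3 seeds")
    results: dict[str, list[MetricReport | None]] = {v: [] for v in variants}
    for seed in seeds:
        data_spec = SynthSpec(**{**spec.__dict__, "seed": spec.seed + seed})
        dataset = generate(data_spec)
        arrays = ArrayDataset.from_triples(dataset.triples)
        tr, va, te = holdout_split(dataset, fractions, seed=seed)
        for variant in variants:
            model = build_ablation(model_cfg, AblationSpec(variant), seed=seed)
            cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
            try:
                model, record = train(
                    model, arrays.subset(tr), arrays.subset(va), cfg
                )
                if record.diverged:
                    raise ArithmeticError("training diverged")
                results[variant].append(evaluate_model(model, arrays.subset(te)))
            except (ArithmeticError, ValidationError):
                results[variant].append(None)

    rows = []
    for variant in variants:
        reports = results[variant]
        ok = [r for r in reports if r is not None]
        row: dict = {"variant": variant, "n_seeds": len(seeds), "n_failed": len(reports) - len(ok)}
        for metric in ("accuracy", "macro_recall", "macro_f1", "macro_auc"):
            vals = np.array([getattr(r, metric) for r in ok], dtype=float)
            if len(vals):
                q1, med, q3 = np.nanpercentile(vals, [25, 50, 75])
                row[f"{metric}_median"] = med
                row[f"{metric}_iqr"] = q3 - q1
            else:
                row[f"{metric}_median"] = np.nan
                row[f"{metric}_iqr"] = np.nan
        row["n_parameters"] = count_parameters(model_cfg, variant)
        row["flops"] = estimate_flops(model_cfg, spec.T, variant)
        rows.append(row)
    return pd.DataFrame(rows)
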