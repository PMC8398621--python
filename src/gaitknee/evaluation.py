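"""Accuracy battery for knee-angle predictions.

Three per-cycle statistics with prediction x_i and actual y_i:

* RMSE  = sqrt(mean (x_i - y_i)^2), degrees;
* MRE   = mean |(x_i - y_i) / x_i|  — note the *prediction* in the
  denominator, which is asymmetric but kept exactly in this form;
* R     = 1 - sum (y_i - x_i)^2 / sum (y_i - ybar)^2, the
  coefficient-of-determination form of the "correlation efficiency" (a
  Pearson correlation is logged alongside for diagnostics).

Agreement between predicted and actual angle is summarized Bland-Altman
style: mean bias of the differences with limits of agreement at
bias +/- 1.96 sample standard deviations, one difference per test gait cycle
(the per-cycle mean of prediction minus actual).

Knee flexion patterns are derived as 180 deg minus the angle, split into the
stance (0-60% GC) and swing (60-100% GC) phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .preprocessing import GaitCycle
from .regressor import LabeledCyclePair, predict_knee_angle

STANCE_SAMPLES = range(0, 60)
SWING_SAMPLES = range(60, 100)


@dataclass(frozen=True)
class MetricSet:
    rmse: float  # degrees
    mre: float  # dimensionless fraction
    r_value: float

    def __post_init__(self) -> None:
        assert self.rmse >= 0 and self.mre >= 0 and self.r_value <= 1.0


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_bias: float  # degrees
    upper_loa: float
    lower_loa: float
    differences: np.ndarray


@dataclass(frozen=True)
class FlexionPattern:
    flexion: np.ndarray  # 100 points, degrees
    stance_range: range = STANCE_SAMPLES
    swing_range: range = SWING_SAMPLES


@dataclass
class EvalReport:
    """Tables mirroring the standard reporting layout."""

    metrics: pd.DataFrame  # model, shoe, speed, rmse_deg, mre, r, pearson_r
    bland_altman: pd.DataFrame  # model, mean_bias, upper_loa, lower_loa
    flexion: pd.DataFrame  # model, shoe, speed, kind, sample_000..099


def accuracy_metrics(prediction, actual) -> MetricSet:
    """RMSE, MRE and R between one predicted and one actual cycle."""
    x = np.asarray(prediction, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: prediction {x.shape} vs actual "
                         f"{y.shape}")
    if np.any(x == 0.0):
        raise ValueError("MRE is undefined for zero prediction values")
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    mre = float(np.mean(np.abs((x - y) / x)))
    ss_res = float(np.sum((y - x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r = 1.0 - ss_res / ss_tot
    return MetricSet(rmse=rmse, mre=mre, r_value=r)


def bland_altman(per_cycle_differences) -> BlandAltmanResult:
    """Mean bias and +/- 1.96 SD limits of agreement."""
    d = np.asarray(per_cycle_differences, dtype=float)
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least two differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_bias=bias, upper_loa=bias + 1.96 * sd,
                             lower_loa=bias - 1.96 * sd, differences=d)


def flexion_pattern(angle_cycle) -> FlexionPattern:
    """Knee flexion (180 - angle) with the fixed stance/swing split."""
    v = (angle_cycle.values if isinstance(angle_cycle, GaitCycle)
         else np.asarray(angle_cycle, dtype=float))
    return FlexionPattern(flexion=180.0 - v)


def pearson_r(prediction, actual) -> float:
    x = np.asarray(prediction, dtype=float)
    y = np.asarray(actual, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_models(models: Dict[str, object],
                    test_pairs: Sequence[LabeledCyclePair],
                    training_subjects: Sequence[str]) -> EvalReport:
    """Full report: per model x shoe x speed metrics, per-model agreement,
    and mean predicted/actual flexion patterns per condition.

    ``test_pairs`` must come from subjects disjoint from
    ``training_subjects``; metrics are computed per cycle and averaged over
    the test cycles of each condition.
    """
    test_subjects = {p.subject for p in test_pairs}
    overlap = test_subjects & set(training_subjects)
    if overlap:
        raise ValueError(f"test subjects overlap training subjects: "
                         f"{sorted(overlap)}")
    metric_rows: List[dict] = []
    ba_rows: List[dict] = []
    flex_rows: List[dict] = []
    conditions = sorted({(p.shoe, p.speed) for p in test_pairs})
    for model_id in sorted(models):
        model = models[model_id]
        diffs = []
        for shoe, speed in conditions:
            pairs = [p for p in test_pairs
                     if p.shoe == shoe and p.speed == speed]
            per_cycle = []
            preds, actuals = [], []
            for p in pairs:
                pred = predict_knee_angle(model, p.pressure)
                actual = p.angle.values
                per_cycle.append(accuracy_metrics(pred.values, actual))
                diffs.append(float(np.mean(pred.values - actual)))
                preds.append(pred.values)
                actuals.append(actual)
            metric_rows.append({
                "model": model_id, "shoe": shoe, "speed": speed,
                "rmse_deg": float(np.mean([m.rmse for m in per_cycle])),
                "mre": float(np.mean([m.mre for m in per_cycle])),
                "r": float(np.mean([m.r_value for m in per_cycle])),
                "pearson_r": float(np.mean(
                    [pearson_r(pr, ac) for pr, ac in zip(preds, actuals)])),
                "n_cycles": len(pairs)})
            for kind, stack in (("predicted", preds), ("actual", actuals)):
                mean_flex = flexion_pattern(np.mean(stack, axis=0)).flexion
                row = {"model": model_id, "shoe": shoe, "speed": speed,
                       "kind": kind}
                row.update({f"sample_{i:03d}": mean_flex[i]
                            for i in range(100)})
                flex_rows.append(row)
        ba = bland_altman(diffs)
        ba_rows.append({"model": model_id, "mean_bias": ba.mean_bias,
                        "upper_loa": ba.upper_loa,
                        "lower_loa": ba.lower_loa})
    return EvalReport(metrics=pd.DataFrame(metric_rows),
                      bland_altman=pd.DataFrame(ba_rows),
                      flexion=pd.DataFrame(flex_rows))


# ---------------------------------------------------------------------------
# optional figures

def plot_bland_altman(report: EvalReport, models_diffs: Dict[str, np.ndarray],
                      path) -> None:
    """Scatter of per-cycle differences with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(models_diffs)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
    for ax, (model_id, d) in zip(axes[0], sorted(models_diffs.items())):
        ba = bland_altman(d)
        ax.scatter(np.arange(d.size), d, s=6)
        for y, style in ((ba.mean_bias, "-"), (ba.upper_loa, "--"),
                         (ba.lower_loa, "--")):
            ax.axhline(y, ls=style, c="k", lw=0.8)
        ax.set_title(model_id)
        ax.set_xlabel("test cycle")
        ax.set_ylabel("difference (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_flexion_patterns(report: EvalReport, path) -> None:
    """Mean predicted vs actual flexion per shoe x speed condition."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flex = report.flexion
    shoes = sorted(flex["shoe"].unique())
    speeds = sorted(flex["speed"].unique())
    sample_cols = [c for c in flex.columns if c.startswith("sample_")]
    fig, axes = plt.subplots(len(speeds), len(shoes),
                             figsize=(3.2 * len(shoes), 2.6 * len(speeds)),
                             squeeze=False)
    for i, speed in enumerate(speeds):
        for j, shoe in enumerate(shoes):
            ax = axes[i][j]
            sub = flex[(flex.shoe == shoe) & (flex.speed == speed)]
            actual = sub[sub.kind == "actual"].iloc[0][sample_cols].to_numpy(float)
            ax.plot(actual, "k-", lw=1.5, label="actual")
            for model_id in sorted(sub[sub.kind == "predicted"]["model"].unique()):
                row = sub[(sub.kind == "predicted") & (sub.model == model_id)]
                ax.plot(row.iloc[0][sample_cols].to_numpy(float), lw=0.8,
                        label=model_id)
            ax.set_title(f"{shoe} / {speed}")
            ax.set_xlabel("% gait cycle")
            ax.set_ylabel("flexion (deg)")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
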