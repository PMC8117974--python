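"""Decision-threshold calibration and cross-validated evaluation.

The verifier needs a cut-off on the minimum normalized DTW distance.  It is
chosen from previously held, clinician-labelled attempts by sweeping every
candidate threshold and maximizing a metric — by default Pearson's r
between the binary decision and the truth label (the phi coefficient).
Two calibration modes exist:

* ``fixed``   — one threshold pooled over all patients;
* ``adapted`` — a separate threshold per patient.

Generalization is assessed with stratified 10-fold cross-validation: the
threshold is calibrated on nine folds and evaluated on the held-out fold,
and per-fold metrics are aggregated as mean, SD, min, max and range.

``ThresholdCalibration`` follows the model/results idiom: construct it from
labelled distances, call ``fit()``, and read estimates off the returned
``CalibrationResults`` (with ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .agreement import confusion_metrics

__all__ = [
    "LabeledDistances",
    "ThresholdCurve",
    "threshold_sweep",
    "ThresholdCalibration",
    "CalibrationResults",
    "calibrate",
    "cross_validate",
    "CrossValidationResults",
]

METRIC_COLUMNS = ("accuracy", "fp_rate", "fn_rate", "f1", "pearson_r")


@dataclass(frozen=True)
class LabeledDistances:
    """Clinician-labelled minimum DTW distances, one row per attempt.

    Columns: patient_id, item_id, min_distance, truth (1 = correct).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"patient_id", "item_id", "min_distance", "truth"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (df["min_distance"] < 0).any():
            raise ValueError("distances must be non-negative")
        if df.duplicated(["patient_id", "item_id"]).any():
            raise ValueError("duplicate (patient_id, item_id) keys")
        truth = _as_binary_truth(df["truth"])
        object.__setattr__(self, "frame", df.assign(truth=truth))

    @classmethod
    def from_records(cls, records) -> "LabeledDistances":
        return cls(pd.DataFrame(records,
                                columns=["patient_id", "item_id",
                                         "min_distance", "truth"]))

    @classmethod
    def from_csv(cls, path) -> "LabeledDistances":
        return cls(pd.read_csv(path))

    @property
    def distances(self) -> np.ndarray:
        return self.frame["min_distance"].to_numpy(dtype=float)

    @property
    def truth(self) -> np.ndarray:
        return self.frame["truth"].to_numpy(dtype=int)

    def patients(self) -> list:
        return sorted(self.frame["patient_id"].unique().tolist())

    def for_patient(self, patient_id) -> "LabeledDistances":
        return LabeledDistances(
            self.frame[self.frame["patient_id"] == patient_id].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)


def _as_binary_truth(col) -> np.ndarray:
    vals = pd.Series(col)
    if vals.dtype == object:
        mapping = {"correct": 1, "incorrect": 0}
        unknown = set(vals.unique()) - set(mapping)
        if unknown:
            raise ValueError(f"unrecognised truth labels: {sorted(unknown)}")
        return vals.map(mapping).to_numpy(dtype=int)
    out = vals.to_numpy()
    if not np.isin(out, (0, 1)).all():
        raise ValueError("numeric truth labels must be 0/1")
    return out.astype(int)


def _decision_metric(distances: np.ndarray, truth: np.ndarray,
                     threshold: float, metric: str) -> float:
    pred = (distances < threshold).astype(int)
    cm = confusion_metrics(pred, truth)
    if metric == "pearson_r":
        return cm.pearson_r if cm.pearson_r is not None else np.nan
    if metric == "accuracy":
        return cm.accuracy
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class ThresholdCurve:
    """Metric value across the candidate threshold grid."""

    thresholds: np.ndarray
    metric_values: np.ndarray
    metric: str

    def best(self) -> tuple:
        """(threshold, value) maximizing the metric; ties -> smaller threshold."""
        vals = self.metric_values
        if np.all(np.isnan(vals)):
            raise ValueError("metric undefined on the entire grid")
        best = np.nanmax(vals)
        idx = int(np.flatnonzero(vals == best)[0])
        return float(self.thresholds[idx]), float(best)


def threshold_sweep(data: LabeledDistances, metric: str = "pearson_r") -> ThresholdCurve:
    """Evaluate the decision metric at every distinguishable threshold.

    The grid is the midpoints between sorted unique distances plus one point
    below the minimum and one above the maximum, so every achievable
    confusion table is visited exactly once.  Thresholds where the metric is
    undefined (constant predictions, for Pearson's r) carry NaN.
    """
    d, y = data.distances, data.truth
    if len(np.unique(y)) < 2:
        raise ValueError("both truth classes are required to sweep thresholds")
    uniq = np.unique(d)
    span = max(uniq[-1] - uniq[0], 1.0)
    grid = np.concatenate([
        [max(uniq[0] - 0.01 * span, uniq[0] / 2)],
        (uniq[:-1] + uniq[1:]) / 2,
        [uniq[-1] + 0.01 * span],
    ]) if len(uniq) > 1 else np.array([uniq[0] / 2, uniq[0] * 1.5])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.array([_decision_metric(d, y, t, metric) for t in grid])
    return ThresholdCurve(grid, values, metric)


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted threshold(s) and the metric they achieve."""

    mode: str
    thresholds: object  # float (fixed) | dict patient -> float (adapted)
    best_metric: object  # float | dict patient -> float
    metric: str
    nobs: int

    def threshold_for(self, patient_id=None) -> float:
        if self.mode == "fixed":
            return float(self.thresholds)
        if patient_id not in self.thresholds:
            raise KeyError(f"no calibrated threshold for patient {patient_id!r}")
        return float(self.thresholds[patient_id])

    def summary(self) -> str:
        lines = [
            "Threshold calibration results",
            "=" * 45,
            f"mode:    {self.mode}",
            f"metric:  {self.metric}",
            f"n obs:   {self.nobs}",
        ]
        if self.mode == "fixed":
            lines.append(f"threshold: {self.thresholds:.4f}   "
                         f"{self.metric}: {self.best_metric:.4f}")
        else:
            for pid in sorted(self.thresholds):
                lines.append(f"  {pid}: threshold {self.thresholds[pid]:.4f}   "
                             f"{self.metric}: {self.best_metric[pid]:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "metric": self.metric,
            "thresholds": self.thresholds if self.mode == "adapted"
            else float(self.thresholds),
            "best_metric": self.best_metric if self.mode == "adapted"
            else float(self.best_metric),
        }


class ThresholdCalibration:
    """Model object: calibrate the decision threshold from labelled data."""

    def __init__(self, data: LabeledDistances, mode: str = "fixed",
                 metric: str = "pearson_r"):
        if mode not in ("fixed", "adapted"):
            raise ValueError(f"mode must be 'fixed' or 'adapted', got {mode!r}")
        self.data = data
        self.mode = mode
        self.metric = metric

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "ThresholdCalibration":
        return cls(LabeledDistances(frame), **kwargs)

    def fit(self) -> CalibrationResults:
        if self.mode == "fixed":
            t, v = threshold_sweep(self.data, self.metric).best()
            return CalibrationResults("fixed", t, v, self.metric, len(self.data))
        thresholds, metrics, bad = {}, {}, []
        for pid in self.data.patients():
            sub = self.data.for_patient(pid)
            if len(np.unique(sub.truth)) < 2:
                bad.append(pid)
                continue
            thresholds[pid], metrics[pid] = threshold_sweep(sub, self.metric).best()
        if bad:
            raise ValueError(
                "adapted calibration needs both truth classes per patient; "
                f"single-class patients: {bad}"
            )
        return CalibrationResults("adapted", thresholds, metrics,
                                  self.metric, len(self.data))


def calibrate(data: LabeledDistances, mode: str = "fixed",
              metric: str = "pearson_r") -> CalibrationResults:
    """Functional form of ``ThresholdCalibration(data, mode).fit()``."""
    return ThresholdCalibration(data, mode, metric).fit()


@dataclass(frozen=True)
class CrossValidationResults:
    """Per-fold and aggregate metrics of threshold generalization."""

    folds: pd.DataFrame  # one row per evaluated fold
    skipped: tuple
    k: int
    seed: int
    metric: str

    @property
    def aggregate(self) -> pd.DataFrame:
        cols = self.folds[list(METRIC_COLUMNS)]
        agg = pd.DataFrame({
            "mean": cols.mean(),
            "sd": cols.std(ddof=1),
            "min": cols.min(),
            "max": cols.max(),
        })
        agg["range"] = agg["max"] - agg["min"]
        return agg

    def summary(self) -> str:
        lines = [
            f"Stratified {self.k}-fold cross-validation (seed {self.seed})",
            "=" * 55,
            self.aggregate.round(4).to_string(),
        ]
        if self.skipped:
            lines.append(f"skipped folds (single-class training data): {self.skipped}")
        return "\n".join(lines)


def cross_validate(data: LabeledDistances, k: int = 10, seed: int = 0,
                   metric: str = "pearson_r") -> CrossValidationResults:
    """Stratified k-fold evaluation of the calibrated threshold.

    Each fold's threshold is fit on the remaining k-1 folds by
    ``threshold_sweep`` and evaluated on the held-out fold.  Pearson's r is
    NaN on folds where it is undefined (constant predictions or truth).
    """
    d, y = data.distances, data.truth
    n = len(d)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both truth classes are required")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, skipped = [], []
    for fold, (train, test) in enumerate(splitter.split(d, y)):
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {fold}: single-class training data, skipped")
            skipped.append(fold)
            continue
        sub = LabeledDistances(data.frame.iloc[train].reset_index(drop=True))
        t, _ = threshold_sweep(sub, metric).best()
        pred = (d[test] < t).astype(int)
        cm = confusion_metrics(pred, y[test])
        rows.append({
            "fold": fold, "threshold": t, "n_test": len(test),
            "accuracy": cm.accuracy, "fp_rate": cm.fp_rate,
            "fn_rate": cm.fn_rate, "f1": cm.f1,
            "pearson_r": np.nan if cm.pearson_r is None else cm.pearson_r,
        })
    return CrossValidationResults(pd.DataFrame(rows), tuple(skipped), k, seed, metric)
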