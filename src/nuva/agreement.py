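"""Evaluation metrics and inter-rater agreement statistics.

Binary verifier decisions are judged against the clinician's labels with
accuracy, false-positive and false-negative proportions (of all items, so
the three sum to one), F1 on the "correct" class, and Pearson's r of the
two binary vectors (the phi coefficient).

Agreement between two binary raters is measured with Gwet's AC1, a
chance-corrected coefficient robust to the prevalence paradoxes of kappa:
with percent agreement pa and chance agreement pe = 2*pi*(1-pi), where pi
is the mean of the raters' category-1 proportions,

    AC1 = (pa - pe) / (1 - pe).

Its standard error uses Gwet's two-rater linearization estimator (no
finite-population correction); the 95% CI is the normal approximation.
The coefficient is interpreted on McHugh's benchmark scale with 95%
certainty: interval membership probabilities from N(AC1, se^2) are
cumulated from the strongest level downward and the first level whose
cumulative probability reaches 0.95 is reported.

Differences between several binary systems on the same items are tested
with Cochran's Q (chi-square, k-1 df); for k = 2 it reduces to McNemar's
statistic without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "BinaryRatings",
    "AgreementReport",
    "gwet_ac1",
    "BenchmarkScale",
    "MCHUGH_SCALE",
    "benchmark_level",
    "cochran_q",
    "CochranQResult",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary-decision quality relative to ground truth.

    fp_rate and fn_rate are proportions of *all* n items, so
    accuracy + fp_rate + fn_rate = 1.  pearson_r is None when either vector
    has zero variance (the correlation is undefined, not zero).
    """

    n: int
    accuracy: float
    fp_rate: float
    fn_rate: float
    f1: float
    pearson_r: float | None

    def to_dict(self) -> dict:
        return {
            "n": self.n, "accuracy": self.accuracy, "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate, "f1": self.f1, "pearson_r": self.pearson_r,
        }


def confusion_metrics(pred, truth) -> ConfusionMetrics:
    """Accuracy, FP/FN proportions, F1 and phi for binary predictions.

    "Correct" (label 1) is the positive class.
    """
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D vectors")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 items")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    accuracy = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    pearson_r = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else None
    return ConfusionMetrics(n, accuracy, fp / n, fn / n, f1, pearson_r)


@dataclass(frozen=True)
class BinaryRatings:
    """Two raters' binary labels over the same items (1 = correct)."""

    item_ids: tuple
    rater_a: np.ndarray
    rater_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.rater_a).astype(int)
        b = np.asarray(self.rater_b).astype(int)
        if len(a) != len(b) or len(a) != len(self.item_ids):
            raise ValueError("item_ids and both rating vectors must align")
        if len(a) < 2:
            raise ValueError("need at least 2 rated items")
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise ValueError("ratings must be binary 0/1")
        object.__setattr__(self, "rater_a", a)
        object.__setattr__(self, "rater_b", b)

    @classmethod
    def from_arrays(cls, rater_a, rater_b, item_ids=None) -> "BinaryRatings":
        rater_a = np.asarray(rater_a)
        if item_ids is None:
            item_ids = tuple(range(len(rater_a)))
        return cls(tuple(item_ids), rater_a, rater_b)

    def __len__(self) -> int:
        return len(self.rater_a)


@dataclass(frozen=True)
class AgreementReport:
    """AC1 estimate with uncertainty and (optionally) a benchmark level."""

    n: int
    pa: float
    ac1: float
    stderr: float
    ci95: tuple
    level_code: int | None = None
    level_name: str | None = None

    def summary(self) -> str:
        lines = [
            "Gwet's AC1 inter-rater agreement",
            "=" * 40,
            f"items:            {self.n}",
            f"percent agreement {self.pa:.4f}",
            f"AC1               {self.ac1:.4f}",
            f"std err           {self.stderr:.4f}",
            f"95% CI            ({self.ci95[0]:.4f}, {self.ci95[1]:.4f})",
        ]
        if self.level_code is not None:
            lines.append(f"benchmark level   {self.level_code} ({self.level_name})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "pa": self.pa, "ac1": self.ac1, "stderr": self.stderr,
            "ci95": list(self.ci95), "level_code": self.level_code,
            "level_name": self.level_name,
        }


def gwet_ac1(ratings: BinaryRatings) -> AgreementReport:
    """Gwet's AC1 for two raters and two categories, with standard error.

    pa is the fraction of items on which the raters agree; chance agreement
    is pe = 2*pi*(1-pi) with pi the average of the raters' category-1
    marginals.  The variance is Gwet's linearization over items.
    """
    a, b = ratings.rater_a, ratings.rater_b
    n = len(ratings)
    agree = (a == b).astype(float)
    pa = float(agree.mean())
    pi = float((a.mean() + b.mean()) / 2.0)
    pe = 2.0 * pi * (1.0 - pi)
    if 1.0 - pe <= 1e-12:
        raise ValueError("chance agreement pe = 1; AC1 undefined")
    ac1 = (pa - pe) / (1.0 - pe)

    # per-item linearization: pi_i = share of the two raters voting 1;
    # pe_i averages over both categories at the pooled marginals
    pi_i = (a + b) / 2.0
    pe_i = pi + pi_i - 2.0 * pi * pi_i
    ac1_i_star = (agree - pe) / (1.0 - pe)
    gamma_i = ac1_i_star - 2.0 * (1.0 - ac1) * (pe_i - pe) / (1.0 - pe)
    var = float(np.sum((gamma_i - gamma_i.mean()) ** 2) / (n * (n - 1)))
    stderr = float(np.sqrt(max(var, 0.0)))
    ci = (ac1 - 1.96 * stderr, ac1 + 1.96 * stderr)
    return AgreementReport(n, pa, ac1, stderr, ci)


@dataclass(frozen=True)
class BenchmarkScale:
    """Ordered agreement intervals (cut-points ascending with codes)."""

    cuts: tuple        # interior boundaries, ascending
    codes: tuple       # len(cuts) + 1 codes, weakest first
    names: tuple

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.cuts) + 1 or len(self.names) != len(self.codes):
            raise ValueError("codes/names must have one more entry than cuts")
        if list(self.cuts) != sorted(self.cuts):
            raise ValueError("cuts must be ascending")

    def level_of(self, value: float) -> int:
        idx = int(np.searchsorted(self.cuts, value, side="left"))
        return self.codes[idx]

    def name_of(self, code: int) -> str:
        return self.names[self.codes.index(code)]

    def interval_probabilities(self, mean: float, stderr: float) -> np.ndarray:
        """Membership probability of each interval under N(mean, stderr^2)."""
        if stderr < 0:
            raise ValueError("stderr must be non-negative")
        if stderr == 0:
            probs = np.zeros(len(self.codes))
            probs[self.codes.index(self.level_of(mean))] = 1.0
            return probs
        edges = np.concatenate([[-np.inf], self.cuts, [np.inf]])
        cdf = stats.norm.cdf(edges, loc=mean, scale=stderr)
        return np.diff(cdf)


# McHugh's interpretation scale for health-care applications.
MCHUGH_SCALE = BenchmarkScale(
    cuts=(0.20, 0.40, 0.60, 0.80, 0.90),
    codes=(1, 2, 3, 4, 5, 6),
    names=("None", "Minimal", "Weak", "Moderate", "Strong", "Almost Perfect"),
)


def benchmark_level(ac1: float, stderr: float,
                    scale: BenchmarkScale = MCHUGH_SCALE) -> tuple:
    """Benchmark an agreement coefficient with 95% certainty.

    Interval membership probabilities are cumulated from the strongest
    level downward; the first level at which the cumulative probability
    reaches 0.95 is returned as (code, name).
    """
    probs = scale.interval_probabilities(ac1, stderr)
    cumulative = 0.0
    for idx in range(len(scale.codes) - 1, -1, -1):
        cumulative += probs[idx]
        if cumulative >= 0.95:
            return scale.codes[idx], scale.names[idx]
    return scale.codes[0], scale.names[0]


def benchmarked_ac1(ratings: BinaryRatings,
                    scale: BenchmarkScale = MCHUGH_SCALE) -> AgreementReport:
    """AC1 report with the benchmark level filled in."""
    rep = gwet_ac1(ratings)
    code, name = benchmark_level(rep.ac1, rep.stderr, scale)
    return AgreementReport(rep.n, rep.pa, rep.ac1, rep.stderr, rep.ci95, code, name)


@dataclass(frozen=True)
class CochranQResult:
    statistic: float
    df: int
    pvalue: float


def cochran_q(outcomes) -> CochranQResult:
    """Cochran's Q test for differences among k binary systems.

    `outcomes` is an items x systems 0/1 matrix.  Items on which all
    systems agree carry no information; if every item is like that, Q = 0
    and p = 1.
    """
    x = np.asarray(outcomes).astype(int)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an items x systems matrix, both dims >= 2")
    k = x.shape[1]
    if np.all(x.min(axis=1) == x.max(axis=1)):
        return CochranQResult(0.0, k - 1, 1.0)
    res = _sm_cochrans_q(x, return_object=True)
    return CochranQResult(float(res.statistic), k - 1, float(res.pvalue))
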