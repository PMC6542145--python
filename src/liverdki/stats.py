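"""Group comparisons and ROC-based evaluation of diffusion markers.

A marker (ADC, MD or MK at one timepoint) is scored against the binary
recurrence outcome.  Marker polarity is fixed from the known biology:
recurrent lesions show *higher* kurtosis (MK) and *lower* diffusivity
(ADC, MD), so MK is evaluated greater-is-positive and ADC/MD
smaller-is-positive.  The empirical ROC curve, its trapezoidal AUC
(equal to the concordant-pair fraction with half credit for ties), the
Youden-optimal cutoff, the Hanley-McNeil standard error / normal 95% CI,
and the DeLong paired-AUC comparison are all computed here; paired and
Welch t-tests delegate to scipy with explicit zero-variance handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

Polarity = Literal["greater", "smaller"]

#: which direction of each marker indicates recurrence
DEFAULT_POLARITY: dict[str, Polarity] = {"mk": "greater", "adc": "smaller", "md": "smaller"}


def infer_polarity(values: np.ndarray, labels: np.ndarray) -> Polarity:
    """Auto-detect polarity from the group means (optional behaviour)."""
    pos_mean = float(np.mean(values[labels]))
    neg_mean = float(np.mean(values[~labels]))
    return "greater" if pos_mean >= neg_mean else "smaller"


@dataclass(frozen=True)
class MarkerSeries:
    """Per-patient marker values with binary outcome labels.

    ``labels`` is boolean with True = recurrence (the positive class).
    """

    values: np.ndarray
    labels: np.ndarray
    polarity: Polarity = "greater"
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        if values.shape != labels.shape or values.ndim != 1:
            raise ValueError("values and labels must be matching 1-D arrays")
        if not np.all(np.isfinite(values)):
            raise ValueError("marker values must be finite")
        if self.polarity not in ("greater", "smaller"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    @property
    def scores(self) -> np.ndarray:
        """Values oriented so that larger score means more recurrence-like."""
        return self.values if self.polarity == "greater" else -self.values


@dataclass(frozen=True)
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    j: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC: ordered operating points plus summary statistics.

    Points run from the all-negative rule (sens 0, spec 1) to the
    all-positive rule (sens 1, spec 0); tied scores share one point.
    ``auc``/``se``/``ci``/``youden`` are filled by :func:`evaluate_marker`.
    """

    points: tuple[OperatingPoint, ...]
    n_pos: int = 0
    n_neg: int = 0
    polarity: Polarity = "greater"
    auc: float | None = None
    se: float | None = None
    ci: tuple[float, float] | None = None
    youden: YoudenResult | None = None

    def __post_init__(self) -> None:
        for p in self.points:
            if not (0 <= p.sensitivity <= 1 and 0 <= p.specificity <= 1):
                raise ValueError("sensitivity/specificity must lie in [0, 1]")
        if self.auc is not None and not 0 <= self.auc <= 1:
            raise ValueError("auc must lie in [0, 1]")

    @classmethod
    def from_operating_points(
        cls, points: Sequence[tuple[float, float, float]]
    ) -> "ROCResult":
        """Build a curve from (cutoff, sensitivity, specificity) triples,
        adding the trivial extremes if absent (e.g. published table rows)."""
        ops = [OperatingPoint(*p) for p in points]
        sens = [p.sensitivity for p in ops]
        spec = [p.specificity for p in ops]
        if not any(s == 0 and c == 1 for s, c in zip(sens, spec)):
            ops.insert(0, OperatingPoint(np.inf, 0.0, 1.0))
        if not any(s == 1 and c == 0 for s, c in zip(sens, spec)):
            ops.append(OperatingPoint(-np.inf, 1.0, 0.0))
        return cls(points=tuple(ops))


def roc_curve(series: MarkerSeries) -> ROCResult:
    """Empirical ROC over every distinct score cutoff.

    The decision rule is score >= cutoff (after polarity orientation);
    cutoffs are reported on the original marker scale.
    """
    if series.n_pos == 0 or series.n_neg == 0:
        raise ValueError("ROC needs both outcome classes present")
    scores = series.scores
    pos = scores[series.labels]
    neg = scores[~series.labels]
    thresholds = np.unique(scores)[::-1]
    points = [OperatingPoint(np.inf, 0.0, 1.0)]
    for t in thresholds:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        cutoff = float(t) if series.polarity == "greater" else float(-t)
        points.append(OperatingPoint(cutoff, sens, spec))
    last = points[-1]
    if not (last.sensitivity == 1.0 and last.specificity == 0.0):
        points.append(OperatingPoint(-np.inf, 1.0, 0.0))
    if series.polarity == "smaller":
        # orient the trivial extremes' cutoffs on the original scale
        points[0] = OperatingPoint(-np.inf, 0.0, 1.0)
        if points[-1].specificity == 0.0 and not np.isfinite(points[-1].cutoff):
            points[-1] = OperatingPoint(np.inf, 1.0, 0.0)
    return ROCResult(
        points=tuple(points), n_pos=series.n_pos, n_neg=series.n_neg,
        polarity=series.polarity,
    )


def auc(source: ROCResult | MarkerSeries) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Equals (concordant pairs + half ties) / (n_pos * n_neg).
    """
    roc = roc_curve(source) if isinstance(source, MarkerSeries) else source
    fpr = np.array([1.0 - p.specificity for p in roc.points])
    tpr = np.array([p.sensitivity for p in roc.points])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def youden_optimal(roc: ROCResult) -> YoudenResult:
    """Cutoff maximising J = sensitivity + specificity - 1.

    Ties in J are broken toward the higher-specificity operating point
    (conservative recurrence calling).
    """
    if not roc.points:
        raise ValueError("ROC has no operating points")
    best = max(roc.points, key=lambda p: (p.youden_j, p.specificity))
    return YoudenResult(
        cutoff=best.cutoff, j=best.youden_j,
        sensitivity=best.sensitivity, specificity=best.specificity,
    )


def hanley_mcneil_ci(
    auc_value: float, n_pos: int, n_neg: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Hanley-McNeil SE of an AUC and the normal (1-alpha) CI clipped to [0,1]."""
    if not 0 <= auc_value <= 1:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one observation")
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (
        n_pos * n_neg
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = float(sps.norm.ppf(1 - alpha / 2))
    return se, float(max(0.0, a - z * se)), float(min(1.0, a + z * se))


def evaluate_marker(series: MarkerSeries, alpha: float = 0.05) -> ROCResult:
    """Full single-marker evaluation: ROC, AUC, Hanley-McNeil CI, Youden."""
    roc = roc_curve(series)
    a = auc(roc)
    se, lo, hi = hanley_mcneil_ci(a, roc.n_pos, roc.n_neg, alpha=alpha)
    return ROCResult(
        points=roc.points, n_pos=roc.n_pos, n_neg=roc.n_neg, polarity=roc.polarity,
        auc=a, se=se, ci=(lo, hi), youden=youden_optimal(roc),
    )


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def _placement_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tx = sps.rankdata(pos, method="average")
    ty = sps.rankdata(neg, method="average")
    tz = sps.rankdata(np.concatenate([pos, neg]), method="average")
    auc_hat = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc_hat), v10, v01


def delong_auc_variance(series: MarkerSeries) -> tuple[float, float]:
    """(AUC, DeLong variance) of one marker series."""
    a, v10, v01 = _placement_components(series.scores, series.labels)
    m, n = series.n_pos, series.n_neg
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return a, float(var)


def delong_test(series_a: MarkerSeries, series_b: MarkerSeries) -> DeLongResult:
    """Two-sided DeLong test of AUC(a) - AUC(b) on the same patients.

    Both series must be defined on identical patients and labels; the
    covariance between the two placement-value vectors accounts for the
    pairing.
    """
    if series_a.values.shape != series_b.values.shape or not np.array_equal(
        series_a.labels, series_b.labels
    ):
        raise ValueError("paired AUC comparison needs identical patients and labels")
    labels = series_a.labels
    a1, v10_1, v01_1 = _placement_components(series_a.scores, labels)
    a2, v10_2, v01_2 = _placement_components(series_b.scores, labels)
    m = int(labels.sum())
    n = int((~labels).sum())
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = a1 - a2
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var_diff)
    p = 1.0 if z == 0 else float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(auc_a=a1, auc_b=a2, z=float(z), p=min(p, 1.0))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def paired_t_test(x_pre: Sequence[float], x_post: Sequence[float]) -> TTestResult:
    """Classical paired t-test on the differences post - pre (two-sided)."""
    pre = np.asarray(x_pre, dtype=float)
    post = np.asarray(x_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("paired test needs two equal-length series, n >= 2")
    if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
        raise ValueError("values must be finite")
    diff = post - pre
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return TTestResult(0.0, n - 1, 1.0)
        return TTestResult(float(np.sign(diff.mean()) * np.inf), n - 1, 0.0)
    res = sps.ttest_rel(post, pre)
    return TTestResult(float(res.statistic), float(n - 1), float(res.pvalue))


def two_sample_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch unequal-variance t-test (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0)
        return TTestResult(float(np.sign(a.mean() - b.mean()) * np.inf),
                           float(a.size + b.size - 2), 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
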