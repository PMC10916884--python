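"""Rule-based foveal hypoplasia grading and ROC calibration of cutoffs.

The ordinal grading scale (1a, 1b, 2, 3, 4) encodes which foveal
specializations are present: grade 1 retains a foveal depression (1a deeper
than 1b), grade 2 lacks the depression but shows outer-segment elongation,
grade 3 additionally lacks OS elongation but retains ONL thickening, and
grade 4 shows none of the three.  Here presence/absence decisions come from
the quantitative specialization ratios compared against calibrated cutoffs,
turning the subjective scale into a deterministic decision tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: ordinal scale, least to most severe; index 1..5 for weighted agreement
GRADES = ("1a", "1b", "2", "3", "4")
GRADE_TO_INDEX = {g: i + 1 for i, g in enumerate(GRADES)}
INDEX_TO_GRADE = {i + 1: g for i, g in enumerate(GRADES)}


@dataclass(frozen=True)
class GradeLabel:
    grade: str

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")

    @property
    def index(self) -> int:
        return GRADE_TO_INDEX[self.grade]

    @classmethod
    def from_index(cls, index: int) -> "GradeLabel":
        return cls(INDEX_TO_GRADE[index])


@dataclass(frozen=True)
class GradeCutoffs:
    """Ratio thresholds for presence of each specialization.

    ``deep_pit_irl`` separates 1a from 1b once a pit is present; the scale
    itself defines that split subjectively, so it is a free parameter
    defaulted to the midpoint between the pit cutoff and a fully
    specialized synthetic IRL ratio.
    """

    pit_irl: float = 1.40
    deep_pit_irl: float = 2.00
    os_elongation: float = 1.20
    onl_thickening: float = 1.10

    def __post_init__(self) -> None:
        if not self.pit_irl < self.deep_pit_irl:
            raise ValueError("deep-pit cutoff must exceed the pit cutoff")
        for name in ("pit_irl", "os_elongation", "onl_thickening"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CUTOFFS = GradeCutoffs()


@dataclass
class ROCResult:
    """Threshold sweep for one ratio against a binary presence label."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    direction: str
    positive_class: str = "specialization_present"


def roc_curve(values, binary_labels, direction: str = "greater") -> ROCResult:
    """ROC by exhaustive threshold sweep over midpoints of sorted values.

    ``direction='greater'`` means high values indicate the positive class
    (a test value is called positive when it exceeds the threshold).  AUC is
    the trapezoidal area under sensitivity vs. 1 − specificity.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if v.size != y.size or v.size == 0:
        raise ValueError("values and labels must be equal-length and nonempty")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")
    if direction == "less":
        v = -v
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        called = v > t
        sens[i] = np.sum(called & (y == 1)) / n_pos
        spec[i] = np.sum(~called & (y == 0)) / n_neg
    # lexicographic sort keeps tied-FPR points in ascending-TPR order
    order = np.lexsort((sens, 1.0 - spec))
    fpr = (1.0 - spec)[order]
    tpr = sens[order]
    auc = float(np.trapezoid(tpr, fpr))
    if direction == "less":
        thresholds = -thresholds
    result = ROCResult(thresholds, sens, spec, auc, np.nan, direction)
    result.optimal_cutoff = optimal_cutoff(result)
    return result


def optimal_cutoff(roc: ROCResult) -> float:
    """Threshold maximizing sensitivity + specificity.

    Ties prefer higher specificity, then the smaller threshold.
    """
    youden = roc.sensitivity + roc.specificity
    best = youden.max()
    tied = np.flatnonzero(youden >= best - 1e-12)
    tied = tied[roc.specificity[tied] >= roc.specificity[tied].max() - 1e-12]
    return float(roc.thresholds[tied].min())


def assign_grade_from_ratios(
    irl_ratio: float,
    os_ratio: float,
    onl_ratio: float,
    cutoffs: GradeCutoffs = DEFAULT_CUTOFFS,
) -> GradeLabel:
    """Decision tree over the three presence calls.

    Pit present → grade 1 (1a when the pit is deep, else 1b); otherwise OS
    elongation present → 2; otherwise ONL thickening present → 3; all
    absent → 4.  Increasing any ratio can never yield a more severe grade.
    """
    if cutoffs is None:
        raise ValueError("cutoffs are required")
    if irl_ratio >= cutoffs.pit_irl:
        return GradeLabel("1a" if irl_ratio >= cutoffs.deep_pit_irl else "1b")
    if os_ratio >= cutoffs.os_elongation:
        return GradeLabel("2")
    if onl_ratio >= cutoffs.onl_thickening:
        return GradeLabel("3")
    return GradeLabel("4")


def assign_grade(metrics, cutoffs: GradeCutoffs = DEFAULT_CUTOFFS) -> GradeLabel:
    """Grade a :class:`~foveaspec.layers.FovealMetrics` object."""
    return assign_grade_from_ratios(
        metrics.irl_ratio, metrics.os_ratio, metrics.onl_ratio, cutoffs
    )


#: binary contrasts used to calibrate each cutoff against reference grades
ROC_CONTRASTS = {
    # metric column -> (grades in the positive "specialization present" class)
    "irl_ratio": ("1a", "1b"),            # pit present vs grades 2-4
    "os_ratio": ("1a", "1b", "2"),        # OS elongation present vs 3-4
    "onl_ratio": ("1a", "1b", "2", "3"),  # ONL thickening present vs 4
}


def calibrate_cutoffs(cohort, deep_pit_irl: float | None = None) -> tuple[GradeCutoffs, dict[str, ROCResult]]:
    """ROC-calibrate the three presence cutoffs against reference grades.

    ``cohort`` is a DataFrame with ``irl_ratio``, ``os_ratio``, ``onl_ratio``
    and ``grade`` columns; the grade column is treated as ground truth.
    """
    rocs: dict[str, ROCResult] = {}
    values: dict[str, float] = {}
    for col, positive in ROC_CONTRASTS.items():
        labels = cohort["grade"].isin(positive).to_numpy().astype(int)
        rocs[col] = roc_curve(cohort[col].to_numpy(), labels, direction="greater")
        values[col] = rocs[col].optimal_cutoff
    if deep_pit_irl is None:
        deep_pit_irl = max(values["irl_ratio"] + 0.3,
                           0.5 * (values["irl_ratio"] + float(cohort["irl_ratio"].max())))
    cutoffs = GradeCutoffs(
        pit_irl=values["irl_ratio"],
        deep_pit_irl=deep_pit_irl,
        os_elongation=values["os_ratio"],
        onl_thickening=values["onl_ratio"],
    )
    return cutoffs, rocs
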