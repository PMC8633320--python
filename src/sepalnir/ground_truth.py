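"""Fusing a multi-grader severity panel into one score per sepal.

Each sepal is graded 0-5 by a panel of graders.  The grades are fused by
principal component analysis: the grader-column-centered matrix is projected
onto its first principal component, the sign is fixed so the projection
correlates positively with the per-sepal mean grade, and the scores are
affinely rescaled so their least-squares relationship to the mean grades is
the identity — putting the fused severity back on the 0-5 grade scale.  The
fraction of panel variance explained by PC1 measures grader agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GradePanel", "FusedSeverity", "fuse_grades_pca", "batch_summary"]


@dataclass
class GradePanel:
    """Complete sepal x grader grade matrix, every cell in [0, 5]."""

    grades: np.ndarray
    sepal_ids: np.ndarray

    def __post_init__(self) -> None:
        self.grades = np.asarray(self.grades, dtype=float)
        self.sepal_ids = np.asarray(self.sepal_ids)
        if self.grades.ndim != 2:
            raise ValueError("grades must be a sepal x grader matrix")
        if self.sepal_ids.size != self.grades.shape[0]:
            raise ValueError("one sepal id per row required")
        if np.isnan(self.grades).any():
            raise ValueError("panel has missing cells; complete grading required")
        if self.grades.min() < 0 or self.grades.max() > 5:
            raise ValueError("grades must lie in [0, 5]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GradePanel":
        """Build from a DataFrame indexed by sepal_id with one column per grader."""
        return cls(grades=frame.to_numpy(dtype=float), sepal_ids=frame.index.to_numpy())

    @property
    def n_graders(self) -> int:
        return self.grades.shape[1]


@dataclass
class FusedSeverity:
    """Per-sepal fused severity on the grade scale plus the PC1 variance ratio."""

    sepal_ids: np.ndarray
    severity: np.ndarray
    explained_variance_ratio: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sepal_id": self.sepal_ids, "severity": self.severity})


def fuse_grades_pca(panel: GradePanel) -> FusedSeverity:
    """Project the panel onto PC1 and rescale to the grade scale.

    Steps: center each grader column; eigendecompose the grader covariance;
    project sepals onto the leading eigenvector; orient the sign so the scores
    correlate positively with the per-sepal mean grade; regress mean grades on
    the scores and report the fitted values as severities.  A zero-variance
    panel (all graders, all sepals identical) degenerates gracefully: the
    common grade is returned with ratio 1.
    """
    if panel.n_graders < 2:
        raise ValueError("PCA fusion needs at least 2 graders")
    if panel.grades.shape[0] < 3:
        raise ValueError("PCA fusion needs at least 3 sepals")
    grades = panel.grades
    centered = grades - grades.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / centered.shape[0]
    total_var = np.trace(cov)
    if total_var == 0:
        return FusedSeverity(
            sepal_ids=panel.sepal_ids,
            severity=np.full(grades.shape[0], grades[0, 0]),
            explained_variance_ratio=1.0,
        )
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, -1]
    ratio = float(eigvals[-1] / total_var)
    scores = centered @ pc1

    mean_grade = grades.mean(axis=1)
    sign = np.sign(np.dot(scores - scores.mean(), mean_grade - mean_grade.mean()))
    if sign < 0:
        scores = -scores

    # Affine rescale: least-squares fit of mean grades on the scores, so the
    # fused severity lives on the 0-5 grade scale.
    var_scores = scores.var()
    if var_scores == 0:  # graders disagree only along degenerate directions
        severity = np.full_like(scores, mean_grade.mean())
    else:
        beta = np.cov(scores, mean_grade, bias=True)[0, 1] / var_scores
        alpha = mean_grade.mean() - beta * scores.mean()
        severity = alpha + beta * scores
    return FusedSeverity(
        sepal_ids=panel.sepal_ids, severity=severity, explained_variance_ratio=ratio
    )


def batch_summary(
    severity: np.ndarray,
    batches: np.ndarray,
    low_cutoff: float = 1.0,
    high_cutoff: float = 4.0,
) -> pd.DataFrame:
    """Per-batch severity statistics: mean, sd, CV, and % low / moderate / high.

    "Low" sepals have severity below ``low_cutoff``; "high" above
    ``high_cutoff``; the remainder are moderate, so the three percentages sum
    to 100.  CV = sd / mean; reported as NaN for a zero-mean batch (undefined)
    rather than raising.
    """
    severity = np.asarray(severity, dtype=float)
    batches = np.asarray(batches)
    if severity.size != batches.size:
        raise ValueError("one batch label per sepal required")
    rows = []
    for batch in np.unique(batches):
        vals = severity[batches == batch]
        mean = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        cv = np.nan if mean == 0 else sd / mean
        low = 100.0 * np.mean(vals < low_cutoff)
        high = 100.0 * np.mean(vals > high_cutoff)
        rows.append(
            {
                "batch": batch,
                "n": vals.size,
                "mean": mean,
                "sd": sd,
                "cv": cv,
                "pct_low": low,
                "pct_moderate": 100.0 - low - high,
                "pct_high": high,
            }
        )
    return pd.DataFrame(rows)
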