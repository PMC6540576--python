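"""Evaluation statistics: concordance with the true phenotype, per-attribute
association with Bonferroni correction, cross-cohort t-statistic
normalization, bivariate histograms, and top-k feature overlap."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .survival import LabelAssignment
from .synthgen import Dataset

__all__ = [
    "ConcordanceResult",
    "AssociationResult",
    "welch_t",
    "concordance",
    "attribute_association",
    "normalize_validation_tstat",
    "bivariate_histogram",
    "top_k_feature_overlap",
]


class ConcordanceResult(NamedTuple):
    value: float
    orientation_invariant: float


def welch_t(a: np.ndarray, b: np.ndarray, equal_var: bool = False):
    """Column-wise two-sample t statistics and two-sided p values.

    Welch (unequal variance) by default; attributes with zero variance in
    both groups get t = 0, p = 1 rather than NaN.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, n1 + n2 - 2.0)
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, p


@dataclass(frozen=True)
class AssociationResult:
    attribute_ids: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    significant_bonferroni: np.ndarray
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.significant_bonferroni.sum())


def concordance(labels: LabelAssignment, truth: np.ndarray) -> ConcordanceResult:
    """Fraction of samples whose class label matches the true phenotype.

    The prognosis-anchored mapping is fixed: class 1 (poor) corresponds to
    phenotype B, class 2 (good) to phenotype A.  The orientation-invariant
    variant max(c, 1 - c) is reported alongside.
    """
    truth = np.asarray(truth, dtype=object)
    if len(truth) != len(labels):
        raise ValueError("labels and truth cover different numbers of samples")
    if not np.all(np.isin(truth, ("A", "B"))):
        raise ValueError("true phenotype must be 'A' or 'B'")
    c = float(np.mean((labels.labels == 1) == (truth == "B")))
    return ConcordanceResult(c, max(c, 1.0 - c))


def attribute_association(
    data: Dataset,
    labels: LabelAssignment,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> AssociationResult:
    """Per-attribute two-sample t test between the two classes with a
    Bonferroni-adjusted significance call at familywise level ``alpha``."""
    if not np.array_equal(data.sample_ids, labels.sample_ids):
        raise ValueError("dataset and labels refer to different samples")
    g1 = data.values[labels.labels == 1]
    g2 = data.values[labels.labels == 2]
    t, p = welch_t(g1, g2, equal_var=equal_var)
    threshold = alpha / data.n_attributes
    return AssociationResult(data.attribute_ids, t, p, p < threshold, alpha)


def normalize_validation_tstat(
    t, n1_val: int, n2_val: int, n1_dev: int, n2_dev: int
):
    """Rescale validation-set t statistics to the development-set group sizes.

    Multiplies by sqrt(1/n1_val + 1/n2_val) / sqrt(1/n1_dev + 1/n2_dev), so
    statistics from cohorts of different size are comparable on a common
    scale.
    """
    for c in (n1_val, n2_val, n1_dev, n2_dev):
        if c < 1:
            raise ValueError("group counts must be >= 1")
    factor = np.sqrt(1.0 / n1_val + 1.0 / n2_val) / np.sqrt(1.0 / n1_dev + 1.0 / n2_dev)
    out = np.asarray(t, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def bivariate_histogram(
    t_dev,
    t_val,
    n_bins: int = 200,
    value_range: tuple[float, float] = (-20.0, 20.0),
) -> np.ndarray:
    """Bivariate histogram of paired t statistics (one pair per attribute).

    Values outside the range are clipped into the edge bins, so the total
    count always equals the number of attributes.
    """
    t_dev = np.asarray(t_dev, dtype=float)
    t_val = np.asarray(t_val, dtype=float)
    if t_dev.shape != t_val.shape:
        raise ValueError("t statistic lists must have equal length")
    lo, hi = value_range
    x = np.clip(t_dev, lo, hi)
    y = np.clip(t_val, lo, hi)
    h, _, _ = np.histogram2d(x, y, bins=n_bins, range=[[lo, hi], [lo, hi]])
    return h.astype(int)


def top_k_feature_overlap(ranked_lists: Sequence[Sequence], k: int = 100) -> dict:
    """Union/intersection accounting of top-k feature sets across datasets."""
    if len(ranked_lists) < 2:
        raise ValueError("need at least 2 ranked lists")
    tops = []
    for lst in ranked_lists:
        if len(lst) < k:
            raise ValueError(f"a ranked list has fewer than k={k} entries")
        tops.append(set(list(lst)[:k]))
    union = set.union(*tops)
    common = set.intersection(*tops)
    return {
        "distinct": len(union),
        "common": len(common),
        "common_fraction": len(common) / len(union) if union else 0.0,
    }
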