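"""Two-group Cox proportional-hazards estimation and survival-derived label constructions.

Class label conventions follow the prognostic orientation used throughout the
package: class 1 is the poor-prognosis group and class 2 the good-prognosis
group, so a hazard ratio above 1 means class 1 has worse outcomes.

The Cox model here is deliberately minimal: a single binary covariate
(class 1 vs class 2), fit by Newton iteration on the scalar log hazard ratio
of the partial likelihood with Efron handling of tied event times.  The
solver is vectorized over many candidate label vectors sharing one survival
table, which is what sub-classifier filtering and large sampling-distribution
simulations require.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalTable",
    "LabelAssignment",
    "CoxResult",
    "MedianSplit",
    "cox_two_group_hr",
    "two_group_loghr_batch",
    "median_dichotomize",
    "enumerate_ambiguous_assignments",
    "inject_label_noise",
    "random_labels",
]

# status codes for Cox fits
COX_OK = "ok"
COX_UNDEFINED = "undefined"  # a class is empty (or carries no information)
COX_MONOTONE = "monotone"  # monotone partial likelihood, |log HR| unbounded

_MONOTONE_BOUND = 20.0  # |log HR| beyond this is treated as a monotone likelihood


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample time-to-event endpoint (overall survival, RFS, ...)."""

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.sample_ids, dtype=object)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if not (len(ids) == len(time) == len(event)):
            raise ValueError("sample_ids, time and event must have equal length")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate sample ids in survival table")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be finite and > 0")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalTable":
        return SurvivalTable(self.sample_ids[idx], self.time[idx], self.event[idx])


@dataclass(frozen=True)
class LabelAssignment:
    """Binary training class labels: 1 = poor prognosis, 2 = good prognosis."""

    sample_ids: np.ndarray
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        ids = np.asarray(self.sample_ids, dtype=object)
        lab = np.asarray(self.labels, dtype=int)
        if len(ids) != len(lab):
            raise ValueError("sample_ids and labels must have equal length")
        if not np.all(np.isin(lab, (1, 2))):
            raise ValueError("labels must be 1 (poor prognosis) or 2 (good prognosis)")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 1)), int(np.sum(self.labels == 2))

    def with_labels(self, labels, provenance: str | None = None) -> "LabelAssignment":
        return LabelAssignment(
            self.sample_ids, labels,
            self.provenance if provenance is None else provenance,
        )

    def swapped(self) -> "LabelAssignment":
        return self.with_labels(3 - self.labels, self.provenance + "|swapped")


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    status: str = COX_OK

    @property
    def defined(self) -> bool:
        return self.status == COX_OK


def _efron_structures(time: np.ndarray, event: np.ndarray):
    """Sort by time and group tied event times for the Efron partial likelihood.

    Returns (order, groups) where each group is (risk-set start index in the
    sorted order, indices of its event members).
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    n = len(t)
    i = 0
    groups = []
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev_members = [k for k in range(i, j) if e[k] == 1]
        if ev_members:
            groups.append((i, np.asarray(ev_members)))
        i = j
    return order, groups


def two_group_loghr_batch(
    time: np.ndarray,
    event: np.ndarray,
    class1: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log HR of class 1 vs class 2 for many label vectors at once.

    Parameters
    ----------
    time, event
        Shared survival data, length n.
    class1
        Boolean array of shape (n, m): column j indicates membership of
        class 1 (poor prognosis) under labeling j.

    Returns
    -------
    loghr : (m,) float — clipped at +/-_MONOTONE_BOUND for monotone likelihoods
    se : (m,) float — Wald standard error of the log HR (NaN where undefined)
    status : (m,) array of status codes
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(class1, dtype=bool)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    order, groups = _efron_structures(time, event)
    Xs = X[order].astype(float)

    status = np.full(m, COX_OK, dtype=object)
    n1 = Xs.sum(axis=0)
    undefined = (n1 == 0) | (n1 == n)

    if not groups:
        status[:] = COX_UNDEFINED
        return np.zeros(m), np.full(m, np.nan), status

    # suffix counts of class-1 members at risk
    suffix1 = np.flipud(np.cumsum(np.flipud(Xs), axis=0))

    # expanded rows: one per (group, l)
    a0_list, a1_list = [], []
    d1_total = np.zeros(m)
    for start, ev_members in groups:
        d = len(ev_members)
        d1 = Xs[ev_members].sum(axis=0)
        d0 = d - d1
        N1 = suffix1[start]
        N0 = (len(time) - start) - N1
        d1_total += d1
        for l in range(d):
            frac = l / d
            a0_list.append(N0 - frac * d0)
            a1_list.append(N1 - frac * d1)
    a0 = np.asarray(a0_list)  # (E, m)
    a1 = np.asarray(a1_list)

    beta = np.zeros(m)
    active = ~undefined
    for _ in range(60):
        if not active.any():
            break
        r = np.exp(beta[active])
        num = a1[:, active] * r
        C = a0[:, active] + num
        phi = num / C
        U = d1_total[active] - phi.sum(axis=0)
        info = (phi * (1.0 - phi)).sum(axis=0)
        info = np.maximum(info, 1e-300)
        step = np.clip(U / info, -5.0, 5.0)
        beta[active] += step
        conv = (np.abs(U) < 1e-10) | (np.abs(step) < 1e-12)
        idx = np.flatnonzero(active)
        active[idx[conv]] = False

    monotone = (np.abs(beta) >= _MONOTONE_BOUND) & ~undefined
    beta = np.clip(beta, -_MONOTONE_BOUND, _MONOTONE_BOUND)

    # standard error from observed information at the estimate
    r = np.exp(beta)
    num = a1 * r
    C = a0 + num
    phi = num / C
    info = (phi * (1.0 - phi)).sum(axis=0)
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)

    status[monotone] = COX_MONOTONE
    status[undefined] = COX_UNDEFINED
    beta[undefined] = np.nan
    se[undefined | monotone] = np.nan
    return beta, se, status


def cox_two_group_hr(surv: SurvivalTable, labels: LabelAssignment) -> CoxResult:
    """Hazard ratio (class 1 poor vs class 2 good) from a single-covariate Cox fit.

    A 95% Wald confidence interval accompanies the estimate.  An empty class
    yields an undefined result (``status='undefined'``, NaN hazard ratio); a
    monotone partial likelihood is flagged and reported as a 0 or +inf
    sentinel hazard ratio.
    """
    if not np.array_equal(surv.sample_ids, labels.sample_ids):
        raise ValueError("survival table and labels refer to different samples")
    if surv.event.sum() < 1:
        raise ValueError("at least one event is required for a Cox fit")
    x = (labels.labels == 1)
    loghr, se, status = two_group_loghr_batch(surv.time, surv.event, x[:, None])
    st = status[0]
    if st == COX_UNDEFINED:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, COX_UNDEFINED)
    if st == COX_MONOTONE:
        hr = math.inf if loghr[0] > 0 else 0.0
        return CoxResult(hr, np.nan, np.nan, np.nan, COX_MONOTONE)
    b, s = float(loghr[0]), float(se[0])
    return CoxResult(math.exp(b), math.exp(b - 1.959963984540054 * s),
                     math.exp(b + 1.959963984540054 * s), s, COX_OK)


@dataclass(frozen=True)
class MedianSplit:
    """Result of dichotomizing a time-to-event endpoint at the median.

    ``labels`` uses 0 for samples that cannot be assigned unambiguously
    (censored before reaching the median).
    """

    sample_ids: np.ndarray
    labels: np.ndarray
    median: float
    ambiguous_ids: np.ndarray

    def to_assignment(self, provenance: str = "median-IC") -> LabelAssignment:
        if len(self.ambiguous_ids):
            raise ValueError(
                "ambiguous samples present; enumerate_ambiguous_assignments "
                "or dichotomize with ignore_censoring=True"
            )
        return LabelAssignment(self.sample_ids, self.labels, provenance)


def median_dichotomize(surv: SurvivalTable, ignore_censoring: bool = False) -> MedianSplit:
    """Split at median time: below-median events -> class 1 (poor), at/after -> class 2.

    Samples censored before the median cannot reach the landmark and are
    reported as ambiguous, unless ``ignore_censoring`` is set, in which case
    the split uses the time value alone.
    """
    if len(surv) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    med = float(np.median(surv.time))
    labels = np.where(surv.time < med, 1, 2)
    if ignore_censoring:
        ambiguous = np.array([], dtype=object)
    else:
        amb_mask = (surv.time < med) & (surv.event == 0)
        labels = np.where(amb_mask, 0, labels)
        ambiguous = surv.sample_ids[amb_mask]
    return MedianSplit(surv.sample_ids, labels, med, ambiguous)


def enumerate_ambiguous_assignments(split: MedianSplit) -> list[LabelAssignment]:
    """All balanced completions of a median split with ambiguous samples.

    The m ambiguous samples are assigned floor(m/2) to class 1 and the rest to
    class 2 in every possible combination, yielding C(m, floor(m/2))
    assignments.  With no ambiguity the single complete assignment is returned.
    """
    amb_idx = np.flatnonzero(split.labels == 0)
    m = len(amb_idx)
    if m == 0:
        return [LabelAssignment(split.sample_ids, split.labels, "median-IC")]
    out = []
    for poor in itertools.combinations(range(m), m // 2):
        lab = split.labels.copy()
        lab[amb_idx] = 2
        lab[amb_idx[list(poor)]] = 1
        out.append(LabelAssignment(split.sample_ids, lab,
                                   f"median-IC-ambiguous-{len(out)}"))
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def inject_label_noise(labels: LabelAssignment, fraction: float, seed: int) -> LabelAssignment:
    """Swap labels between random pairs of samples, one from each class.

    ``fraction`` is the total fraction of labels changed: round(fraction*N/2)
    pairs are swapped, changing 2*round(fraction*N/2) labels while preserving
    both class sizes exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_pairs = _round_half_up(fraction * len(labels) / 2.0)
    c1 = np.flatnonzero(labels.labels == 1)
    c2 = np.flatnonzero(labels.labels == 2)
    if len(c1) < n_pairs or len(c2) < n_pairs:
        raise ValueError(
            f"cannot swap {n_pairs} pairs with class sizes {len(c1)}/{len(c2)}"
        )
    rng = np.random.default_rng(seed)
    lab = labels.labels.copy()
    lab[rng.choice(c1, size=n_pairs, replace=False)] = 2
    lab[rng.choice(c2, size=n_pairs, replace=False)] = 1
    return labels.with_labels(lab, f"{labels.provenance}|noise-{fraction:g}")


def random_labels(sample_ids, seed: int) -> LabelAssignment:
    """Assign class 1 or 2 with probability 1/2 each; re-drawn if one class is empty."""
    ids = np.asarray(sample_ids, dtype=object)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    while True:
        lab = rng.integers(1, 3, size=len(ids))
        if (lab == 1).any() and (lab == 2).any():
            return LabelAssignment(ids, lab, "random-IC")
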