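"""The iterative refinement engine.

One refinement iteration takes the current training class labels, fits a
bagged ensemble classifier on them, and replaces the labels with the
ensemble's out-of-bag classifications of the development set.  Iterating
drives the label/classifier pair toward self-consistency: a fixed point where
the classifier reproduces exactly the labels it was trained on.  The loop can
also settle into a periodic attractor (a short cycle of label vectors, e.g. a
pair of samples swapping back and forth), which is detected and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classifiers import ClassifierSpec, EnsembleClassifier, fit_ensemble, oob_classify
from .evaluate import concordance
from .survival import (
    LabelAssignment,
    SurvivalTable,
    cox_two_group_hr,
    enumerate_ambiguous_assignments,
    inject_label_noise,
    median_dichotomize,
    random_labels,
)
from .synthgen import Dataset

__all__ = [
    "IterationRecord",
    "RefinementTrace",
    "ConvergenceStatus",
    "run_ira",
    "detect_convergence",
    "make_initial_condition",
]

FIXED_POINT = "fixed_point"
CYCLE = "cycle"
MAX_ITERATIONS = "max_iterations"
NOT_CONVERGED = "not_converged"
DEGENERATE_COLLAPSE = "degenerate_collapse"


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    labels: LabelAssignment
    n_label_changes: int
    dev_hr: float
    concordance_with_truth: float | None = None


@dataclass(frozen=True)
class ConvergenceStatus:
    status: str
    cycle_length: int | None = None


@dataclass
class RefinementTrace:
    iterations: list[IterationRecord]
    status: str
    cycle_length: int | None = None
    final_classifier: EnsembleClassifier | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.iterations) - 1  # iteration 0 holds the initial labels

    @property
    def final_labels(self) -> LabelAssignment:
        return self.iterations[-1].labels

    def label_history(self) -> list[LabelAssignment]:
        return [rec.labels for rec in self.iterations]


def detect_convergence(label_history: list[LabelAssignment]) -> ConvergenceStatus:
    """Fixed point if the last labeling equals the second-to-last; otherwise a
    cycle of the smallest length ell > 1 such that the last labeling equals
    the one ell steps back; otherwise not converged."""
    if not label_history:
        raise ValueError("label history is empty")
    if len(label_history) < 2:
        return ConvergenceStatus(NOT_CONVERGED)
    last = label_history[-1].labels
    if np.array_equal(last, label_history[-2].labels):
        return ConvergenceStatus(FIXED_POINT)
    for ell in range(2, len(label_history)):
        if np.array_equal(last, label_history[-1 - ell].labels):
            return ConvergenceStatus(CYCLE, ell)
    return ConvergenceStatus(NOT_CONVERGED)


def _safe_hr(surv: SurvivalTable, labels: LabelAssignment) -> float:
    n1, n2 = labels.class_counts()
    if n1 == 0 or n2 == 0 or surv is None:
        return float("nan")
    return cox_two_group_hr(surv, labels).hr


def run_ira(
    data: Dataset,
    surv: SurvivalTable,
    initial: LabelAssignment,
    spec: ClassifierSpec,
    max_iterations: int = 10,
) -> RefinementTrace:
    """Iterate classifier fitting and out-of-bag relabeling to self-consistency.

    Each iteration t fits the ensemble with seed ``spec.seed + t`` so the
    labels -> labels map is deterministic given the master seed, then adopts
    the ensemble's OOB labels as the next training labels.  The loop stops at
    a fixed point, at a detected cycle, when one class empties out
    (degenerate collapse), or after ``max_iterations`` refinement iterations.
    At a fixed point the final classifier's OOB classification equals its own
    training labels.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    n1, n2 = initial.class_counts()
    if n1 == 0 or n2 == 0:
        raise ValueError("initial labels must populate both classes")

    truth = data.true_phenotype

    def conc(lab: LabelAssignment):
        return concordance(lab, truth).value if truth is not None else None

    records = [IterationRecord(0, initial, 0, _safe_hr(surv, initial), conc(initial))]
    history = [initial]
    status, cycle_len = MAX_ITERATIONS, None
    clf = None
    for t in range(1, max_iterations + 1):
        try:
            clf = fit_ensemble(data, history[-1], surv, replace(spec, seed=spec.seed + t))
        except RuntimeError:
            # every bag degenerate (e.g. nothing passed HR filtering): the
            # refinement map is undefined at these labels
            status = DEGENERATE_COLLAPSE
            break
        oob = oob_classify(clf, data)
        new = oob.labels.with_labels(oob.labels.labels, f"iteration-{t}")
        n_changes = int(np.sum(new.labels != history[-1].labels))
        records.append(IterationRecord(t, new, n_changes, _safe_hr(surv, new), conc(new)))
        history.append(new)
        c1, c2 = new.class_counts()
        if c1 == 0 or c2 == 0:
            status = DEGENERATE_COLLAPSE
            break
        conv = detect_convergence(history)
        if conv.status == FIXED_POINT:
            status = FIXED_POINT
            break
        if conv.status == CYCLE:
            status, cycle_len = CYCLE, conv.cycle_length
            break
    return RefinementTrace(records, status, cycle_len, clf)


def make_initial_condition(
    kind: str,
    surv: SurvivalTable,
    seed: int = 0,
    n_realizations: int = 10,
    noise_fraction: float = 0.1,
) -> list[LabelAssignment]:
    """Initial training-class label realizations for the refinement loop.

    kind='median_tte': median dichotomization with all balanced completions of
    censoring-ambiguous samples, plus (when ambiguity exists) one realization
    dichotomizing at the median time ignoring censoring.
    kind='random': ``n_realizations`` independent fair coin assignments.
    kind='noisy_median': pairwise label swaps injected into the
    ignore-censoring median realization, ``n_realizations`` times.
    """
    if kind == "median_tte":
        split = median_dichotomize(surv)
        out = enumerate_ambiguous_assignments(split)
        if len(split.ambiguous_ids):
            ignore = median_dichotomize(surv, ignore_censoring=True)
            out.append(ignore.to_assignment("median-IC-ignore-censoring"))
        return out
    if kind == "random":
        return [random_labels(surv.sample_ids, seed + i) for i in range(n_realizations)]
    if kind == "noisy_median":
        base = median_dichotomize(surv, ignore_censoring=True).to_assignment("median-IC")
        return [inject_label_noise(base, noise_fraction, seed + i)
                for i in range(n_realizations)]
    raise ValueError(f"unknown initial condition kind {kind!r}")
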