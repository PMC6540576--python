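"""Bagged classifier paradigms used inside the iterative refinement loop.

Two paradigms are provided:

* ``drc`` — the dropout-regularized combination: many k-nearest-neighbor
  sub-classifiers, each built on one or two attributes, optionally pruned by
  the hazard ratio their training-set classifications achieve, then combined
  by averaging logistic fits over random dropout draws of a few live
  sub-classifiers.
* ``bagged_logreg`` — strongly regularized bagged logistic regression on
  t-test-selected attributes, with the same dropout-averaging scheme applied
  to attribute values instead of sub-classifier outputs.

Both are bagged over stratified train/test splits of the development set so
that every development sample receives an out-of-bag (OOB) classification:
the average over only those bags whose training split excluded it.  OOB
classifications are the unbiased development-set estimates the refinement
loop feeds back as new training labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .evaluate import welch_t
from .survival import LabelAssignment, SurvivalTable, two_group_loghr_batch
from .synthgen import Dataset

__all__ = [
    "ClassifierSpec",
    "SubClassifier",
    "MasterClassifier",
    "EnsembleClassifier",
    "ClassificationResult",
    "ttest_feature_selection",
    "build_subclassifiers",
    "filter_subclassifiers",
    "fit_master_dropout",
    "fit_ensemble",
    "classify",
    "oob_classify",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one ensemble classifier.

    ``hr_filter_range`` activates sub-classifier pruning: only sub-classifiers
    whose training-split classifications achieve an oriented hazard ratio
    (class 1 poor vs class 2 good) inside the closed interval are combined.
    ``n_selected_features`` activates per-bag t-test feature selection.
    """

    paradigm: str = "drc"
    n_bags: int = 100
    train_fraction: float = 2.0 / 3.0
    knn_k: int = 5
    subset_depth: int = 2
    hr_filter_range: tuple[float, float] | None = None
    n_dropout_draws: int = 1000
    n_live: int = 10
    n_selected_features: int | None = None
    decision_threshold: float = 0.5
    ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.paradigm not in ("drc", "bagged_logreg"):
            raise ValueError("paradigm must be 'drc' or 'bagged_logreg'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.subset_depth not in (1, 2):
            raise ValueError("subset_depth must be 1 or 2")
        if self.hr_filter_range is not None:
            low, high = self.hr_filter_range
            if low < 1.0 or high < low:
                raise ValueError("hr_filter_range must satisfy 1 <= low <= high")
        if self.n_dropout_draws < 1:
            raise ValueError("n_dropout_draws must be >= 1")
        if self.n_live < 1:
            raise ValueError("n_live must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "paradigm", "n_bags", "train_fraction", "knn_k", "subset_depth",
            "hr_filter_range", "n_dropout_draws", "n_live",
            "n_selected_features", "decision_threshold", "ridge", "seed")}
        if d["hr_filter_range"] is not None:
            d["hr_filter_range"] = list(d["hr_filter_range"])
        return d


@dataclass(frozen=True)
class SubClassifier:
    """A kNN classifier on a small attribute subset (indices are local to the
    feature list its bag selected)."""

    feature_subset: tuple[int, ...]
    k: int

    def __post_init__(self):
        if len(self.feature_subset) == 0:
            raise ValueError("feature subset must be non-empty")


def ttest_feature_selection(data: Dataset, labels: LabelAssignment, k: int) -> np.ndarray:
    """The k attribute ids with largest |two-sample t statistic| between the
    classes; ties broken by ascending attribute index."""
    idx = _ttest_select_idx(data.values, labels.labels, k)
    return data.attribute_ids[idx]


def _ttest_select_idx(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    if k > values.shape[1]:
        raise ValueError("k exceeds the number of attributes")
    t, _ = welch_t(values[labels == 1], values[labels == 2])
    # stable sort on -|t| keeps ascending attribute index among ties
    order = np.argsort(-np.abs(t), kind="stable")
    return order[:k]


def build_subclassifiers(
    features: np.ndarray | list,
    depth: int,
    train_data=None,
    k: int = 5,
) -> list[SubClassifier]:
    """One kNN sub-classifier per feature subset of size 1..depth
    (all singletons, plus all unordered pairs at depth 2)."""
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    n = len(features)
    if n == 0:
        raise ValueError("features must be non-empty")
    subs = [SubClassifier((i,), k) for i in range(n)]
    if depth == 2:
        subs.extend(SubClassifier(pair, k) for pair in itertools.combinations(range(n), 2))
    return subs


def _knn_outputs(
    train_vals: np.ndarray,
    train_y: np.ndarray,
    query_vals: np.ndarray,
    subsets: list[tuple[int, ...]],
    k: int,
    leave_one_out: bool = False,
    chunk_elems: int = 16_000_000,
) -> np.ndarray:
    """Predicted class (1/2) of each kNN sub-classifier for each query sample.

    Distances are Euclidean on raw attribute values; distance ties are broken
    by ascending training-sample index (stable sort).  With ``leave_one_out``
    the query set is the training set and each sample is excluded from its own
    neighbor list, which keeps training-split outputs honest for sub-classifier
    filtering and for fitting the dropout combination.

    Returns an (n_query, n_subs) int8 array.
    """
    n_q, n_tr = query_vals.shape[0], train_vals.shape[0]
    kk = min(k, n_tr - 1 if leave_one_out else n_tr)
    if kk < 1:
        raise ValueError("training split too small for kNN")
    y1 = (train_y == 1)
    out = np.empty((n_q, len(subsets)), dtype=np.int8)
    chunk = max(1, chunk_elems // max(1, n_q * n_tr))
    for start in range(0, len(subsets), chunk):
        batch = subsets[start:start + chunk]
        D = np.zeros((len(batch), n_q, n_tr))
        for pos in range(max(len(s) for s in batch)):
            feats = np.array([s[pos] if pos < len(s) else -1 for s in batch])
            use = feats >= 0
            qf = query_vals[:, feats[use]].T  # (b, n_q)
            tf = train_vals[:, feats[use]].T
            D[use] += (qf[:, :, None] - tf[:, None, :]) ** 2
        if leave_one_out:
            ii = np.arange(n_tr)
            D[:, ii, ii] = np.inf
        nbr = np.argsort(D, axis=-1, kind="stable")[..., :kk]
        votes = y1[nbr].sum(axis=-1)
        out[:, start:start + chunk] = np.where(2 * votes > kk, 1, 2).transpose(1, 0)
    return out


def filter_subclassifiers(
    subs: list[SubClassifier],
    train_outputs: np.ndarray,
    surv_train: SurvivalTable,
    hr_range: tuple[float, float],
) -> tuple[list[SubClassifier], np.ndarray]:
    """Retain sub-classifiers whose training-split classifications achieve an
    oriented hazard ratio within [low, high].

    Orientation is fixed (class 1 = poor prognosis); a sub-classifier whose
    groups invert the hazard (HR < low) is discarded rather than folded into
    its reciprocal, as is any sub-classifier assigning all training samples to
    one class (undefined HR).

    Returns the accepted sub-classifiers and a boolean acceptance mask.
    """
    low, high = hr_range
    class1 = train_outputs == 1
    loghr, _, status = two_group_loghr_batch(surv_train.time, surv_train.event, class1)
    hr = np.where(status == "monotone",
                  np.where(loghr > 0, np.inf, 0.0),
                  np.exp(loghr))
    accept = (status != "undefined") & (hr >= low) & (hr <= high)
    return [s for s, a in zip(subs, accept) if a], accept


def _class_balance_weights(y01: np.ndarray) -> np.ndarray:
    """Per-sample weights making both classes contribute equally to a fit.

    Balancing anchors the weighted mean of fitted probabilities at 1/2
    regardless of the class proportions in the training labels.  Inside the
    refinement loop this is what keeps the label proportions from drifting:
    with an unweighted fit the intercept tracks the class-1 prevalence, so
    once the labels tip past 50% every low-signal sample follows the majority
    and the proportions ratchet until one class is empty.
    """
    n = len(y01)
    n1 = y01.sum()
    if n1 == 0 or n1 == n:
        return np.ones(n)
    return np.where(y01 > 0, n / (2.0 * n1), n / (2.0 * (n - n1)))


def _batched_ridge_logistic(
    X: np.ndarray,
    y01: np.ndarray,
    ridge: float,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 50,
) -> np.ndarray:
    """Newton/IRLS fit of ridge-penalized logistic regressions, batched over
    the leading axis of X (one fit per dropout draw).

    X: (d, n, p) including the intercept column; returns coefficients (d, p).
    The small ridge penalty guarantees convergence on separable draws.
    """
    d, n, p = X.shape
    sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    beta = np.zeros((d, p))
    eye = ridge * np.eye(p)
    for _ in range(max_iter):
        eta = np.einsum("dnp,dp->dn", X, beta)
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = np.einsum("dnp,dn->dp", X, sw * (y01 - prob)) - ridge * beta
        w = sw * np.maximum(prob * (1.0 - prob), 1e-10)
        hess = np.einsum("dnp,dn,dnq->dpq", X, w, X) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        beta += step
        if np.max(np.abs(grad)) < 1e-8:
            break
    return beta


def _dropout_draws(n_subs: int, n_live: int, n_draws: int, rng: np.random.Generator):
    live = min(n_live, n_subs)
    if live == n_subs:
        return np.arange(n_subs)[None, :]  # all draws identical; one suffices
    return np.argsort(rng.random((n_draws, n_subs)), axis=1)[:, :live]


@dataclass
class MasterClassifier:
    """One bag's classifier plus its train/test bookkeeping.

    For the ``drc`` paradigm the dropout-averaged logistic combination acts on
    binary sub-classifier outputs; for ``bagged_logreg`` it acts directly on
    standardized attribute values.
    """

    paradigm: str
    feature_ids: np.ndarray  # attribute ids this master needs, in local order
    draw_idx: np.ndarray  # (n_draws, n_live) columns used per dropout draw
    coefs: np.ndarray  # (n_draws, n_live + 1) with leading intercept
    train_index: np.ndarray  # positions of the training split in the dev set
    test_mask: np.ndarray  # boolean over dev samples
    # drc-specific state
    subsets: list[tuple[int, ...]] | None = None
    k: int = 5
    train_values: np.ndarray | None = None  # training split, local feature order
    train_labels: np.ndarray | None = None
    # bagged_logreg-specific state
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """Class-1 probability for rows of ``values`` (columns already mapped
        to ``feature_ids`` order): dropout-averaged logistic output."""
        if self.paradigm == "drc":
            design = (_knn_outputs(self.train_values, self.train_labels, values,
                                   self.subsets, self.k) == 1).astype(float)
        else:
            design = (values - self.center) / self.scale
        X = design[:, self.draw_idx]  # (n, d, L)
        eta = self.coefs[:, 0][None, :] + np.einsum("ndl,dl->nd", X, self.coefs[:, 1:])
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return prob.mean(axis=1)


@dataclass
class EnsembleClassifier:
    spec: ClassifierSpec
    bags: list[MasterClassifier]
    dev_sample_ids: np.ndarray
    selected_features: np.ndarray | None = None

    @property
    def n_bags(self) -> int:
        return len(self.bags)


@dataclass(frozen=True)
class ClassificationResult:
    sample_ids: np.ndarray
    probability: np.ndarray
    labels: LabelAssignment


def fit_master_dropout(
    subs: list[SubClassifier],
    train_outputs: np.ndarray,
    train_labels: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Dropout-regularized logistic combination of sub-classifier outputs.

    For each dropout draw, ``n_live`` sub-classifiers are retained uniformly
    at random and a ridge-penalized logistic model of their binary outputs is
    fit to the training labels; the master's probability is the average of
    the per-draw probabilities.  Returns (draw_idx, coefficients).
    """
    if len(subs) == 0:
        raise ValueError("no sub-classifiers to combine")
    draw_idx = _dropout_draws(len(subs), spec.n_live, spec.n_dropout_draws, rng)
    design01 = (train_outputs == 1).astype(float)
    n = design01.shape[0]
    X = np.concatenate(
        [np.ones((draw_idx.shape[0], n, 1)),
         design01[:, draw_idx].transpose(1, 0, 2)],
        axis=2,
    )
    y01 = (train_labels == 1).astype(float)
    coefs = _batched_ridge_logistic(X, y01, spec.ridge,
                                    sample_weight=_class_balance_weights(y01))
    return draw_idx, coefs


def _stratified_split(labels: np.ndarray, train_fraction: float, rng: np.random.Generator):
    train_idx = []
    for cls in (1, 2):
        members = np.flatnonzero(labels == cls)
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.append(rng.permutation(members)[:n_train])
    train = np.sort(np.concatenate(train_idx))
    mask = np.ones(len(labels), dtype=bool)
    mask[train] = False
    return train, np.flatnonzero(mask)


def fit_ensemble(
    data: Dataset,
    labels: LabelAssignment,
    surv: SurvivalTable | None,
    spec: ClassifierSpec,
) -> EnsembleClassifier:
    """Fit ``spec.n_bags`` master classifiers over stratified train/test splits.

    Per bag: optional t-test feature selection on the training split,
    sub-classifier construction and leave-one-out training outputs, hazard
    ratio filtering when configured, and the dropout combination.  Splits are
    re-drawn until every development sample lands in at least one test split,
    so OOB classification is defined everywhere.
    """
    if not np.array_equal(data.sample_ids, labels.sample_ids):
        raise ValueError("dataset and labels refer to different samples")
    n1, n2 = labels.class_counts()
    if n1 < 2 or n2 < 2:
        raise ValueError("both classes need at least 2 samples to fit an ensemble")
    if spec.hr_filter_range is not None and surv is None:
        raise ValueError("hr filtering requires a survival table")
    if surv is not None and not np.array_equal(surv.sample_ids, data.sample_ids):
        raise ValueError("survival table and dataset refer to different samples")

    rng = np.random.default_rng(spec.seed)
    n = data.n_samples

    bags: list[MasterClassifier] = []
    union_features: set = set()
    covered = np.zeros(n, dtype=bool)
    attempts = 0
    max_attempts = max(200, 20 * spec.n_bags)
    # keep drawing until n_bags accepted bags exist and every sample has been
    # out-of-bag at least once (a single bag cannot cover; flagged below)
    while attempts < max_attempts and (
        len(bags) < spec.n_bags or (spec.n_bags > 1 and not covered.all())
    ):
        attempts += 1
        train, test = _stratified_split(labels.labels, spec.train_fraction, rng)
        y_tr = labels.labels[train]
        if spec.n_selected_features is not None:
            sel = _ttest_select_idx(data.values[train], y_tr, spec.n_selected_features)
        else:
            sel = np.arange(data.n_attributes)
        feature_ids = data.attribute_ids[sel]
        union_features.update(feature_ids.tolist())
        train_vals = data.values[np.ix_(train, sel)]
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test] = True

        if spec.paradigm == "drc":
            subs = build_subclassifiers(feature_ids, spec.subset_depth, k=spec.knn_k)
            subsets = [s.feature_subset for s in subs]
            outputs = _knn_outputs(train_vals, y_tr, train_vals, subsets,
                                   spec.knn_k, leave_one_out=True)
            if spec.hr_filter_range is not None:
                subs, accept = filter_subclassifiers(
                    subs, outputs, surv.subset(train), spec.hr_filter_range)
                outputs = outputs[:, accept]
                if len(subs) == 0:
                    warnings.warn("bag dropped: no sub-classifier passed HR filtering")
                    continue
            draw_idx, coefs = fit_master_dropout(subs, outputs, y_tr, spec, rng)
            bags.append(MasterClassifier(
                paradigm="drc", feature_ids=feature_ids, draw_idx=draw_idx,
                coefs=coefs, train_index=train, test_mask=test_mask,
                subsets=[s.feature_subset for s in subs], k=spec.knn_k,
                train_values=train_vals, train_labels=y_tr,
            ))
            covered[test] = True
        else:  # bagged_logreg
            center = train_vals.mean(axis=0)
            scale = train_vals.std(axis=0, ddof=0)
            scale = np.where(scale < 1e-12, 1.0, scale)
            design = (train_vals - center) / scale
            draw_idx = _dropout_draws(design.shape[1], spec.n_live,
                                      spec.n_dropout_draws, rng)
            X = np.concatenate(
                [np.ones((draw_idx.shape[0], design.shape[0], 1)),
                 design[:, draw_idx].transpose(1, 0, 2)],
                axis=2,
            )
            y01 = (y_tr == 1).astype(float)
            coefs = _batched_ridge_logistic(X, y01, spec.ridge,
                                            sample_weight=_class_balance_weights(y01))
            bags.append(MasterClassifier(
                paradigm="bagged_logreg", feature_ids=feature_ids,
                draw_idx=draw_idx, coefs=coefs, train_index=train,
                test_mask=test_mask, center=center, scale=scale,
            ))
            covered[test] = True

    if not bags:
        raise RuntimeError("all bags degenerate: no ensemble could be fit")
    if not covered.all():
        warnings.warn(
            "could not cover every sample out-of-bag; "
            "OOB classification will be undefined for some samples"
        )
    selected = (np.array(sorted(union_features), dtype=object)
                if spec.n_selected_features is not None else None)
    return EnsembleClassifier(spec, bags, data.sample_ids.copy(), selected)


def _master_inputs(master: MasterClassifier, data: Dataset) -> np.ndarray:
    pos = {a: i for i, a in enumerate(data.attribute_ids)}
    cols = []
    for fid in master.feature_ids:
        if fid not in pos:
            raise KeyError(f"dataset is missing attribute {fid!r}")
        cols.append(pos[fid])
    return data.values[:, cols]


def classify(clf: EnsembleClassifier, data: Dataset) -> ClassificationResult:
    """Standard classification: per-sample probability averaged over all bags,
    label 1 if probability exceeds the decision threshold, else 2 (ties to 2)."""
    probs = np.stack([m.predict_proba(_master_inputs(m, data)) for m in clf.bags])
    prob = probs.mean(axis=0)
    lab = np.where(prob > clf.spec.decision_threshold, 1, 2)
    return ClassificationResult(
        data.sample_ids, prob,
        LabelAssignment(data.sample_ids, lab, "classified"),
    )


def oob_classify(clf: EnsembleClassifier, data: Dataset) -> ClassificationResult:
    """Out-of-bag classification of the development set: each sample's
    probability averages only the masters for whose bag it was a test sample."""
    if not np.array_equal(data.sample_ids, clf.dev_sample_ids):
        raise ValueError("out-of-bag classification is defined only for the development set")
    probs = np.stack([m.predict_proba(_master_inputs(m, data)) for m in clf.bags])
    mask = np.stack([m.test_mask for m in clf.bags])
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        missing = data.sample_ids[counts == 0]
        raise ValueError(f"samples never out-of-bag: {list(missing[:5])}")
    prob = (probs * mask).sum(axis=0) / counts
    lab = np.where(prob > clf.spec.decision_threshold, 1, 2)
    return ClassificationResult(
        data.sample_ids, prob,
        LabelAssignment(data.sample_ids, lab, "oob"),
    )
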