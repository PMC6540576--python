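import numpy as np
import pytest

from phenorefine.survival import LabelAssignment, SurvivalTable
from phenorefine.synthgen import (
    Dataset,
    SyntheticConfig,
    build_reference_projection,
    generate_dataset,
    random_correlation_matrix,
)


def efron_loglik(time, event, x, beta):
    """Independent direct computation of the Efron partial log-likelihood for a
    single binary covariate (test oracle; kept free of the package's solver).
    ``beta`` may be a scalar or an array of candidate log hazard ratios."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    beta = np.asarray(beta, float)
    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    n = len(t)
    ll = np.zeros(beta.shape)
    r = np.exp(beta)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = [k for k in range(i, j) if e[k] == 1]
        d = len(ev)
        if d:
            d1 = sum(xs[k] for k in ev)
            N1 = xs[i:].sum()
            N0 = (n - i) - N1
            ll = ll + beta * d1
            for l in range(d):
                ll = ll - np.log((N0 - l / d * (d - d1)) + (N1 - l / d * d1) * r)
        i = j
    return ll


def grid_loghr(time, event, x, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximizer of the Efron partial likelihood over a log-HR grid."""
    grid = np.arange(lo, hi + step, step)
    lls = efron_loglik(time, event, x, grid)
    return grid[int(np.argmax(lls))]


@pytest.fixture(scope="session")
def small_synth():
    """One small two-phenotype realization: 30+30 samples, 200 attributes
    (40 informative), alpha = 2."""
    cfg = SyntheticConfig(
        n_samples_a=30, n_samples_b=30, n_attributes=200, n_informative=40,
        alpha=2.0, reference_size=4000, seed=7,
    )
    corr = random_correlation_matrix(cfg.n_informative, 7)
    ref = build_reference_projection(corr, cfg)
    return generate_dataset(cfg, corr, ref), cfg, corr, ref


@pytest.fixture(scope="session")
def paper_scale_synth():
    """One paper-scale realization: 60+60 samples, 1000 attributes, alpha = 2."""
    cfg = SyntheticConfig(alpha=2.0, seed=5)
    corr = random_correlation_matrix(cfg.n_informative, 5)
    ref = build_reference_projection(corr, cfg)
    return generate_dataset(cfg, corr, ref)


@pytest.fixture()
def separable_toy():
    """Two well-separated Gaussian blobs with matching survival difference:
    linearly separable in every informative attribute pair."""
    rng = np.random.default_rng(11)
    n = 40
    v1 = np.concatenate([rng.normal(0, 0.3, (n // 2, 4)), rng.normal(4, 0.3, (n // 2, 4))])
    noise = rng.standard_normal((n, 3))
    values = np.hstack([v1, noise])
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    attrs = np.array([f"g{j}" for j in range(7)], dtype=object)
    truth = np.array(["B"] * (n // 2) + ["A"] * (n // 2), dtype=object)
    time = np.where(truth == "B", rng.exponential(0.3, n), rng.exponential(1.5, n))
    ds = Dataset(ids, attrs, values, survival_time=time,
                 event=np.ones(n, int), true_phenotype=truth)
    labels = LabelAssignment(ids, np.where(truth == "B", 1, 2), "truth")
    return ds, labels


def make_surv(times, events=None, ids=None):
    times = np.asarray(times, float)
    if events is None:
        events = np.ones(len(times), int)
    if ids is None:
        ids = np.array([f"s{i}" for i in range(len(times))], dtype=object)
    return SurvivalTable(ids, times, np.asarray(events, int))


def make_labels(surv, labels):
    return LabelAssignment(surv.sample_ids, np.asarray(labels, int))
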