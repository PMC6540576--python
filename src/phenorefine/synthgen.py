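"""Synthetic two-phenotype survival datasets.

The simulator creates sample-by-attribute matrices containing two molecular
phenotypes, A (good survival) and B (poor survival).  Most attributes are
iid standard-normal noise; a block of informative attributes is multivariate
normal with a randomly correlated structure, centered at ``mean_A`` with
variance ``var_A`` for phenotype A and at ``mean_B`` with variance ``var_B``
for phenotype B.  Survival times are exponential and uncensored; for
phenotype-B samples the time is divided by a scaling factor

    f(p) = 1 + alpha * (p - l) / (u - l)   for p > l,   f(p) = 1 otherwise,

where p is the projection of the sample's informative block onto the first
principal component of a large phenotype-B reference set and l, u are the 5th
and 95th percentiles of the reference projections.  alpha >= 0 controls the
survival separation between the phenotypes; alpha = 0 gives identical
survival distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .survival import SurvivalTable

__all__ = [
    "SyntheticConfig",
    "ReferenceProjection",
    "Dataset",
    "random_correlation_matrix",
    "build_reference_projection",
    "scaling_factor",
    "generate_dataset",
    "sampling_distribution",
    "SamplingSummary",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All simulator parameters.

    The defaults reproduce the canonical study conditions: 60 samples per
    phenotype, 1000 attributes of which the last 100 are informative,
    phenotype A centered at 0 with variance 0.1 and phenotype B at 2 with
    variance 1, a 10,000-instance reference set for the principal-component
    projection, and unit-rate exponential survival (hazard ratios and
    concordances are invariant to the rate).
    """

    n_samples_a: int = 60
    n_samples_b: int = 60
    n_attributes: int = 1000
    n_informative: int = 100
    mean_a: float = 0.0
    var_a: float = 0.1
    mean_b: float = 2.0
    var_b: float = 1.0
    alpha: float = 1.0
    reference_size: int = 10000
    survival_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_attributes:
            raise ValueError("n_informative must not exceed n_attributes")
        if self.n_samples_a + self.n_samples_b <= 0:
            raise ValueError("need at least one sample")
        if self.n_samples_a < 0 or self.n_samples_b < 0:
            raise ValueError("sample counts must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.var_a <= 0 or self.var_b <= 0:
            raise ValueError("variances must be positive")
        if self.survival_rate <= 0:
            raise ValueError("survival_rate must be positive")
        if self.reference_size < 2:
            raise ValueError("reference_size must be at least 2")

    @property
    def n_samples(self) -> int:
        return self.n_samples_a + self.n_samples_b


@dataclass(frozen=True)
class ReferenceProjection:
    """First principal component of the phenotype-B reference set with the
    5th/95th-percentile cutoffs of the reference projections."""

    pc1: np.ndarray
    center: np.ndarray
    lower_cutoff: float
    upper_cutoff: float

    def __post_init__(self):
        if not self.lower_cutoff < self.upper_cutoff:
            raise ValueError("lower_cutoff must be below upper_cutoff")

    def project(self, values: np.ndarray) -> np.ndarray:
        """Projection of informative-block value rows onto the reference PC1."""
        return (np.asarray(values, dtype=float) - self.center) @ self.pc1


@dataclass(frozen=True)
class Dataset:
    """Sample x attribute matrix with survival endpoint and optional truth."""

    sample_ids: np.ndarray
    attribute_ids: np.ndarray
    values: np.ndarray
    survival_time: np.ndarray | None = None
    event: np.ndarray | None = None
    true_phenotype: np.ndarray | None = None
    informative_attributes: np.ndarray | None = None

    def __post_init__(self):
        ids = np.asarray(self.sample_ids, dtype=object)
        attrs = np.asarray(self.attribute_ids, dtype=object)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(ids), len(attrs)):
            raise ValueError("values matrix shape does not match ids")
        if np.any(~np.isfinite(vals)):
            raise ValueError("values matrix contains missing/non-finite entries")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "attribute_ids", attrs)
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_ids)

    def survival_table(self) -> SurvivalTable:
        if self.survival_time is None or self.event is None:
            raise ValueError("dataset carries no survival data")
        return SurvivalTable(self.sample_ids, self.survival_time, self.event)


def random_correlation_matrix(n: int, seed: int) -> np.ndarray:
    """Random valid correlation matrix via the boundary-based construction of
    Numpacharoen and Atsawarungruangkit.

    The matrix is built as C = B B' with unit-norm lower-triangular rows of B.
    Each correlation c[i, j] is drawn uniformly within the exact feasible
    interval implied by the already-fixed entries, guaranteeing unit diagonal,
    off-diagonals in [-1, 1], and positive semidefiniteness by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    B = np.zeros((n, n))
    C = np.eye(n)
    B[0, 0] = 1.0
    for i in range(1, n):
        c = rng.uniform(-1.0, 1.0)
        C[i, 0] = C[0, i] = c
        B[i, 0] = c
        for j in range(1, i):
            m = B[i, :j] @ B[j, :j]
            rem_i = max(1.0 - B[i, :j] @ B[i, :j], 0.0)
            s = np.sqrt(rem_i) * B[j, j]
            c = rng.uniform(m - s, m + s)
            C[i, j] = C[j, i] = c
            B[i, j] = (c - m) / B[j, j] if B[j, j] > 1e-12 else 0.0
        B[i, i] = np.sqrt(max(1.0 - B[i, :i] @ B[i, :i], 0.0))
    return C


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """Matrix square-root-like factor L with L L' = corr (Cholesky, with an
    eigendecomposition fallback for PSD-singular inputs)."""
    corr = np.asarray(corr, dtype=float)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        if w.max() <= 1e-12:
            raise ValueError("degenerate correlation matrix: no variance direction")
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def build_reference_projection(corr: np.ndarray, config: SyntheticConfig) -> ReferenceProjection:
    """Reference PC1 and projection cutoffs from a large phenotype-B sample.

    Draws ``config.reference_size`` phenotype-B realizations of the
    informative block, mean-centers them, extracts the first principal
    component (sign fixed so the loading sum is non-negative), and sets the
    lower/upper cutoffs to the 5th/95th percentiles (linear interpolation) of
    the reference projections.
    """
    corr = np.asarray(corr, dtype=float)
    k = config.n_informative
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix must be {k} x {k}")
    L = _corr_factor(corr)
    rng = np.random.default_rng([config.seed, 1])
    z = rng.standard_normal((config.reference_size, k))
    X = config.mean_b + np.sqrt(config.var_b) * (z @ L.T)
    center = X.mean(axis=0)
    Xc = X - center
    cov = (Xc.T @ Xc) / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12:
        raise ValueError("degenerate reference covariance: zero variance only")
    pc1 = v[:, -1]
    if pc1.sum() < 0:
        pc1 = -pc1
    p = Xc @ pc1
    lo, hi = np.percentile(p, [5.0, 95.0])
    return ReferenceProjection(pc1, center, float(lo), float(hi))


def scaling_factor(p, lower_cutoff: float, upper_cutoff: float, alpha: float):
    """Survival scaling factor 1 + alpha*(p-l)/(u-l) for p > l, and 1 for p <= l."""
    if not upper_cutoff > lower_cutoff:
        raise ValueError("upper_cutoff must exceed lower_cutoff")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = np.asarray(p, dtype=float)
    f = np.where(
        p <= lower_cutoff,
        1.0,
        1.0 + alpha * (p - lower_cutoff) / (upper_cutoff - lower_cutoff),
    )
    return float(f) if f.ndim == 0 else f


def generate_dataset(
    config: SyntheticConfig,
    corr: np.ndarray,
    ref: ReferenceProjection,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """One dataset realization under the two-phenotype survival model.

    Non-informative attributes are iid standard normal for both phenotypes.
    The informative block (the last ``n_informative`` attributes) is drawn per
    phenotype with covariance D^{1/2} R D^{1/2}, the same correlation R for
    both.  Survival is exponential with rate ``survival_rate`` and no
    censoring; each phenotype-B time is divided by the scaling factor of the
    sample's informative-block projection onto the reference PC1.

    A generator may be passed to draw streams of realizations; by default the
    draw is seeded from ``config.seed`` and regenerating with the same config
    is bit-identical.
    """
    k = config.n_informative
    if np.asarray(corr).shape != (k, k):
        raise ValueError(f"correlation matrix must be {k} x {k}")
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    na, nb, ns = config.n_samples_a, config.n_samples_b, config.n_samples
    n_noise = config.n_attributes - k
    L = _corr_factor(corr)

    values = np.empty((ns, config.n_attributes))
    values[:, :n_noise] = rng.standard_normal((ns, n_noise))
    za = rng.standard_normal((na, k))
    zb = rng.standard_normal((nb, k))
    values[:na, n_noise:] = config.mean_a + np.sqrt(config.var_a) * (za @ L.T)
    values[na:, n_noise:] = config.mean_b + np.sqrt(config.var_b) * (zb @ L.T)

    time = rng.exponential(1.0 / config.survival_rate, size=ns)
    p = ref.project(values[na:, n_noise:])
    time[na:] /= scaling_factor(p, ref.lower_cutoff, ref.upper_cutoff, config.alpha)

    sample_ids = np.array([f"S{i+1:04d}" for i in range(ns)], dtype=object)
    attribute_ids = np.array([f"A{j+1:04d}" for j in range(config.n_attributes)], dtype=object)
    truth = np.array(["A"] * na + ["B"] * nb, dtype=object)
    return Dataset(
        sample_ids=sample_ids,
        attribute_ids=attribute_ids,
        values=values,
        survival_time=time,
        event=np.ones(ns, dtype=int),
        true_phenotype=truth,
        informative_attributes=attribute_ids[n_noise:],
    )


@dataclass(frozen=True)
class SamplingSummary:
    """Sampling distribution of per-realization evaluation metrics."""

    alpha: float
    n_reps: int
    concordance: np.ndarray
    hazard_ratio: np.ndarray

    @property
    def median_concordance(self) -> float:
        return float(np.median(self.concordance))

    @property
    def concordance_iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.concordance, [25.0, 75.0])
        return float(lo), float(hi)

    @property
    def median_hr(self) -> float:
        return float(np.median(self.hazard_ratio))

    @property
    def hr_iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.hazard_ratio, [25.0, 75.0])
        return float(lo), float(hi)

    def percentile_rank(self, concordance_value: float = 0.5) -> float:
        """Percentile rank of a concordance value within the sampling
        distribution: 100 x fraction of realizations strictly below it."""
        return float(100.0 * np.mean(self.concordance < concordance_value))

    def to_dict(self) -> dict:
        lo_c, hi_c = self.concordance_iqr
        lo_h, hi_h = self.hr_iqr
        return {
            "alpha": self.alpha,
            "n_reps": self.n_reps,
            "median_concordance": self.median_concordance,
            "concordance_iqr": [lo_c, hi_c],
            "median_hr": self.median_hr,
            "hr_iqr": [lo_h, hi_h],
            "percentile_rank_of_0.5": self.percentile_rank(0.5),
        }


def sampling_distribution(config: SyntheticConfig, n_reps: int, seed: int) -> SamplingSummary:
    """Sampling distribution over dataset realizations of (i) the two-group
    Cox HR between true phenotypes (B = poor vs A = good) and (ii) the
    concordance of median-dichotomized initial labels with the true phenotype.

    One random correlation matrix and one reference projection are drawn from
    ``seed`` and held fixed across all realizations.
    """
    from .survival import median_dichotomize, two_group_loghr_batch

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    corr = random_correlation_matrix(config.n_informative, seed)
    cfg = replace(config, seed=seed)
    ref = build_reference_projection(corr, cfg)
    rng = np.random.default_rng([seed, 3])
    concs = np.empty(n_reps)
    hrs = np.empty(n_reps)
    for rep in range(n_reps):
        ds = generate_dataset(cfg, corr, ref, rng=rng)
        surv = ds.survival_table()
        split = median_dichotomize(surv)  # synthetic data are uncensored
        truth_poor = ds.true_phenotype == "B"
        concs[rep] = np.mean((split.labels == 1) == truth_poor)
        loghr, _, status = two_group_loghr_batch(surv.time, surv.event, truth_poor[:, None])
        hrs[rep] = np.exp(loghr[0]) if status[0] == "ok" else np.nan
    return SamplingSummary(config.alpha, n_reps, concs, hrs)
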