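# phenorefine

Iterative refinement of training class labels and classifiers for the
discovery of survival-associated molecular phenotypes.

## The problem

High-dimensional molecular profiles (mRNA expression, proteomics) from
patient cohorts often hide binary phenotypes — a good-prognosis and a
poor-prognosis group — that no single annotation defines.  Supervised
learning needs training labels, but a time-to-event endpoint such as overall
survival (OS) or recurrence-free survival (RFS) gives only a noisy proxy:
dichotomizing at the median survival mislabels every patient whose outcome
was driven by factors outside the molecular phenotype, and censored patients
below the landmark cannot be labeled at all.

`phenorefine` implements a semi-supervised fix: start from imperfect labels,
fit a bagged classifier, replace the labels with the classifier's
**out-of-bag (OOB)** classifications of the development set, and repeat until
labels and classifier are self-consistent (the classifier reproduces the
labels it was trained on).  Because OOB estimates are unbiased for samples
used in development, the loop relaxes toward the structure of the molecular
feature space rather than toward the noise in the initial labels.  Endpoint
data can steer the loop through the initial labels and by pruning
sub-classifiers on the hazard ratio they achieve.

The package is aimed at methodologists studying this class of
label-refinement procedures: it ships the full synthetic model system in
which the true phenotype is known, so that recovery can be quantified
exactly, together with the two classifier paradigms and the evaluation
statistics used to study the approach on real cohorts.

## Core model and algorithm

**Synthetic two-phenotype survival data.**  Each of N_S samples carries 1000
attributes; 900 are iid N(0, 1) noise, and 100 informative attributes are
multivariate normal with a random correlation structure R (same R for both
phenotypes): phenotype A ~ N(0, 0.1·diag⁰·⁵ R diag⁰·⁵) and phenotype B ~
N(2, R).  Survival is exponential and uncensored.  A 10,000-instance
phenotype-B reference set defines the first principal component; with l and
u the 5th/95th percentiles of the reference projections, each phenotype-B
sample with projection p has its survival time divided by

    f(p) = 1 + α (p − l)/(u − l)   if p > l,   1 otherwise,   α ≥ 0,

so α controls the survival separation between phenotypes.

**DRC classifier.**  The dropout-regularized combination builds one
k-nearest-neighbor sub-classifier per attribute singleton (and optionally
pair), optionally prunes sub-classifiers whose training-split
classifications achieve an oriented Cox hazard ratio outside a window such
as [1.3, 100], and combines the survivors by averaging ridge-logistic fits
over random dropout draws of `n_live` sub-classifiers.  Masters are bagged
over stratified 2/3 train / 1/3 test splits; a sample's OOB probability
averages only the bags that did not train on it.

**Iterative refinement (IRA).**  One refinement iteration = fit ensemble on
current labels → classify the development set OOB → adopt the
classifications as the next labels.  The loop stops at a fixed point, a
periodic attractor (label cycle), or an iteration cap, and reports the
two-group Cox hazard ratio HR = h_poor/h_good per iteration.

## Worked example

```python
from phenorefine import (SyntheticConfig, random_correlation_matrix,
                         build_reference_projection, generate_dataset,
                         median_dichotomize, run_ira)
from phenorefine.studies import synthetic_study_spec

cfg = SyntheticConfig(alpha=1.0, seed=3)            # 60+60 samples, 1000 attrs
corr = random_correlation_matrix(cfg.n_informative, seed=3)
ref = build_reference_projection(corr, cfg)
data = generate_dataset(cfg, corr, ref)
surv = data.survival_table()

initial = median_dichotomize(surv).to_assignment()   # median-survival labels
trace = run_ira(data, surv, initial, synthetic_study_spec(seed=3))
for rec in trace.iterations:
    print(f"iteration {rec.iteration}: {rec.n_label_changes:3d} label changes, "
          f"concordance with truth {rec.concordance_with_truth:.3f}")
print(trace.status)
```

Output:

```
iteration 0:   0 label changes, concordance with truth 0.567
iteration 1:  52 label changes, concordance with truth 0.800
iteration 2:  25 label changes, concordance with truth 0.992
iteration 3:   1 label changes, concordance with truth 1.000
iteration 4:   0 label changes, concordance with truth 1.000
fixed_point
```

The initial median-dichotomized labels agree with the hidden phenotype for
only 56.7% of samples; one refinement iteration lifts this to 80%, two more
reach the exact phenotype, and the last confirms self-consistency (no label
changes: the classifier reproduces its own training labels).

The same pipeline is available from the shell:

```
phenorefine simulate --alpha 1.0 --seed 3 --out-dir sim/
phenorefine run-ira --data sim/expression.tsv --survival sim/survival.tsv \
    --truth sim/truth.tsv --ic median --n-bags 60 --subset-depth 1 \
    --n-features 100 --out trace.json
phenorefine sampling-dist --alpha 2.0 --n-reps 1000 --seed 1
```

## Layout

- `phenorefine.synthgen` — synthetic data model and sampling-distribution studies
- `phenorefine.survival` — two-group Cox partial-likelihood fits, label constructions
- `phenorefine.classifiers` — DRC and bagged-logistic ensembles with OOB bookkeeping
- `phenorefine.ira` — the refinement loop, convergence/cycle detection, initial conditions
- `phenorefine.evaluate` — concordance, attribute association, t-statistic normalization,
  bivariate histograms, top-k feature overlap
- `phenorefine.io` / `phenorefine.cli` — TSV/JSON interfaces and the command line
- `docs/methods.md` — modeling assumptions, parameter choices, numerical details
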