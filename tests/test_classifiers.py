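import warnings
from dataclasses import replace

import numpy as np
import pytest

from phenorefine.classifiers import (
    ClassifierSpec,
    MasterClassifier,
    EnsembleClassifier,
    _knn_outputs,
    build_subclassifiers,
    classify,
    filter_subclassifiers,
    fit_ensemble,
    fit_master_dropout,
    oob_classify,
    ttest_feature_selection,
)
from phenorefine.evaluate import concordance
from phenorefine.survival import LabelAssignment

from conftest import make_labels, make_surv


def small_spec(**kw):
    base = dict(paradigm="drc", n_bags=10, knn_k=5, subset_depth=1,
                n_dropout_draws=50, n_live=4, seed=0)
    base.update(kw)
    return ClassifierSpec(**base)


class TestTtestFeatureSelection:
    def test_planted_attribute_ranked_first(self, separable_toy):
        ds, labels = separable_toy
        top = ttest_feature_selection(ds, labels, 1)
        assert top[0] in {"g0", "g1", "g2", "g3"}  # an informative column

    def test_k_equals_all_returns_by_descending_t(self, separable_toy):
        ds, labels = separable_toy
        out = ttest_feature_selection(ds, labels, ds.n_attributes)
        assert len(out) == ds.n_attributes
        from phenorefine.evaluate import welch_t

        t, _ = welch_t(ds.values[labels.labels == 1], ds.values[labels.labels == 2])
        order = {a: i for i, a in enumerate(ds.attribute_ids)}
        tvals = [abs(t[order[a]]) for a in out]
        assert tvals == sorted(tvals, reverse=True)

    def test_zero_variance_attribute_gets_t_zero(self, separable_toy):
        ds, labels = separable_toy
        values = ds.values.copy()
        values[:, 5] = 1.0  # constant in both classes
        ds2 = replace(ds, values=values)
        out = ttest_feature_selection(ds2, labels, ds2.n_attributes)
        assert out[-1] == "g5"

    def test_k_too_large_rejected(self, separable_toy):
        ds, labels = separable_toy
        with pytest.raises(ValueError):
            ttest_feature_selection(ds, labels, ds.n_attributes + 1)


class TestBuildSubclassifiers:
    @pytest.mark.parametrize(
        "n_features,depth,expected", [(100, 2, 5050), (3, 1, 3), (2, 2, 3), (1, 1, 1)]
    )
    def test_subset_counts(self, n_features, depth, expected):
        subs = build_subclassifiers(list(range(n_features)), depth)
        assert len(subs) == expected
        assert all(1 <= len(s.feature_subset) <= depth for s in subs)

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValueError):
            build_subclassifiers([], 1)


class TestKnnOutputs:
    def test_matches_direct_nearest_neighbor_vote(self):
        rng = np.random.default_rng(0)
        train = rng.standard_normal((15, 3))
        query = rng.standard_normal((6, 3))
        y = np.where(rng.random(15) < 0.5, 1, 2)
        subsets = [(0,), (1,), (0, 2)]
        out = _knn_outputs(train, y, query, subsets, k=3)
        for si, sub in enumerate(subsets):
            d = ((query[:, None, sub] - train[None, :, sub]) ** 2).sum(-1)
            for qi in range(6):
                nn = np.argsort(d[qi], kind="stable")[:3]
                votes = (y[nn] == 1).sum()
                assert out[qi, si] == (1 if votes >= 2 else 2)

    def test_leave_one_out_excludes_self(self):
        # two tight clusters; with self included every sample would echo its
        # own label, with LOO the lone mislabeled sample flips
        train = np.array([[0.0], [0.01], [0.02], [5.0], [5.01], [5.02]])
        y = np.array([1, 1, 2, 2, 2, 2])  # sample 2 mislabeled within cluster 1
        out = _knn_outputs(train, y, train, [(0,)], k=2, leave_one_out=True)
        assert out[2, 0] == 1  # neighbors are samples 0,1 -> class 1


class TestFilterSubclassifiers:
    def _setup(self):
        rng = np.random.default_rng(5)
        n = 40
        surv = make_surv(np.sort(rng.exponential(1, n)))
        subs = build_subclassifiers(list(range(8)), 1)
        outputs = np.where(rng.random((n, 8)) < 0.5, 1, 2).astype(np.int8)
        # sub 0: strong (but imperfect) poor-prognosis split: mostly the
        # shortest times in class 1, with a few swaps to keep the HR finite
        strong = np.where(np.arange(n) < n // 2, 1, 2)
        strong[[0, 1, n - 2, n - 1]] = [2, 2, 1, 1]
        outputs[:, 0] = strong
        # sub 1: inverted orientation
        outputs[:, 1] = 3 - strong
        # sub 2: single-class output
        outputs[:, 2] = 1
        return subs, outputs, surv

    def test_orientation_and_degenerate_handling(self):
        subs, outputs, surv = self._setup()
        kept, accept = filter_subclassifiers(subs, outputs, surv, (1.3, 100.0))
        assert accept[0]  # correctly oriented strong sub passes
        assert not accept[1]  # inverted sub discarded, not reciprocal-folded
        assert not accept[2]  # undefined HR discarded
        assert len(kept) == accept.sum()

    def test_monotone_in_lower_bound(self):
        subs, outputs, surv = self._setup()
        _, loose = filter_subclassifiers(subs, outputs, surv, (1.3, 100.0))
        _, strict = filter_subclassifiers(subs, outputs, surv, (2.0, 100.0))
        assert np.all(loose | ~strict)  # strict set is a subset

    def test_wide_range_keeps_all_defined_oriented(self):
        subs, outputs, surv = self._setup()
        _, accept = filter_subclassifiers(subs, outputs, surv, (1.0, np.inf))
        from phenorefine.survival import two_group_loghr_batch

        loghr, _, status = two_group_loghr_batch(surv.time, surv.event, outputs == 1)
        expected = (status != "undefined") & ((loghr >= 0) | (status == "monotone") & (loghr > 0))
        # accepted iff defined and HR >= 1 in the poor-prognosis orientation
        assert np.array_equal(accept, (status != "undefined") & (np.where(
            status == "monotone", np.where(loghr > 0, np.inf, 0.0), np.exp(loghr)) >= 1.0))


class TestMasterDropout:
    def test_single_subclassifier_master_echoes_it(self):
        rng = np.random.default_rng(1)
        outputs = np.where(rng.random((30, 1)) < 0.5, 1, 2).astype(np.int8)
        y = outputs[:, 0]
        spec = small_spec(n_live=1, n_dropout_draws=10)
        draw_idx, coefs = fit_master_dropout(
            [build_subclassifiers([0], 1)[0]], outputs, y, spec, rng)
        X = (outputs == 1).astype(float)
        eta = coefs[:, 0][None, :] + X[:, draw_idx][:, :, 0] * coefs[:, 1]
        prob = (1 / (1 + np.exp(-eta))).mean(1)
        assert np.all((prob > 0.5) == (y == 1))

    def test_probabilities_stable_across_dropout_seeds(self):
        rng = np.random.default_rng(2)
        n, S = 40, 30
        outputs = np.where(rng.random((n, S)) < 0.5, 1, 2).astype(np.int8)
        y = np.where(rng.random(n) < 0.5, 1, 2)
        subs = build_subclassifiers(list(range(S)), 1)
        spec = small_spec(n_live=8, n_dropout_draws=1000)
        probs = []
        for seed in (1, 2):
            draw_idx, coefs = fit_master_dropout(
                subs, outputs, y, spec, np.random.default_rng(seed))
            X = (outputs == 1).astype(float)[:, draw_idx]
            eta = coefs[:, 0][None, :] + np.einsum("ndl,dl->nd", X, coefs[:, 1:])
            probs.append((1 / (1 + np.exp(-eta))).mean(1))
        assert np.max(np.abs(probs[0] - probs[1])) < 0.02

    def test_empty_sub_list_rejected(self):
        with pytest.raises(ValueError):
            fit_master_dropout([], np.empty((5, 0)), np.ones(5, int),
                               small_spec(), np.random.default_rng(0))


class TestEnsemble:
    def test_deterministic_given_seed(self, separable_toy):
        ds, labels = separable_toy
        spec = small_spec()
        surv = ds.survival_table()
        p1 = classify(fit_ensemble(ds, labels, surv, spec), ds).probability
        p2 = classify(fit_ensemble(ds, labels, surv, spec), ds).probability
        assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("paradigm", ["drc", "bagged_logreg"])
    def test_separable_toy_perfect_oob(self, separable_toy, paradigm):
        ds, labels = separable_toy
        spec = small_spec(paradigm=paradigm, n_selected_features=4)
        clf = fit_ensemble(ds, labels, ds.survival_table(), spec)
        oob = oob_classify(clf, ds)
        assert np.array_equal(oob.labels.labels, labels.labels)

    def test_oob_never_uses_training_bags(self, separable_toy):
        ds, labels = separable_toy
        from phenorefine.classifiers import _master_inputs

        clf = fit_ensemble(ds, labels, ds.survival_table(), small_spec())
        probs = np.stack([m.predict_proba(_master_inputs(m, ds)) for m in clf.bags])
        for m in clf.bags:
            assert not m.test_mask[m.train_index].any()
            assert m.test_mask.sum() > 0
        # manual masked average reproduces oob_classify
        mask = np.stack([m.test_mask for m in clf.bags])
        expected = (probs * mask).sum(0) / mask.sum(0)
        oob = oob_classify(clf, ds)
        assert np.allclose(oob.probability, expected)

    def test_every_sample_out_of_bag_at_least_once(self, separable_toy):
        ds, labels = separable_toy
        clf = fit_ensemble(ds, labels, ds.survival_table(), small_spec(n_bags=3))
        cover = np.stack([m.test_mask for m in clf.bags]).sum(0)
        assert cover.min() >= 1

    def test_single_bag_flags_coverage_violation(self, separable_toy):
        ds, labels = separable_toy
        with pytest.warns(UserWarning, match="out-of-bag"):
            clf = fit_ensemble(ds, labels, ds.survival_table(), small_spec(n_bags=1))
        assert clf.n_bags == 1

    def test_bag_order_invariance(self, separable_toy):
        ds, labels = separable_toy
        clf = fit_ensemble(ds, labels, ds.survival_table(), small_spec())
        p1 = classify(clf, ds).probability
        rng = np.random.default_rng(0)
        shuffled = EnsembleClassifier(
            clf.spec, [clf.bags[i] for i in rng.permutation(clf.n_bags)],
            clf.dev_sample_ids, clf.selected_features)
        p2 = classify(shuffled, ds).probability
        assert np.allclose(p1, p2, atol=1e-12)

    def test_missing_attribute_named_in_error(self, separable_toy):
        ds, labels = separable_toy
        clf = fit_ensemble(ds, labels, ds.survival_table(), small_spec())
        ds2 = replace(ds, values=ds.values[:, :5], attribute_ids=ds.attribute_ids[:5])
        with pytest.raises(KeyError, match="g5|g6"):
            classify(clf, ds2)

    def test_oob_requires_development_set(self, separable_toy, small_synth):
        ds, labels = separable_toy
        clf = fit_ensemble(ds, labels, ds.survival_table(), small_spec())
        other, _, _, _ = small_synth
        with pytest.raises(ValueError, match="development"):
            oob_classify(clf, other)

    def test_strong_separation_oob_concordance(self, paper_scale_synth):
        """Feature-space phenotypes at alpha=2 with true labels: OOB
        classification recovers the truth nearly perfectly."""
        ds = paper_scale_synth
        labels = LabelAssignment(
            ds.sample_ids, np.where(ds.true_phenotype == "B", 1, 2), "truth")
        spec = ClassifierSpec(paradigm="drc", n_bags=15, knn_k=25, subset_depth=1,
                              n_selected_features=100, n_dropout_draws=100, seed=4)
        clf = fit_ensemble(ds, labels, ds.survival_table(), spec)
        oob = oob_classify(clf, ds)
        assert concordance(oob.labels, ds.true_phenotype).value >= 0.95

    def test_probability_tie_assigns_good_prognosis(self, separable_toy):
        ds, labels = separable_toy
        # a master with all-zero coefficients emits probability exactly 0.5
        master = MasterClassifier(
            paradigm="bagged_logreg",
            feature_ids=ds.attribute_ids[:2],
            draw_idx=np.zeros((1, 2), dtype=int),
            coefs=np.zeros((1, 3)),
            train_index=np.arange(10),
            test_mask=np.ones(ds.n_samples, dtype=bool),
            center=np.zeros(2), scale=np.ones(2),
        )
        clf = EnsembleClassifier(small_spec(), [master], ds.sample_ids)
        res = classify(clf, ds)
        assert np.all(res.probability == 0.5)
        assert np.all(res.labels.labels == 2)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(paradigm="svm"),
            dict(train_fraction=1.0),
            dict(subset_depth=3),
            dict(hr_filter_range=(0.5, 2.0)),
            dict(n_dropout_draws=0),
            dict(n_live=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierSpec(**kwargs)
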