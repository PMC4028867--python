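"""Decision rules, confusion metrics and cross-validation harness."""

import numpy as np
import pytest

from brainhmm import classifier as clf
from brainhmm import discrete_hmm as dh
from brainhmm.classifier import (
    ConfusionCounts,
    SubjectFeatures,
    SubjectRecord,
    confusion_metrics,
)

WELL_SEPARATED_POS = dh.DiscreteHMM(
    A=[[0.9, 0.1], [0.1, 0.9]],
    B=[[0.7, 0.2, 0.05, 0.05], [0.05, 0.05, 0.2, 0.7]],
    pi=[0.5, 0.5],
)
# genuinely different dynamics AND emissions (not a state relabeling of the
# positive model, which would induce the same observation distribution)
WELL_SEPARATED_NEG = dh.DiscreteHMM(
    A=[[0.55, 0.45], [0.45, 0.55]],
    B=[[0.4, 0.4, 0.1, 0.1], [0.1, 0.1, 0.4, 0.4]],
    pi=[0.5, 0.5],
)


def _record(states, obs, sid="s", group="demented"):
    return SubjectRecord(
        subject_id=sid, group=group,
        state_sequence=np.asarray(states), observation_sequence=np.asarray(obs),
    )


def _feature_subject(sid, group, center, n_slices=12, sd=0.05, seed=0):
    """Subject whose per-slice vectors cluster around a group center."""
    rng = np.random.default_rng(seed)
    return SubjectFeatures(
        subject_id=sid, group=group,
        state_vectors=center[0] + sd * rng.normal(size=(n_slices, 3)),
        symbol_vectors=center[1] + sd * rng.normal(size=(n_slices, 5)),
    )


def _separable_dataset(n_per_group=5, sd=0.05):
    pos_center = (np.array([2.0, 2.0, 2.0]), np.array([5.0, 5.0, 5.0, 5.0, 5.0]))
    neg_center = (np.zeros(3), np.zeros(5))
    ds = []
    for i in range(n_per_group):
        ds.append(_feature_subject(f"d{i}", "demented", pos_center, sd=sd, seed=i))
        ds.append(_feature_subject(f"c{i}", "control", neg_center, sd=sd, seed=100 + i))
    return ds


class TestConfusionMetrics:
    def test_hand_computed_rates_to_three_decimals(self):
        # 75-per-group study design: 61/14 and 60/15 splits
        sens, spec, acc = confusion_metrics(ConfusionCounts(TP=61, FN=14, TN=60, FP=15))
        assert round(sens, 3) == 0.813
        assert round(spec, 3) == 0.800
        assert round(acc, 3) == 0.807

    def test_symmetric_and_perfect_cases(self):
        assert confusion_metrics(ConfusionCounts(1, 1, 1, 1)) == (0.5, 0.5, 0.5)
        assert confusion_metrics(ConfusionCounts(TP=5, TN=7, FP=0, FN=0)) == (1, 1, 1)

    def test_zero_denominators_reported_as_none(self):
        sens, spec, acc = confusion_metrics(ConfusionCounts(TP=0, FN=0, TN=3, FP=1))
        assert sens is None
        assert spec == 0.75


class TestLikelihoodRule:
    def test_sampled_records_classified_to_their_generator(self):
        hits = 0
        for seed in range(100):
            _, obs = dh.sample(WELL_SEPARATED_POS, 135, seed)
            label, _ = clf.classify_by_likelihood(
                _record(np.zeros_like(obs), obs),
                WELL_SEPARATED_POS, WELL_SEPARATED_NEG,
            )
            hits += label == "demented"
        assert hits >= 95

    def test_identical_models_tie_to_control(self):
        label, tie = clf.classify_by_likelihood(
            _record([0, 1], [0, 1]), WELL_SEPARATED_POS, WELL_SEPARATED_POS
        )
        assert label == "control" and tie


class TestKldRule:
    def test_zero_divergence_wins(self):
        # subject whose own supervised model reproduces one group model
        _, obs = dh.sample(WELL_SEPARATED_POS, 400, seed=1)
        states, _ = dh.sample(WELL_SEPARATED_POS, 400, seed=1)
        record = _record(states, obs)
        subject_model = dh.estimate_supervised(
            [record.state_sequence], [record.observation_sequence], N=2, M=4
        )
        label, tie = clf.classify_by_kld(
            record, subject_model, WELL_SEPARATED_NEG, T=500, seed=3
        )
        assert label == "demented" and not tie

    def test_agrees_with_likelihood_on_separated_models(self):
        agree = 0
        n = 20
        for seed in range(n):
            model = WELL_SEPARATED_POS if seed % 2 else WELL_SEPARATED_NEG
            states, obs = dh.sample(model, 135, seed)
            record = _record(states, obs)
            l1, _ = clf.classify_by_likelihood(
                record, WELL_SEPARATED_POS, WELL_SEPARATED_NEG
            )
            l2, _ = clf.classify_by_kld(
                record, WELL_SEPARATED_POS, WELL_SEPARATED_NEG, T=1000, seed=seed
            )
            agree += l1 == l2
        assert agree >= int(0.9 * n)

    def test_label_stable_across_kld_seeds_when_margin_large(self):
        states, obs = dh.sample(WELL_SEPARATED_POS, 135, seed=0)
        record = _record(states, obs)
        labels = {
            clf.classify_by_kld(
                record, WELL_SEPARATED_POS, WELL_SEPARATED_NEG, T=1000, seed=s
            )[0]
            for s in range(10)
        }
        assert labels == {"demented"}


class TestGroupTraining:
    def test_singleton_pool_equals_subject_estimate(self):
        rec = _record([0, 0, 1, 1], [1, 2, 3, 0])
        model = clf.train_group_model([rec], N=2, M=4, pseudocount=0.0)
        direct = dh.estimate_supervised(
            [rec.state_sequence], [rec.observation_sequence], N=2, M=4,
            pseudocount=0.0,
        )
        assert np.array_equal(model.A, direct.A)
        assert np.array_equal(model.B, direct.B)

    def test_pooling_is_order_invariant(self):
        recs = [
            _record([0, 1, 1], [0, 2, 3], sid=f"s{i}") for i in range(3)
        ] + [_record([1, 0, 0], [3, 1, 0], sid="s3")]
        a = clf.train_group_model(recs, N=2, M=4)
        b = clf.train_group_model(recs[::-1], N=2, M=4)
        assert np.array_equal(a.A, b.A) and np.array_equal(a.B, b.B)

    def test_trained_models_closer_to_own_generator(self):
        from brainhmm.synthetic_data import sample_hmm_dataset

        data = sample_hmm_dataset(
            WELL_SEPARATED_POS, WELL_SEPARATED_NEG, 30, 135, seed=5
        )
        models = {}
        for label, gen in (("a", WELL_SEPARATED_POS), ("b", WELL_SEPARATED_NEG)):
            recs = [
                _record(d.states, d.observations, group=label)
                for d in data if d.label == label
            ]
            models[label] = clf.train_group_model(recs, N=2, M=4)

        def linf(m1, m2):
            return max(np.abs(m1.A - m2.A).max(), np.abs(m1.B - m2.B).max())

        assert linf(models["a"], WELL_SEPARATED_POS) < linf(
            models["a"], WELL_SEPARATED_NEG
        )
        assert linf(models["b"], WELL_SEPARATED_NEG) < linf(
            models["b"], WELL_SEPARATED_POS
        )

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            clf.train_group_model([], N=2, M=4)


class TestLooCrossval:
    def test_separable_groups_classified_perfectly(self):
        report = clf.loo_crossval(_separable_dataset(), rule="likelihood")
        assert report.accuracy == 1.0
        assert report.counts.TP == 5 and report.counts.TN == 5

    def test_indistinguishable_groups_sit_at_chance(self):
        # both groups drawn from the same feature distribution: nothing to
        # learn, so LOO accuracy stays in a chance band.  (Bitwise-identical
        # subjects are avoided: there the held-out subject's own group has
        # one fewer training sequence, so pseudocount smoothing makes the
        # opposite group's model deterministically sharper.)
        center = (np.ones(3), np.ones(5))
        ds = []
        for i in range(20):
            for group, tag in (("demented", "d"), ("control", "c")):
                ds.append(
                    _feature_subject(f"{tag}{i}", group, center, sd=1.0, seed=31 + i * 2 + (tag == "c"))
                )
        report = clf.loo_crossval(ds, rule="likelihood")
        assert 0.3 <= report.accuracy <= 0.7

    def test_order_free(self):
        ds = _separable_dataset(n_per_group=3)
        a = clf.loo_crossval(ds, rule="likelihood")
        b = clf.loo_crossval(ds[::-1], rule="likelihood")
        assert a.accuracy == b.accuracy
        assert a.counts.TP == b.counts.TP

    def test_needs_two_subjects_per_group(self):
        with pytest.raises(ValueError):
            clf.loo_crossval(_separable_dataset(n_per_group=1))


class TestNfoldCrossval:
    def test_deterministic_given_seed(self):
        ds = _separable_dataset(n_per_group=6, sd=1.5)
        a = clf.nfold_crossval(ds, train_fraction=0.5, repeats=5, seed=3)
        b = clf.nfold_crossval(ds, train_fraction=0.5, repeats=5, seed=3)
        assert a.per_repeat == b.per_repeat

    def test_single_repeat_equals_manual_round(self):
        ds = _separable_dataset(n_per_group=5)
        seed = 9
        report = clf.nfold_crossval(
            ds, train_fraction=0.8, repeats=1, rule="likelihood", seed=seed
        )
        train, test = clf.stratified_split(ds, 0.8, np.random.default_rng(seed))
        pair = clf.fit_pipeline(train, "demented", "control", vq_seed=seed)
        hits = 0
        for subj in test:
            label, _ = clf.classify_by_likelihood(
                pair.encode(subj), pair.models["demented"], pair.models["control"],
                "demented", "control",
            )
            hits += label == subj.group
        assert report.accuracy == hits / len(test)

    def test_fraction_leaving_no_test_subject_raises(self):
        ds = _separable_dataset(n_per_group=3)
        with pytest.raises(ValueError):
            clf.nfold_crossval(ds, train_fraction=0.99, repeats=1)


class TestSeverityTabulation:
    def test_detection_rate_per_stratum(self):
        ds = _separable_dataset(n_per_group=4)
        severities = ["very_mild", "very_mild", "mild", "mild"]
        for subj, sev in zip([s for s in ds if s.group == "demented"], severities):
            subj.severity = sev
        preds = {s.subject_id: "demented" for s in ds if s.group == "demented"}
        preds[[s for s in ds if s.severity == "mild"][0].subject_id] = "control"
        rates = clf.detection_rate_by_severity(ds, preds, "demented")
        assert rates == {"mild": 0.5, "very_mild": 1.0}
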