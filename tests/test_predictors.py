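"""Baseline predictor, evaluation statistics, and the SVM pipeline."""

import dataclasses
from math import comb

import numpy as np
import pytest

from prefdyn import predictors as prd
from prefdyn import synth
from prefdyn.types import LandmarkDataError, VideoPair

from conftest import random_video


def make_pair(rng, domain="cartoons", preferred=1, n_frames=9):
    v1 = random_video(rng, n_frames=n_frames, domain=domain, slot=1)
    v2 = random_video(rng, n_frames=n_frames, domain=domain, slot=2)
    return VideoPair(video1=v1, video2=v2, preferred=preferred)


class TestDifferenceScore:
    def test_identical_videos_zero(self, rng):
        v = random_video(rng, domain="cartoons", slot=1)
        v2 = dataclasses.replace(v, slot=2)
        pair = VideoPair(video1=v, video2=v2, preferred=1)
        assert prd.difference_score(pair, "dstd") == 0.0

    def test_swap_negates(self, rng):
        pair = make_pair(rng)
        swapped = VideoPair(
            video1=dataclasses.replace(pair.video2, slot=1),
            video2=dataclasses.replace(pair.video1, slot=2),
            preferred=2,
        )
        np.testing.assert_allclose(
            prd.difference_score(swapped, "dmaxmin"),
            -prd.difference_score(pair, "dmaxmin"),
            rtol=1e-9,
        )

    def test_equals_independent_statistics(self, rng):
        from prefdyn.descriptors import video_statistic
        from prefdyn.preprocess import preprocess_video

        pair = make_pair(rng)
        expected = video_statistic(
            preprocess_video(pair.video1), "dstd"
        ) - video_statistic(preprocess_video(pair.video2), "dstd")
        assert prd.difference_score(pair, "dstd") == expected


class TestBaselineRule:
    @pytest.mark.parametrize(
        "domain, expect_when_s1_higher",
        [("cartoons", 1), ("paintings", 1), ("people", 2), ("animals", 2)],
    )
    def test_domain_direction(self, rng, domain, expect_when_s1_higher):
        cfg = synth.SimConfig.strong_signal(seed=9)
        # build a pair where video 1 is unambiguously more mobile
        v1 = synth.simulate_video(cfg, 10.0, domain, seed=1, slot=1)
        v2 = synth.simulate_video(cfg, 0.5, domain, seed=2, slot=2)
        pair = VideoPair(video1=v1, video2=v2, preferred=1)
        pred = prd.predict_pair_baseline(pair, "dstd")
        assert pred.s1 > pred.s2
        assert pred.predicted == expect_when_s1_higher

    def test_tie_flagged_slot1(self, rng):
        v = random_video(rng, domain="cartoons", slot=1)
        pair = VideoPair(
            video1=v, video2=dataclasses.replace(v, slot=2), preferred=2
        )
        pred = prd.predict_pair_baseline(pair, "dstd")
        assert pred.tie and pred.predicted == 1 and not pred.correct

    def test_uniform_scaling_never_changes_predictions(self, rng):
        from prefdyn.types import LandmarkFrame

        pair = make_pair(rng, domain="people")
        k = 2.5
        scale = lambda v: v.with_frames(
            [LandmarkFrame(index=f.index, points=f.points * k) for f in v.frames]
        )
        scaled = VideoPair(
            video1=scale(pair.video1), video2=scale(pair.video2), preferred=pair.preferred
        )
        a = prd.predict_pair_baseline(pair, "dmaxmin")
        b = prd.predict_pair_baseline(scaled, "dmaxmin")
        assert a.predicted == b.predicted


class TestEvaluateBaseline:
    def test_all_correct_closed_form(self):
        cfg = synth.SimConfig.strong_signal(seed=4)
        pairs = synth.simulate_pairs(cfg, domains=("cartoons",), n_targets=1, pairs_per_target=8)
        rep = prd.evaluate_baseline(pairs, "dmaxmin")
        if rep.domain_accuracy["cartoons"] == 1.0:
            assert rep.domain_p["cartoons"] == pytest.approx(0.5 ** 8)

    def test_pooled_is_weighted_mean(self):
        cfg = synth.SimConfig(seed=6)
        pairs = synth.simulate_pairs(cfg, n_targets=1, pairs_per_target=4)
        rep = prd.evaluate_baseline(pairs, "dstd")
        weighted = sum(
            rep.domain_accuracy[d] * rep.domain_n[d] for d in rep.domain_accuracy
        ) / sum(rep.domain_n.values())
        assert rep.pooled_accuracy == pytest.approx(weighted)

    def test_excluded_pairs_skipped(self, rng):
        pairs = [make_pair(rng, preferred=1), make_pair(rng, preferred=2)]
        pairs[1] = dataclasses.replace(pairs[1], excluded=True)
        rep = prd.evaluate_baseline(pairs, "dstd")
        assert rep.pooled_n == 1

    def test_reversal_inversion_flips_accuracy_exactly(self):
        """Flipping the simulated mobility-preference link in a reversed
        domain turns accuracy a into 1 - a (no ties on continuous data)."""
        cfg = synth.SimConfig.strong_signal(seed=13)
        pairs = synth.simulate_pairs(cfg, domains=("people",), n_targets=2, pairs_per_target=6)
        rep = prd.evaluate_baseline(pairs, "dstd")
        flipped = [
            dataclasses.replace(p, preferred=3 - p.preferred) for p in pairs
        ]
        rep_f = prd.evaluate_baseline(flipped, "dstd")
        assert rep_f.domain_accuracy["people"] == pytest.approx(
            1 - rep.domain_accuracy["people"]
        )


class TestBinomialP:
    def test_single_coin(self):
        assert prd.binomial_p(1, 1) == pytest.approx(0.5)

    def test_two_of_four_by_enumeration(self):
        assert prd.binomial_p(2, 4) == pytest.approx(11 / 16)

    def test_perfect_run_closed_form(self):
        for n in (1, 5, 12):
            assert prd.binomial_p(n, n) == pytest.approx(0.5 ** n)

    def test_matches_exhaustive_enumeration_all_small_trials(self):
        for n in range(1, 13):
            for k in range(n + 1):
                exact = sum(comb(n, j) for j in range(k, n + 1)) / 2 ** n
                assert prd.binomial_p(k, n) == pytest.approx(exact, abs=1e-15)

    def test_invalid_counts(self):
        for k, n in ((-1, 4), (5, 4), (0, 0)):
            with pytest.raises(ValueError):
                prd.binomial_p(k, n)


class TestCorrelation:
    def test_perfect_linear_relation(self):
        h = np.linspace(0.1, 0.9, 20)
        assert prd.human_algorithm_correlation(h, 3 * h + 1) == pytest.approx(1.0)

    def test_independent_inputs_near_zero(self, rng):
        h, s = rng.uniform(0, 1, 1000), rng.normal(0, 1, 1000)
        assert abs(prd.human_algorithm_correlation(h, s)) < 0.1

    def test_matches_definition_oracle(self, rng):
        h, s = rng.uniform(0, 1, 50), rng.normal(0, 2, 50)
        hm, sm = h.mean(), s.mean()
        expected = ((h - hm) * (s - sm)).sum() / np.sqrt(
            ((h - hm) ** 2).sum() * ((s - sm) ** 2).sum()
        )
        assert prd.human_algorithm_correlation(h, s) == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            prd.human_algorithm_correlation([0.5] * 5, [1, 2, 3, 4, 5])


def strong_pairs(domain="cartoons", n_targets=4, pairs_per_target=10, seed=5):
    cfg = synth.SimConfig.strong_signal(seed=seed)
    return synth.simulate_pairs(
        cfg, domains=(domain,), n_targets=n_targets, pairs_per_target=pairs_per_target
    )


@pytest.fixture(scope="module")
def cartoon_pairs():
    return strong_pairs()


class TestTrainSvm:
    CFG = prd.SvmConfig(
        gamma_grid=(1e-3, 1e-1, 10.0), c_grid=(0.1, 1.0, 100.0), folds=3,
        repetitions=2, seed=0,
    )

    def test_separable_data_fits_perfectly(self, cartoon_pairs):
        model = prd.train_svm(cartoon_pairs, self.CFG)
        X = prd.pair_features(cartoon_pairs)
        y = np.array([prd.pair_label(p) for p in cartoon_pairs])
        assert (model.predict_labels(X) == y).mean() == 1.0

    def test_single_class_rejected(self, cartoon_pairs):
        ones = [p for p in cartoon_pairs if p.preferred == 1]
        with pytest.raises(LandmarkDataError, match="both classes"):
            prd.train_svm(ones, self.CFG)

    def test_label_flip_symmetry(self, cartoon_pairs):
        """Swapping the two videos of every pair (negating features and
        labels) yields mirrored predictions."""
        model = prd.train_svm(cartoon_pairs, self.CFG)
        swapped = [
            VideoPair(
                video1=dataclasses.replace(p.video2, slot=1),
                video2=dataclasses.replace(p.video1, slot=2),
                preferred=3 - p.preferred,
            )
            for p in cartoon_pairs
        ]
        m2 = prd.train_svm(swapped, self.CFG)
        X = prd.pair_features(cartoon_pairs)
        np.testing.assert_array_equal(m2.predict_labels(-X), -model.predict_labels(X))

    def test_tuning_audit_uses_only_training_pairs(self, cartoon_pairs):
        model = prd.train_svm(cartoon_pairs, self.CFG)
        keys = {p.key for p in cartoon_pairs}
        audit = model.audit
        assert set(audit["fitted_pair_keys"]) == keys
        internal = set(audit["internal_train_keys"]) | set(
            audit["internal_validation_keys"]
        )
        assert internal == keys
        assert not set(audit["internal_train_keys"]) & set(
            audit["internal_validation_keys"]
        )
        assert audit["chosen"]["gamma"] in self.CFG.gamma_grid
        assert audit["chosen"]["C"] in self.CFG.c_grid


class TestCrossValidate:
    CFG = TestTrainSvm.CFG

    def test_seeded_reproducibility(self, cartoon_pairs):
        a = prd.cross_validate(cartoon_pairs, self.CFG)
        b = prd.cross_validate(cartoon_pairs, self.CFG)
        assert a.repetition_accuracies == b.repetition_accuracies
        assert [f["test_keys"] for f in a.folds] == [f["test_keys"] for f in b.folds]
        c = prd.cross_validate(
            cartoon_pairs, dataclasses.replace(self.CFG, seed=99)
        )
        assert [f["test_keys"] for f in c.folds] != [f["test_keys"] for f in a.folds]

    def test_strong_signal_high_accuracy(self, cartoon_pairs):
        rep = prd.cross_validate(cartoon_pairs, self.CFG)
        assert rep.mean_accuracy >= 0.9

    def test_fold_count_exceeding_class_rejected(self, cartoon_pairs):
        few = cartoon_pairs[:6]
        cfg = dataclasses.replace(self.CFG, folds=6)
        with pytest.raises(LandmarkDataError):
            prd.cross_validate(few, cfg)

    def test_folds_partition_and_never_leak(self, cartoon_pairs):
        rep = prd.cross_validate(cartoon_pairs, self.CFG)
        all_keys = {p.key for p in cartoon_pairs}
        per_rep: dict[int, list] = {}
        for fold in rep.folds:
            assert not set(fold["train_keys"]) & set(fold["test_keys"])
            assert set(fold["fitted_keys"]) == set(fold["train_keys"])
            per_rep.setdefault(fold["repetition"], []).extend(fold["test_keys"])
        for rep_no, test_keys in per_rep.items():
            assert sorted(test_keys) == sorted(all_keys)  # each pair tested once
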