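"""Metrics: AUC against a pair-counting oracle, support-weighted P/R/F1
against a confusion-matrix oracle, bootstrap intervals, majority voting and
spectral signatures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specband.evaluation import (auc_roc, bootstrap_ci, evaluate_scores,
                                 majority_vote, spectral_signature,
                                 weighted_prf)

rng = np.random.default_rng(13)


def auc_pair_oracle(labels, scores):
    """Exhaustive positive/negative pair counting; ties count one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def prf_confusion_oracle(labels, preds):
    """Per-class metrics from explicit TP/FP/FN counts, weighted by support."""
    out = np.zeros(3)
    n = len(labels)
    for cls in (0, 1):
        tp = sum(1 for l, p in zip(labels, preds) if l == cls and p == cls)
        fp = sum(1 for l, p in zip(labels, preds) if l != cls and p == cls)
        fn = sum(1 for l, p in zip(labels, preds) if l == cls and p != cls)
        support = tp + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out += np.array([prec, rec, f1]) * support / n
    return tuple(out)


class TestAUC:
    def test_perfectly_separated_scores(self):
        assert auc_roc([0, 0, 1, 1], [0.2, 0.6, 0.7, 0.8]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc_roc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_reversing_scores_complements(self):
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=20)
        assert auc_roc(labels, -scores) == pytest.approx(1 - auc_roc(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            auc_roc([1, 1], [0.2, 0.4])

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(4, 30))
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.min() == labels.max():
            labels[0], labels[1] = 0, 1
        scores = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)))
        assert auc_roc(labels, scores) == pytest.approx(
            auc_pair_oracle(labels, scores))


class TestWeightedPRF:
    def test_perfect_predictions(self):
        assert weighted_prf([0, 1, 0, 1], [0, 1, 0, 1]) == (1.0, 1.0, 1.0)

    def test_known_confusion_matrix(self):
        prec, rec, f1 = weighted_prf([0, 0, 1, 1], [0, 1, 1, 1])
        o_prec, o_rec, o_f1 = prf_confusion_oracle([0, 0, 1, 1], [0, 1, 1, 1])
        assert (prec, rec, f1) == pytest.approx((o_prec, o_rec, o_f1))

    def test_balanced_support_equals_macro_average(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        preds = np.array([0, 1, 0, 1, 0, 1])
        weighted = weighted_prf(labels, preds)
        from sklearn.metrics import precision_recall_fscore_support
        p, r, f1, _ = precision_recall_fscore_support(
            labels, preds, average="macro", zero_division=0)
        assert weighted == pytest.approx((p, r, f1))

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_confusion_oracle(self, data):
        n = data.draw(st.integers(2, 25))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        preds = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        assert weighted_prf(labels, preds) == pytest.approx(
            prf_confusion_oracle(labels, preds))


class TestBootstrap:
    labels = np.array([0, 1] * 15)
    scores = np.linspace(0, 1, 30)

    def test_constant_metric_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci(self.labels, self.scores, lambda l, s: 0.42,
                              n_resamples=50, seed=0)
        assert lo == hi == 0.42

    def test_same_seed_same_interval(self):
        a = bootstrap_ci(self.labels, self.scores, auc_roc, seed=3)
        b = bootstrap_ci(self.labels, self.scores, auc_roc, seed=3)
        assert a == b
        assert a[0] <= a[1]

    def test_interval_width_shrinks_with_sample_size(self):
        g = np.random.default_rng(1)
        widths = []
        for n in (100, 1000):
            labels = g.integers(0, 2, n)
            scores = g.uniform(size=n) + 0.3 * labels
            lo, hi = bootstrap_ci(labels, scores, auc_roc, seed=5)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_all_resamples_undefined_raises(self):
        def bad(l, s):
            raise ValueError("undefined")
        with pytest.raises(ValueError, match="every bootstrap resample"):
            bootstrap_ci(self.labels, self.scores, bad, n_resamples=10, seed=0)


class TestMajorityVote:
    def test_simple_majority(self):
        votes = majority_vote(["a"] * 3, [1, 1, 0], [0.9, 0.8, 0.3])
        assert votes[0].plant_label == 1
        assert votes[0].n_predicted_deficient == 2

    def test_tie_broken_by_mean_score(self):
        votes = majority_vote(["a", "a"], [1, 0], [0.9, 0.4])
        assert votes[0].plant_label == 1  # mean 0.65 > 0.5
        votes = majority_vote(["a", "a"], [1, 0], [0.6, 0.4])
        assert votes[0].plant_label == 0  # mean exactly 0.5 -> control

    def test_invariant_to_sample_order(self):
        idents = np.array(["a", "b", "a", "b", "a"])
        preds = np.array([1, 0, 0, 1, 1])
        scores = np.array([0.9, 0.2, 0.4, 0.8, 0.7])
        perm = rng.permutation(5)
        a = majority_vote(idents, preds, scores)
        b = majority_vote(idents[perm], preds[perm], scores[perm])
        assert [(v.identifier, v.plant_label, v.mean_score) for v in a] == \
            [(v.identifier, v.plant_label, v.mean_score) for v in b]

    def test_matches_group_by_oracle(self):
        idents = rng.choice(["a", "b", "c", "d"], size=40)
        preds = rng.integers(0, 2, 40)
        scores = rng.uniform(size=40)
        votes = {v.identifier: v for v in majority_vote(idents, preds, scores)}
        for ident in "abcd":
            sel = idents == ident
            n1, n0 = preds[sel].sum(), (~preds[sel].astype(bool)).sum()
            expected = 1 if n1 > n0 else 0 if n1 < n0 else \
                int(scores[sel].mean() > 0.5)
            assert votes[ident].plant_label == expected
            assert votes[ident].mean_score == pytest.approx(scores[sel].mean())


class TestSpectralSignature:
    def test_constant_cube_zero_sd(self):
        cube = np.full((4, 3, 3), 0.25)
        mean, sd = spectral_signature([cube], [np.ones((3, 3), bool)])
        np.testing.assert_allclose(mean, 0.25)
        np.testing.assert_allclose(sd, 0.0)

    def test_single_pixel(self):
        cube = rng.uniform(size=(4, 3, 3))
        mask = np.zeros((3, 3), bool)
        mask[1, 2] = True
        mean, sd = spectral_signature([cube], [mask])
        np.testing.assert_allclose(mean, cube[:, 1, 2])
        np.testing.assert_allclose(sd, 0.0)

    def test_matches_loop_oracle_across_cubes(self):
        cubes = [rng.uniform(size=(3, 4, 4)) for _ in range(3)]
        masks = [rng.uniform(size=(4, 4)) > 0.4 for _ in range(3)]
        mean, sd = spectral_signature(cubes, masks)
        for c in range(3):
            vals = [cube[c, i, j] for cube, mask in zip(cubes, masks)
                    for i in range(4) for j in range(4) if mask[i, j]]
            assert mean[c] == pytest.approx(np.mean(vals))
            assert sd[c] == pytest.approx(np.std(vals))

    def test_no_plant_pixels_rejected(self):
        with pytest.raises(ValueError, match="no plant pixels"):
            spectral_signature([np.ones((2, 2, 2))], [np.zeros((2, 2), bool)])


class TestReportStructure:
    def _report(self, n_per_session=12, n_sessions=3, seed=0):
        g = np.random.default_rng(seed)
        n = n_per_session * n_sessions
        labels = np.tile([0, 1], n // 2)
        scores = np.clip(0.5 + 0.3 * (labels - 0.5) + g.normal(0, 0.2, n), 0, 1)
        sessions = np.repeat(np.arange(1, n_sessions + 1), n_per_session)
        idents = np.array([f"P-{l}-{i % 4}" for i, l in enumerate(labels)])
        return evaluate_scores(labels, scores, sessions, idents,
                               n_resamples=100, seed=seed)

    def test_one_row_per_session_plus_pooled(self):
        report = self._report()
        assert [r.group for r in report.rows] == ["1", "2", "3", "pooled"]

    def test_pooled_counts_conserve_session_counts(self):
        report = self._report()
        pooled = report.pooled
        for cls in ("C", "D"):
            assert pooled.n_per_class[cls] == sum(
                r.n_per_class[cls] for r in report.session_rows())

    def test_single_class_session_omits_auc_with_warning(self):
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        scores = np.linspace(0.1, 0.9, 8)
        sessions = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        idents = np.array(list("abcdefgh"))
        with pytest.warns(UserWarning, match="single class"):
            report = evaluate_scores(labels, scores, sessions, idents,
                                     n_resamples=50, seed=0)
        row1 = next(r for r in report.rows if r.group == "1")
        assert row1.auc_roc is None and row1.f1 >= 0
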