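import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gemot import metrics
from gemot.metrics import (
    ErrorMatrix,
    auc_broad_sense,
    balanced_accuracy,
    balanced_fdr,
    causality_error_matrix,
    grouping_error_matrices,
)
from gemot.simulate import SyntheticTruth

MODELS = ["M1", "M2", "M3", "M4", "M5"]


def brute_force_confusion(pvals, labels, alpha):
    tp = fp = tn = fn = 0
    for p, lab in zip(pvals, labels):
        called = p <= alpha
        actual = lab in ("M1", "M4")
        if called and actual:
            tp += 1
        elif called:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


class TestErrorMatrix:
    def test_matches_brute_force_loop(self, rng):
        for _ in range(20):
            n = 200
            pvals = rng.uniform(0, 1, n)
            labels = rng.choice(MODELS, n).tolist()
            e = causality_error_matrix(pvals, labels, alpha=0.05)
            assert (e.tp, e.fp, e.tn, e.fn) == brute_force_confusion(pvals, labels, 0.05)
            assert e.total == n

    def test_vacuous_threshold(self, rng):
        pvals = rng.uniform(0, 1, 50)
        labels = rng.choice(MODELS, 50).tolist()
        e = causality_error_matrix(pvals, labels, alpha=1.0)
        assert e.tn == 0 and e.fn == 0

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), tn=st.integers(0, 50), fn=st.integers(0, 50)
    )
    @settings(max_examples=100, deadline=None)
    def test_derived_quantities_identities(self, tp, fp, tn, fn):
        e = ErrorMatrix(tp, fp, tn, fn)
        if tp + fn > 0 and tn + fp > 0:
            assert balanced_accuracy(e) == pytest.approx(
                0.5 * (tp / (tp + fn) + tn / (tn + fp)), abs=1e-12
            )
        if tp + fn > 0:
            pi0 = (fp + tn) / (tp + fn)
            assert e.pi0 == pytest.approx(pi0, abs=1e-12)
            if pi0 > 0 and fp / pi0 + tp > 0:
                assert balanced_fdr(e) == pytest.approx(
                    (fp / pi0) / (fp / pi0 + tp), abs=1e-12
                )


class TestScalarMetrics:
    def test_balanced_accuracy_printed_example(self):
        assert balanced_accuracy(ErrorMatrix(tp=8, fn=2, tn=45, fp=5)) == pytest.approx(0.85)

    def test_balanced_fdr_printed_example(self):
        e = ErrorMatrix(tp=8, fp=2, tn=90, fn=0)
        assert e.pi0 == pytest.approx(11.5)
        assert balanced_fdr(e) == pytest.approx((2 / 11.5) / (2 / 11.5 + 8), abs=1e-12)

    def test_balanced_fdr_reduces_to_plain_fdr_when_balanced(self):
        e = ErrorMatrix(tp=6, fp=2, tn=8, fn=4)  # pi0 = 1
        assert balanced_fdr(e) == pytest.approx(2 / 8)

    def test_errors_on_empty_classes(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ErrorMatrix(1, 0, 0, 0))
        with pytest.raises(ValueError):
            balanced_fdr(ErrorMatrix(0, 1, 1, 0))


class TestAUC:
    def test_perfect_separation(self):
        pvals = [0.001] * 5 + [0.9] * 5
        labels = ["M1"] * 5 + ["M2"] * 5
        assert auc_broad_sense(pvals, labels) == 1.0

    def test_equals_mann_whitney_pairwise_oracle(self, rng):
        for _ in range(20):
            n = 60
            pvals = rng.uniform(0, 1, n)
            pvals[rng.random(n) < 0.3] = 0.01  # induce ties
            labels = rng.choice(MODELS, n).tolist()
            actual = np.array([l in ("M1", "M4") for l in labels])
            if actual.all() or not actual.any():
                continue
            pos, neg = -pvals[actual], -pvals[~actual]
            wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            assert auc_broad_sense(pvals, labels) == pytest.approx(
                wins / (len(pos) * len(neg)), abs=1e-10
            )

    def test_random_scores_near_half(self, rng):
        pvals = rng.uniform(0, 1, 4000)
        labels = rng.choice(MODELS, 4000).tolist()
        assert auc_broad_sense(pvals, labels) == pytest.approx(0.5, abs=0.05)


class TestGrouping:
    @staticmethod
    def toy_truth():
        trait_class = {
            "a1": "causal_shared", "a2": "causal_shared", "aR": "reactive", "aI": "independent",
            "b1": "causal_shared", "b2": "causal_shared", "bR": "reactive", "bI": "independent",
        }
        subs = {
            "sA": {"variant": "vA", "P": ["a1", "a2", "aR", "aI"], "P_C": ["a1", "a2"],
                    "G": [], "G_C": []},
            "sB": {"variant": "vB", "P": ["b1", "b2", "bR", "bI"], "P_C": ["b1", "b2"],
                    "G": [], "G_C": []},
        }
        return SyntheticTruth(trait_class, {}, subs)

    def test_perfect_predictions(self):
        truth = self.toy_truth()
        naive, causal = grouping_error_matrices(
            [{"a1", "a2", "aR", "aI"}, {"b1", "b2", "bR", "bI"}], truth
        )
        assert naive.fp == naive.fn == 0
        assert causal.fp == 4  # reactive/independent traits counted against P^C
        assert causal.fn == 0

    def test_causal_only_predictions(self):
        truth = self.toy_truth()
        naive, causal = grouping_error_matrices([{"a1", "a2"}, {"b1", "b2"}], truth)
        assert causal.fp == causal.fn == 0
        assert naive.fn == 4  # misses reactive/independent members of P(s)

    def test_hand_enumerated_counts(self):
        truth = self.toy_truth()
        naive, causal = grouping_error_matrices([{"a1", "bR"}], truth)
        # sA matches {a1,bR} (intersection 1 with P(sA)); sB matches it too (bR)
        # universe has 8 traits, pooled over 2 sub-networks -> 16 cells
        assert naive.total == causal.total == 16
        assert naive.tp == 2  # a1 in sA, bR in sB
        assert causal.tp == 1  # only a1 counts as causal

    def test_no_predictions_all_positives_fn(self):
        truth = self.toy_truth()
        naive, causal = grouping_error_matrices([], truth)
        assert naive.tp == 0 and naive.fn == 8
        assert causal.fn == 4


class TestPermutationFDR:
    def test_planted_signal_gives_low_fdr(self):
        from gemot import benchmarks
        from gemot.pipeline import synthetic_config
        from gemot.simulate import NetworkSpec, SubNetworkSpec, simulate_network

        spec = NetworkSpec(
            n_variants=20, n_traits=30, n_transcripts=60, n_subnetworks=2,
            sub_spec=SubNetworkSpec(k=5, noise_level=0.25), seed=3,
        )
        ds, _ = simulate_network(spec)
        report = metrics.permutation_module_fdr(ds, synthetic_config(3), n_perm=3, seed=3)
        assert report["bipartite_modules"]["observed"] >= 1
        assert report["bipartite_modules"]["fdr"] == 0.0
        assert report["gemot_modules"]["observed"] >= 1

    def test_invalid_n_perm(self, small_dataset):
        with pytest.raises(ValueError):
            metrics.permutation_module_fdr(small_dataset, None, n_perm=0)
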