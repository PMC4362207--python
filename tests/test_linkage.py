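import numpy as np
import pytest
from scipy import stats

from gemot.linkage import (
    BipartiteGraph,
    LinkPotentialConfig,
    association_score,
    build_bipartite_graph,
    correlation_score,
    ld_correlation,
    link_potential,
)
from gemot.linkage import _link_potential_from_scores
from gemot.data import AlignedDataset

from conftest import labeled, make_variant_table


def brute_force_link_potential(assoc, corr, n_groups=6, one_sided=True):
    """Independent re-implementation: explicit per-cutoff t-test loop."""
    cutoffs = [np.quantile(assoc, q / n_groups) for q in range(1, n_groups)]
    best = 0.0
    for cut in cutoffs:
        hi = corr[assoc > cut]
        lo = corr[assoc <= cut]
        if len(hi) < 2 or len(lo) < 2:
            continue
        if abs(hi.mean() - lo.mean()) <= 1e-12 * (1 + abs(hi.mean()) + abs(lo.mean())):
            continue  # degenerate contrast maps to 0 by contract
        t, p = stats.ttest_ind(hi, lo, equal_var=True)
        if not np.isfinite(t):
            continue
        if one_sided:
            p = stats.t.sf(t, len(hi) + len(lo) - 2)
        best = max(best, min(-np.log10(max(p, 1e-320)), 320.0))
    return best


class TestAssociationScore:
    def test_matches_pooled_t_oracle(self):
        # frozen from the pooled two-sample t formula: t=3.674 (df 4), p=0.02131
        score = association_score([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert score == pytest.approx(-np.log10(0.021312), abs=2e-4)

    def test_random_instances_match_scipy(self, rng):
        for _ in range(50):
            v = rng.binomial(1, 0.5, 30).astype(float)
            if v.sum() < 2 or v.sum() > 28:
                continue
            g = rng.standard_normal(30)
            _, p = stats.ttest_ind(g[v == 1], g[v == 0], equal_var=True)
            assert association_score(g, v) == pytest.approx(-np.log10(p), abs=1e-9)

    def test_zero_effect_and_degenerate_group(self):
        assert association_score([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == 0.0
        assert association_score([1, 2, 3, 4], [0, 0, 0, 1]) == 0.0  # one obs in a group

    def test_affine_invariance(self, rng):
        v = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        g = rng.standard_normal(8)
        s = association_score(g, v)
        assert association_score(3.7 * g + 11, v) == pytest.approx(s, abs=1e-9)
        assert association_score(-2.0 * g, v) == pytest.approx(s, abs=1e-9)


class TestCorrelationScore:
    def test_perfect_and_sign_invariant(self):
        assert correlation_score([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert correlation_score([1, 2, 3], [-2, -4, -6]) == pytest.approx(1.0)

    def test_matches_brute_force_formula(self, rng):
        g = rng.standard_normal(50)
        p = rng.standard_normal(50)
        num = np.sum((g - g.mean()) * (p - p.mean()))
        den = np.sqrt(np.sum((g - g.mean()) ** 2) * np.sum((p - p.mean()) ** 2))
        assert correlation_score(g, p) == pytest.approx(abs(num / den), abs=1e-12)

    def test_degenerate_inputs(self):
        assert correlation_score([1, 1, 1], [1, 2, 3]) == 0.0
        assert correlation_score([1, 2], [1, 2]) == 0.0  # too few pairs


class TestLinkPotential:
    def test_no_separation_gives_zero(self, rng):
        assoc = rng.uniform(0, 5, 60)
        corr = np.full(60, 0.3)
        assert _link_potential_from_scores(assoc, corr[:, None], LinkPotentialConfig())[0] == 0.0

    def test_planted_signal_matches_brute_force(self, rng):
        n = 500
        assoc = rng.uniform(0, 10, n)
        corr = np.where(assoc > np.quantile(assoc, 5 / 6), 0.8, 0.1) + rng.normal(0, 0.02, n)
        mine = _link_potential_from_scores(assoc, corr[:, None], LinkPotentialConfig())[0]
        ref = brute_force_link_potential(assoc, corr)
        assert mine == pytest.approx(ref, rel=1e-9)
        assert mine > 50  # strong planted separation

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            assoc = rng.gamma(2.0, 1.0, n)
            corr = rng.uniform(0, 1, n)
            mine = _link_potential_from_scores(assoc, corr[:, None], LinkPotentialConfig())[0]
            assert mine == pytest.approx(brute_force_link_potential(assoc, corr), rel=1e-9)

    def test_default_partition_has_five_cutoffs(self):
        cfg = LinkPotentialConfig()
        assert cfg.n_groups == 6
        qs = np.arange(1, cfg.n_groups) / cfg.n_groups
        assert len(qs) == 5

    def test_trait_negation_invariance(self, rng):
        v = rng.binomial(1, 0.5, 40).astype(float)
        t = rng.standard_normal(40)
        expr = rng.standard_normal((30, 40))
        assert link_potential(v, t, expr) == pytest.approx(link_potential(v, -t, expr), abs=1e-9)

    def test_too_few_transcripts_errors(self, rng):
        with pytest.raises(ValueError):
            link_potential(rng.binomial(1, 0.5, 10), rng.standard_normal(10), rng.standard_normal((5, 10)))


class TestBipartiteGraph:
    def test_composition_equals_individual_calls(self, small_dataset):
        ds = small_dataset
        graph = build_bipartite_graph(ds)
        for vi in (0, 5):
            for ti in (0, 3):
                w = link_potential(
                    ds.genotypes.genotypes.values[vi], ds.traits.values[ti], ds.expression
                )
                assert graph.weights[vi, ti] == pytest.approx(w, abs=1e-9)

    def test_transcript_order_invariance(self, small_dataset, rng):
        ds = small_dataset
        g1 = build_bipartite_graph(ds)
        perm = rng.permutation(ds.expression.shape[0])
        ds2 = AlignedDataset(
            ds.genotypes,
            ds.expression.subset_rows([ds.expression.row_ids[i] for i in perm]),
            ds.traits,
            ds.strains,
        )
        g2 = build_bipartite_graph(ds2)
        np.testing.assert_allclose(g1.weights, g2.weights, atol=1e-9)

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            BipartiteGraph(np.array([[-1.0]]), ["v"], ["t"])


class TestLD:
    def test_self_complement_and_monomorphic(self):
        geno = make_variant_table(
            [[0, 1, 0, 1, 1], [1, 0, 1, 0, 0], [0, 0, 0, 0, 0], [0, 1, 0, 1, 1]]
        )
        r = ld_correlation(geno, "v0")
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert r[2] == 0.0  # monomorphic
        assert r[3] == pytest.approx(1.0)
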