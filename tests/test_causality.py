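import numpy as np
import pytest

from gemot.causality import (
    MODEL_FACTORIZATIONS,
    causality_pvalue,
    fit_triplet_model,
    mediation_pvalue,
)
from gemot.simulate import TripletSpec, simulate_triplets


def brute_force_fit(model_id, v, g, p):
    """Normal-equations oracle: per-equation OLS + pooled residual variance."""
    data = {"v": np.asarray(v, float), "g": np.asarray(g, float), "p": np.asarray(p, float)}
    n = len(data["v"])
    total_rss = 0.0
    betas = {}
    for child, parents in MODEL_FACTORIZATIONS[model_id]:
        X = np.column_stack([np.ones(n)] + [data[q] for q in parents])
        beta = np.linalg.solve(X.T @ X, X.T @ data[child])
        resid = data[child] - X @ beta
        total_rss += resid @ resid
        betas[child] = beta
    sigma2 = total_rss / (2 * n)
    ll = -n * (np.log(2 * np.pi) + np.log(sigma2) + 1)
    return ll, betas, sigma2


@pytest.fixture
def triplet(rng):
    n = 60
    v = rng.binomial(1, 0.5, n).astype(float)
    g = 0.5 * v + rng.normal(0, 0.6, n)
    p = 4.0 * g + rng.normal(0, 0.6, n)
    return v, g, p


class TestFit:
    @pytest.mark.parametrize("model_id", sorted(MODEL_FACTORIZATIONS))
    def test_matches_normal_equations_oracle(self, model_id, triplet):
        v, g, p = triplet
        fit = fit_triplet_model(model_id, v, g, p)
        ll, betas, sigma2 = brute_force_fit(model_id, v, g, p)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)
        assert fit.sigma2 == pytest.approx(sigma2, abs=1e-10)
        for eq, coefs in fit.coefficients.items():
            child = eq.split("|")[0]
            assert coefs["intercept"] == pytest.approx(betas[child][0], abs=1e-8)

    def test_generative_model_dominates_in_low_noise_limit(self, rng):
        n = 50
        v = rng.binomial(1, 0.5, n).astype(float)
        g = 0.5 * v + rng.normal(0, 1e-6, n)
        p = 1.0 * g + rng.normal(0, 1e-6, n)
        lls = {m: fit_triplet_model(m, v, g, p).loglik for m in ("M1", "M2", "M3")}
        assert lls["M1"] > lls["M2"] and lls["M1"] > lls["M3"]

    def test_m1_nested_in_m4(self, triplet):
        v, g, p = triplet
        assert fit_triplet_model("M4", v, g, p).loglik >= fit_triplet_model("M1", v, g, p).loglik

    def test_requires_both_alleles_and_enough_data(self, rng):
        with pytest.raises(ValueError):
            fit_triplet_model("M1", [0, 0, 0, 0, 0], rng.standard_normal(5), rng.standard_normal(5))
        with pytest.raises(ValueError):
            fit_triplet_model("M1", [0, 1, 0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestCausalityPvalue:
    def test_lr_consistent_with_model_fits(self, triplet):
        v, g, p = triplet
        res = causality_pvalue(v, g, p, B=10, seed=0)
        lr2 = fit_triplet_model("M1", v, g, p).loglik - fit_triplet_model("M2", v, g, p).loglik
        lr3 = fit_triplet_model("M1", v, g, p).loglik - fit_triplet_model("M3", v, g, p).loglik
        assert res.lr_vs_M2 == pytest.approx(lr2, abs=1e-8)
        assert res.lr_vs_M3 == pytest.approx(lr3, abs=1e-8)

    def test_causality_p_is_max_and_floored(self, triplet):
        v, g, p = triplet
        res = causality_pvalue(v, g, p, B=50, seed=3)
        assert res.causality_p == max(res.p_vs_M2, res.p_vs_M3)
        assert res.p_vs_M2 >= 1.0 / 51 and res.p_vs_M3 >= 1.0 / 51
        assert res.n_permutations == 50

    def test_default_permutation_count_is_100(self, triplet):
        v, g, p = triplet
        assert causality_pvalue(v, g, p, seed=0).n_permutations == 100

    def test_allele_swap_invariance(self, triplet):
        v, g, p = triplet
        a = causality_pvalue(v, g, p, B=64, seed=9)
        b = causality_pvalue(1 - v, g, p, B=64, seed=9)
        assert a.lr_vs_M2 == pytest.approx(b.lr_vs_M2, abs=1e-9)
        assert a.lr_vs_M3 == pytest.approx(b.lr_vs_M3, abs=1e-9)

    def test_common_scale_invariance(self, triplet):
        v, g, p = triplet
        a = causality_pvalue(v, g, p, B=32, seed=5)
        b = causality_pvalue(v, 2.5 * g, 2.5 * p, B=32, seed=5)
        assert a.lr_vs_M2 == pytest.approx(b.lr_vs_M2, rel=1e-9)
        assert a.lr_vs_M3 == pytest.approx(b.lr_vs_M3, rel=1e-9)
        assert a.causality_p == b.causality_p

    def test_chain_significant_fork_not(self, rng):
        n = 100
        hits_chain, hits_fork = 0, 0
        reps = 20
        for i in range(reps):
            v = rng.binomial(1, 0.5, n).astype(float)
            m = 1.5 * v + rng.normal(0, 0.3, n)
            chain_t = 0.6 * m + rng.normal(0, 0.2, n)
            fork_t = 1.5 * v + rng.normal(0, 0.3, n)
            if mediation_pvalue(v, m, chain_t, B=100, seed=i).causality_p <= 0.05:
                hits_chain += 1
            if mediation_pvalue(v, m, fork_t, B=100, seed=i).causality_p <= 0.05:
                hits_fork += 1
        assert hits_chain >= 18
        assert hits_fork <= 4

    def test_mediation_identical_to_causality(self, triplet):
        v, g, p = triplet
        a = causality_pvalue(v, g, p, B=40, seed=11)
        b = mediation_pvalue(v, g, p, B=40, seed=11)
        assert (a.p_vs_M2, a.p_vs_M3, a.causality_p) == (b.p_vs_M2, b.p_vs_M3, b.causality_p)

    def test_invalid_B(self, triplet):
        v, g, p = triplet
        with pytest.raises(ValueError):
            causality_pvalue(v, g, p, B=0)


class TestSmallBenchmarks:
    def test_m4_detected_as_broad_sense_causal(self, rng):
        spec = TripletSpec(per_model_count=30, lambda_=4.0, sigma=0.6, seed=21)
        coll, _ = simulate_triplets(spec)
        idx = [i for i, lab in enumerate(coll.labels) if lab == "M4"]
        ps = [causality_pvalue(coll.v[i], coll.g[i], coll.p[i], B=100, seed=i).causality_p for i in idx]
        assert np.median(ps) <= 0.05

    def test_reactive_and_mirrored_models_not_called(self, rng):
        spec = TripletSpec(per_model_count=30, lambda_=4.0, sigma=0.6, seed=22)
        coll, _ = simulate_triplets(spec)
        for lab in ("M3", "M5"):
            idx = [i for i, l in enumerate(coll.labels) if l == lab]
            ps = [
                causality_pvalue(coll.v[i], coll.g[i], coll.p[i], B=100, seed=i).causality_p
                for i in idx
            ]
            assert np.mean(np.array(ps) <= 0.05) <= 0.1, lab
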