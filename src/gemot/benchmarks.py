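"""Reusable synthetic benchmarks for the causality test and the pipeline.

Each routine simulates data under a published study design, runs the method,
and returns plain-dict metrics, so the command line, the test suite, and
reproduction scripts all share one code path.
"""

from __future__ import annotations

import numpy as np

from gemot import metrics, simulate
from gemot.causality import causality_pvalue
from gemot.data import AlignedDataset, LabeledMatrix, VariantTable
from gemot.pipeline import PipelineConfig, run, synthetic_config
from gemot.refine import refine_module
from gemot.rng import derive_seeds


def _collection_pvalues(coll: simulate.TripletCollection, B: int, seed: int) -> np.ndarray:
    seeds = derive_seeds(seed, len(coll.labels))
    return np.array(
        [
            causality_pvalue(coll.v[i], coll.g[i], coll.p[i], B=B, seed=int(seeds[i])).causality_p
            for i in range(len(coll.labels))
        ]
    )


def causality_benchmark(
    seed: int = 0,
    B: int = 100,
    alpha: float = 0.05,
    per_model: int = 250,
    lambda_: float = 4.0,
    sigma: float = 0.6,
) -> dict:
    """AUC and balanced FDR of broad-sense causality on the M1-M5 collection."""
    spec = simulate.TripletSpec(per_model_count=per_model, lambda_=lambda_, sigma=sigma, seed=seed)
    coll, _ = simulate.simulate_triplets(spec)
    pvals = _collection_pvalues(coll, B, seed)
    e = metrics.causality_error_matrix(pvals, coll.labels, alpha)
    return {
        "n_triplets": len(coll.labels),
        "auc": metrics.auc_broad_sense(pvals, coll.labels),
        "balanced_fdr": metrics.balanced_fdr(e),
        "balanced_accuracy": metrics.balanced_accuracy(e),
        "counts": {"tp": e.tp, "fp": e.fp, "tn": e.tn, "fn": e.fn},
    }


def type_i_error(
    seed: int = 0,
    n_replicates: int = 500,
    B: int = 100,
    alpha: float = 0.05,
    lambda_: float = 4.0,
    sigma: float = 0.6,
) -> dict:
    """Empirical rejection rate of the causality test on M2-only (null) data."""
    spec = simulate.TripletSpec(per_model_count=n_replicates, lambda_=lambda_, sigma=sigma, seed=seed)
    coll, _ = simulate.simulate_triplets(spec)
    keep = [i for i, lab in enumerate(coll.labels) if lab == "M2"]
    sub = simulate.TripletCollection(coll.v[keep], coll.g[keep], coll.p[keep], ["M2"] * len(keep))
    pvals = _collection_pvalues(sub, B, seed)
    return {
        "n_replicates": len(keep),
        "rejection_rate": float(np.mean(pvals <= alpha)),
        "alpha": alpha,
    }


def subnetwork_benchmark(
    seed: int = 0,
    noise: float = 0.5,
    total_traits: int = 7,
    count: int = 100,
    net_kind: str = "Net-1",
    B: int = 1000,
    cutoff: float = 0.005,
) -> dict:
    """Stage-III grouping accuracy on a collection of co-mapped sub-networks.

    Each sub-network is handed to stage III as a ready-made tripartite module
    (mimicking its role in the full pipeline); the refined trait sets are
    scored against the known causal trait subsets, pooled over sub-networks.
    """
    spec = simulate.SubNetworkSpec(
        net_kind=net_kind, k=total_traits - 2, noise_level=noise, n_subnetworks=count, seed=seed
    )
    pairs = simulate.simulate_subnetworks(spec)
    merged_truth = simulate.SyntheticTruth({}, {}, {})
    predicted_groups: list[set[str]] = []
    sub_seeds = derive_seeds(seed, count)
    for (ds, truth), s in zip(pairs, sub_seeds):
        merged_truth.trait_class.update(truth.trait_class)
        merged_truth.transcript_class.update(truth.transcript_class)
        merged_truth.subnetworks.update(truth.subnetworks)
        tri = simulate.as_tripartite_module(ds)
        ref = refine_module(tri, ds, transcript_cutoff=cutoff, B=B, seed=int(s))
        if ref is not None:
            predicted_groups.append(set(ref.trait_ids))
    naive, causal = metrics.grouping_error_matrices(predicted_groups, merged_truth)
    return {
        "n_subnetworks": count,
        "noise_level": noise,
        "n_recovered_modules": len(predicted_groups),
        "naive_balanced_accuracy": metrics.balanced_accuracy(naive),
        "causal_balanced_accuracy": metrics.balanced_accuracy(causal),
        "causal_balanced_fdr": metrics.balanced_fdr(causal) if causal.tp + causal.fp > 0 else 0.0,
    }


def network_recovery(
    seed: int = 0,
    noise: float = 0.5,
    total_traits: int = 7,
    config: PipelineConfig | None = None,
) -> dict:
    """End-to-end pipeline run on one planted large network.

    Reports the per-stage module counts and the best Jaccard index between
    any recovered module's trait set and any planted causal trait group.
    """
    spec = simulate.NetworkSpec(
        sub_spec=simulate.SubNetworkSpec(k=total_traits - 2, noise_level=noise),
        seed=seed,
    )
    ds, truth = simulate.simulate_network(spec)
    config = config or synthetic_config(seed)
    result = run(ds, config)
    best_jaccard = 0.0
    recovered = [set(g.trait_ids) for g in result.gemot]
    for sub_id in truth.subnetworks:
        p_c = truth.causal_traits(sub_id)
        for q in recovered:
            j = len(q & p_c) / len(q | p_c)
            best_jaccard = max(best_jaccard, j)
    return {"counts": result.counts, "best_jaccard": best_jaccard}


def simulate_noise_dataset(
    n_variants: int = 100,
    n_traits: int = 100,
    n_transcripts: int = 200,
    n_individuals: int = 100,
    seed: int = 0,
) -> AlignedDataset:
    """A structure-free dataset: binomial genotypes, standard-normal traits,
    covariance-structured but signal-free transcripts."""
    rng = np.random.default_rng(seed)
    strains = [f"S{j:03d}" for j in range(n_individuals)]
    vids = [f"v{i:03d}" for i in range(n_variants)]
    geno = VariantTable(
        vids,
        ["1"] * n_variants,
        [1_000_000 * (i + 1) for i in range(n_variants)],
        LabeledMatrix(rng.binomial(1, 0.5, size=(n_variants, n_individuals)).astype(float), vids, strains),
    )
    cov = simulate.synthesize_background_cov(n_transcripts, seed=seed)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_transcripts))
    expr = LabeledMatrix(
        chol @ rng.standard_normal((n_transcripts, n_individuals)),
        [f"g{i:03d}" for i in range(n_transcripts)],
        strains,
    )
    traits = LabeledMatrix(
        rng.standard_normal((n_traits, n_individuals)),
        [f"p{i:03d}" for i in range(n_traits)],
        strains,
    )
    return AlignedDataset(geno, expr, traits, strains)


def null_module_rate(n_seeds: int = 20, seed: int = 0, config: PipelineConfig | None = None) -> dict:
    """Fraction of pure-noise datasets yielding zero validated modules."""
    seeds = derive_seeds(seed, n_seeds)
    zero = 0
    counts = []
    for s in seeds:
        ds = simulate_noise_dataset(seed=int(s))
        cfg = config or synthetic_config(int(s))
        result = run(ds, cfg)
        counts.append(result.counts["gemot_modules"])
        if result.counts["gemot_modules"] == 0:
            zero += 1
    return {
        "n_seeds": n_seeds,
        "zero_module_fraction": zero / n_seeds,
        "gemot_module_counts": counts,
    }
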