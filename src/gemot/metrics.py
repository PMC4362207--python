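"""Benchmark metrics: confusion counts, balanced accuracy, class-imbalance
corrected FDR, rank-based AUC, trait-grouping evaluation, and whole-pipeline
permutation FDR.

The balanced FDR rescales false positives by pi0 = (FP + TN) / (TP + FN),
the negative-to-positive ratio of the benchmark, so methods can be compared
across collections with different class imbalance: FDR = FP_a / (FP_a + TP)
with FP_a = FP / pi0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from gemot.data import AlignedDataset, LabeledMatrix
from gemot.simulate import BROAD_SENSE_POSITIVE, SyntheticTruth


@dataclass
class ErrorMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def pi0(self) -> float:
        return (self.fp + self.tn) / (self.tp + self.fn)

    @property
    def fp_a(self) -> float:
        return self.fp / self.pi0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def causality_error_matrix(pvals, truth_labels, alpha: float) -> ErrorMatrix:
    """Confusion counts for broad-sense causality calls (positive: p <= alpha;
    actual positive: generating model in {M1, M4})."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) != len(truth_labels):
        raise ValueError("pvals and truth_labels must have equal length")
    called = pvals <= alpha
    actual = np.array([lab in BROAD_SENSE_POSITIVE for lab in truth_labels])
    return ErrorMatrix(
        tp=int(np.sum(called & actual)),
        fp=int(np.sum(called & ~actual)),
        tn=int(np.sum(~called & ~actual)),
        fn=int(np.sum(~called & actual)),
    )


def balanced_accuracy(e: ErrorMatrix) -> float:
    """(TPR + TNR) / 2; requires both classes to be present."""
    if e.tp + e.fn == 0 or e.tn + e.fp == 0:
        raise ValueError("balanced accuracy undefined with an empty class")
    return 0.5 * (e.tpr + e.tnr)


def balanced_fdr(e: ErrorMatrix) -> float:
    """FP_a / (FP_a + TP) with FP_a = FP / pi0 correcting class imbalance."""
    if e.tp + e.fn == 0:
        raise ValueError("pi0 undefined without actual positives")
    if e.fp == 0:
        if e.tp == 0:
            raise ValueError("balanced FDR undefined with FP_a + TP = 0")
        return 0.0
    fp_a = e.fp_a
    return fp_a / (fp_a + e.tp)


def auc_broad_sense(pvals, truth_labels) -> float:
    """Rank-based AUC of score -p against broad-sense truth (midrank ties)."""
    pvals = np.asarray(pvals, dtype=float)
    actual = np.array([lab in BROAD_SENSE_POSITIVE for lab in truth_labels])
    if actual.all() or not actual.any():
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(actual, -pvals))


def _match_group(groups: list[set[str]], target: set[str]) -> set[str]:
    """The predicted group with the largest intersection with ``target``.

    Ties break toward the smaller group, then lexicographic member order.
    """
    if not groups:
        return set()
    scored = sorted(
        groups,
        key=lambda q: (-len(q & target), len(q), tuple(sorted(q))),
    )
    return scored[0]


def grouping_error_matrices(
    predicted_groups: list[set[str]],
    truth: SyntheticTruth,
    universe: list[str] | None = None,
) -> tuple[ErrorMatrix, ErrorMatrix]:
    """Naive-grouping and grouping-by-causality confusion counts, pooled over
    sub-networks.

    For each sub-network s the matched group Q(s) is the predicted trait
    group with the largest intersection with P(s).  The naive matrix scores
    membership in Q(s) against P(s); the causal matrix scores it against the
    causal subset P^C(s).
    """
    if universe is None:
        universe = sorted(truth.trait_class)
    naive = np.zeros(4, dtype=int)  # tp, fp, tn, fn
    causal = np.zeros(4, dtype=int)
    for sub_id in sorted(truth.subnetworks):
        p_s = truth.all_traits(sub_id)
        p_c = truth.causal_traits(sub_id)
        q_s = _match_group([set(g) for g in predicted_groups], p_s)
        for t in universe:
            pred = t in q_s
            for counts, actual_set in ((naive, p_s), (causal, p_c)):
                actual = t in actual_set
                if pred and actual:
                    counts[0] += 1
                elif pred and not actual:
                    counts[1] += 1
                elif not pred and not actual:
                    counts[2] += 1
                else:
                    counts[3] += 1
    return (
        ErrorMatrix(*[int(x) for x in naive]),
        ErrorMatrix(*[int(x) for x in causal]),
    )


def permutation_module_fdr(
    ds: AlignedDataset,
    config=None,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, object]:
    """Whole-pipeline permutation FDR: reshuffle every transcript across
    strains, re-run the pipeline, and compare per-stage module counts.

    Returns per stage the observed count, the mean null count, and
    FDR = mean(null) / observed (None when the observed count is zero).
    """
    from gemot.pipeline import PipelineConfig, run  # local import: avoids a cycle

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or PipelineConfig()
    observed = run(ds, config).counts
    rng = np.random.default_rng(seed)
    null_counts = {stage: [] for stage in observed}
    for _ in range(n_perm):
        shuffled = rng.permuted(ds.expression.values, axis=1)
        ds_perm = AlignedDataset(
            ds.genotypes,
            LabeledMatrix(shuffled, list(ds.expression.row_ids), list(ds.expression.col_ids)),
            ds.traits,
            list(ds.strains),
        )
        perm_counts = run(ds_perm, config).counts
        for stage in observed:
            null_counts[stage].append(perm_counts[stage])
    report: dict[str, object] = {}
    for stage, obs in observed.items():
        mean_null = float(np.mean(null_counts[stage]))
        report[stage] = {
            "observed": obs,
            "mean_null": mean_null,
            "fdr": (mean_null / obs) if obs > 0 else None,
        }
    return report
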