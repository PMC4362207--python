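"""Stage III: representative-variant selection, Fisher-combined transcript
causality, and iterative elimination of non-causative transcripts and
unaffected traits.

The module's genomic interval is anchored to a single representative variant
(the interval variant with the best mean association to the candidate
transcripts).  Every (candidate, trait) pair receives a permutation-based
broad-sense causality p-value against that variant; a transcript's overall
evidence across the module's traits is combined with Fisher's method
(chi-squared with 2k degrees of freedom).  Transcripts whose combined p-value
is non-significant are dropped, then traits left without any significantly
causal transcript are dropped, and the two steps repeat to a fixed point.
Pair-level p-values are computed once and cached: the representative variant
is fixed, so re-computation could not change them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gemot.causality import causality_pvalue
from gemot.data import AlignedDataset
from gemot.linkage import association_score
from gemot.rng import derive_seeds
from gemot.transcripts import TripartiteModule

log = logging.getLogger(__name__)

MAX_REFINE_ITERATIONS = 50


@dataclass
class GemotModule:
    interval: tuple[str, int, int]
    representative_variant: str
    driver_transcripts: list[str]
    trait_ids: list[str]
    causality_matrix: dict[tuple[str, str], float]
    fisher_p: dict[str, float]


def representative_variant(
    module: TripartiteModule,
    ds: AlignedDataset,
) -> str:
    """The interval variant with the best mean association over the candidates.

    Ties go to the lowest physical position (variants are stored in genomic
    order, so the first maximum wins).
    """
    if not module.candidate_transcripts or not module.base.variant_ids:
        raise ValueError("module needs at least one candidate transcript and one variant")
    cand_rows = [ds.expression.row(g) for g in module.candidate_transcripts]
    best_id, best_mean = None, -np.inf
    for vid in module.base.variant_ids:
        v = ds.genotypes.genotypes.row(vid)
        mean_assoc = float(np.mean([association_score(g, v) for g in cand_rows]))
        if mean_assoc > best_mean:
            best_id, best_mean = vid, mean_assoc
    return best_id


def fisher_transcript_p(pvals: list[float]) -> float:
    """Fisher's combination: X = -2 sum(ln p), upper tail of chi2 with 2k df."""
    pvals = list(pvals)
    if not pvals:
        raise ValueError("need at least one p-value")
    if any(p <= 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * float(np.sum(np.log(pvals)))
    return float(stats.chi2.sf(x, 2 * len(pvals)))




def causality_matrix(
    module: TripartiteModule,
    ds: AlignedDataset,
    rep_variant: str,
    B: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Broad-sense causality p-value for every (candidate, trait) pair.

    Pairs with degenerate data (too few complete observations, constant
    vectors) get p = 1.
    """
    v = ds.genotypes.genotypes.row(rep_variant)
    pairs = [(g, t) for g in module.candidate_transcripts for t in module.base.trait_ids]
    seeds = derive_seeds(seed, len(pairs))
    out: dict[tuple[str, str], float] = {}
    for (g, t), s in zip(pairs, seeds):
        try:
            res = causality_pvalue(v, ds.expression.row(g), ds.traits.row(t), B=B, seed=int(s))
            out[(g, t)] = res.causality_p
        except ValueError:
            log.warning("causality_matrix: degenerate pair (%s, %s); p = 1", g, t)
            out[(g, t)] = 1.0
    return out


def refine_module(
    module: TripartiteModule,
    ds: AlignedDataset,
    transcript_cutoff: float = 0.005,
    B: int = 1000,
    seed: int = 0,
) -> GemotModule | None:
    """Iteratively eliminate non-causative transcripts and unaffected traits.

    Returns None when every transcript or every trait is eliminated.  With
    the add-one permutation correction the cutoff must be attainable, i.e.
    B >= 1/cutoff - 1.
    """
    if not 0 < transcript_cutoff < 1:
        raise ValueError("transcript_cutoff must be in (0, 1)")
    if B < 1.0 / transcript_cutoff - 1.0:
        raise ValueError(
            f"B={B} cannot attain p < {transcript_cutoff}; need B >= {int(np.ceil(1 / transcript_cutoff - 1))}"
        )
    rep = representative_variant(module, ds)
    pmat = causality_matrix(module, ds, rep, B=B, seed=seed)

    transcripts = list(module.candidate_transcripts)
    traits = list(module.base.trait_ids)
    for _ in range(MAX_REFINE_ITERATIONS):
        fisher = {g: fisher_transcript_p([pmat[(g, t)] for t in traits]) for g in transcripts}
        kept_g = [g for g in transcripts if fisher[g] < transcript_cutoff]
        kept_t = [
            t for t in traits if any(pmat[(g, t)] < transcript_cutoff for g in kept_g)
        ]
        if not kept_g or not kept_t:
            return None
        if kept_g == transcripts and kept_t == traits:
            break
        transcripts, traits = kept_g, kept_t

    fisher = {g: fisher_transcript_p([pmat[(g, t)] for t in traits]) for g in transcripts}
    return GemotModule(
        interval=module.base.interval,
        representative_variant=rep,
        driver_transcripts=transcripts,
        trait_ids=traits,
        causality_matrix=pmat,
        fisher_p=fisher,
    )
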