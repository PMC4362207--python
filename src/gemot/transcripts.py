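"""Stage II: rank-based transcript link scores and tripartite modules.

For each transcript we rank its correlation scores against every trait and
its association scores against every variant (descending, average ranks for
ties, each list ranked separately).  The transcript's ranks at the module's
traits and variants (pooled) are compared with the full pooled rank list by a
two-sample Kolmogorov-Smirnov test; a small p-value means the transcript's
best scores concentrate inside the module, i.e. it is a plausible mediator.
Transcripts passing the cutoff become the module's candidate transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from gemot.bicluster import BipartiteModule
from gemot.data import AlignedDataset
from gemot.linkage import association_matrix, correlation_matrix


@dataclass
class TripartiteModule:
    base: BipartiteModule
    candidate_transcripts: list[str]
    link_scores: dict[str, float]


def _ks_pvalue(module_sample: np.ndarray, background: np.ndarray) -> float:
    method = "exact" if len(module_sample) + len(background) < 30 else "asymp"
    res = stats.ks_2samp(module_sample, background, method=method)
    return float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


def _link_scores_for_module(
    module: BipartiteModule,
    ds: AlignedDataset,
    assoc: np.ndarray,
    corr: np.ndarray,
) -> np.ndarray:
    """K-S link p-value of every transcript for one module.

    assoc: (n_variants, n_transcripts); corr: (n_transcripts, n_traits).
    """
    if not module.trait_ids or not module.variant_ids:
        raise ValueError("module must have at least one trait and one variant")
    v_idx = [ds.genotypes.index_of(v) for v in module.variant_ids]
    t_idx = [ds.traits.row_ids.index(t) for t in module.trait_ids]
    n_transcripts = corr.shape[0]
    # rank 1 = strongest score, average ranks for ties; each list separately
    corr_ranks = stats.rankdata(-corr, axis=1)
    assoc_ranks = stats.rankdata(-assoc.T, axis=1)
    out = np.empty(n_transcripts)
    for g in range(n_transcripts):
        background = np.concatenate([corr_ranks[g], assoc_ranks[g]])
        sample = np.concatenate([corr_ranks[g, t_idx], assoc_ranks[g, v_idx]])
        out[g] = _ks_pvalue(sample, background)
    return out


def transcript_link_score(
    transcript_id: str,
    module: BipartiteModule,
    ds: AlignedDataset,
    assoc: np.ndarray | None = None,
    corr: np.ndarray | None = None,
) -> float:
    """K-S p-value comparing a transcript's in-module ranks with all its ranks."""
    if assoc is None:
        assoc = association_matrix(ds)
    if corr is None:
        corr = correlation_matrix(ds)
    g = ds.expression.row_ids.index(transcript_id)
    scores = _link_scores_for_module(module, ds, assoc, corr)
    return float(scores[g])


def extend_to_tripartite(
    module: BipartiteModule,
    ds: AlignedDataset,
    cutoff: float = 0.01,
    assoc: np.ndarray | None = None,
    corr: np.ndarray | None = None,
) -> TripartiteModule | None:
    """Attach all transcripts with link score < cutoff, sorted ascending by score.

    Returns None when no transcript survives (the module is dropped).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if assoc is None:
        assoc = association_matrix(ds)
    if corr is None:
        corr = correlation_matrix(ds)
    scores = _link_scores_for_module(module, ds, assoc, corr)
    hits = [
        (scores[g], ds.expression.row_ids[g])
        for g in range(len(scores))
        if scores[g] < cutoff or cutoff == 1  # cutoff 1 is vacuous: keep all
    ]
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[1]))
    return TripartiteModule(
        base=module,
        candidate_transcripts=[g for _, g in hits],
        link_scores={g: float(s) for s, g in hits},
    )
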