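"""Stage-I scoring: variant-transcript association, transcript-trait
correlation, the link-potential statistic, and the bipartite graph.

The link potential of a (variant, trait) pair asks whether transcripts
strongly associated with the variant are also unusually correlated with the
trait -- evidence that some transcript could mediate between them, without
naming the transcript.  Association scores are -log10 p of a pooled
two-sample t-test of expression between the two allele groups; correlation
scores are absolute Pearson r.  The association range is partitioned into
``n_groups`` equal-count groups (so ``n_groups - 1`` cutoffs); at each cutoff
the correlation scores above vs at/below it are compared by a one-sided
t-test, and the best -log10 p across cutoffs is the link potential.

All degenerate statistics (empty allele group, zero variance) map to score 0
so graph weights stay finite; log-scale survival functions are used so that
extreme p-values never underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from gemot.data import AlignedDataset, LabeledMatrix, VariantTable

log = logging.getLogger(__name__)

_LN10 = np.log(10.0)


@dataclass
class LinkPotentialConfig:
    """Settings for the link-potential statistic.

    n_groups: number of equal-count association groups (n_groups - 1 cutoffs).
    one_sided: test for larger correlations in the high-association group.
    equal_var: pooled (Student) two-sample t-tests; Welch when False.
    """

    n_groups: int = 6
    one_sided: bool = True
    equal_var: bool = True

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")


@dataclass
class BipartiteGraph:
    """Variants x traits matrix of link-potential weights (all finite, >= 0)."""

    weights: np.ndarray
    variant_ids: list[str]
    trait_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.variant_ids), len(self.trait_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if not np.isfinite(self.weights).all() or (self.weights < 0).any():
            raise ValueError("weights must be finite and non-negative")

    def weight(self, variant_id: str, trait_id: str) -> float:
        return float(self.weights[self.variant_ids.index(variant_id), self.trait_ids.index(trait_id)])


#: scores are capped at -log10 of the smallest representable p (1e-320)
MAX_SCORE = 320.0


def _neglog10_t_sf(t: np.ndarray | float, df: np.ndarray | float, two_sided: bool) -> np.ndarray:
    """-log10 p of a t statistic via the log survival function, capped at MAX_SCORE."""
    t = np.asarray(t, dtype=float)
    if two_sided:
        logp = stats.t.logsf(np.abs(t), df) + np.log(2.0)
        logp = np.minimum(logp, 0.0)  # 2*sf can exceed 1 at t ~ 0
    else:
        logp = stats.t.logsf(t, df)
    logp = np.maximum(logp, -MAX_SCORE * _LN10)
    return -logp / _LN10


def _negligible_diff(m1, m0) -> np.ndarray:
    """Mean differences at floating-point noise level (degenerate tests -> 0)."""
    return np.abs(m1 - m0) <= 1e-12 * (1.0 + np.abs(m1) + np.abs(m0))


def _pooled_t(m1, v1, n1, m0, v0, n0, equal_var: bool):
    """Two-sample t statistic and df from group means/variances (ddof=1) and sizes."""
    if equal_var:
        df = n1 + n0 - 2
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    else:
        se1, se0 = v1 / n1, v0 / n0
        denom = np.sqrt(se1 + se0)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (se1 + se0) ** 2 / (se1**2 / (n1 - 1) + se0**2 / (n0 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    return t, df


def association_score(
    g: np.ndarray,
    v: np.ndarray,
    two_sided: bool = True,
    equal_var: bool = True,
) -> float:
    """-log10 p of a two-sample t-test of transcript values between allele groups.

    Returns 0 (with a warning) when either allele group has fewer than two
    pairwise-complete observations or the pooled variance is zero, so genome
    scans never abort on degenerate variants.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    obs = ~(np.isnan(g) | np.isnan(v))
    g, v = g[obs], v[obs]
    g0, g1 = g[v == 0], g[v == 1]
    if len(g0) < 2 or len(g1) < 2:
        log.warning("association_score: an allele group has < 2 observations; score 0")
        return 0.0
    if _negligible_diff(g1.mean(), g0.mean()):
        return 0.0
    t, df = _pooled_t(
        g1.mean(), g1.var(ddof=1), len(g1), g0.mean(), g0.var(ddof=1), len(g0), equal_var
    )
    if np.isnan(t):
        return 0.0
    return float(_neglog10_t_sf(t, df, two_sided))


def correlation_score(g: np.ndarray, p: np.ndarray) -> float:
    """Absolute Pearson correlation over pairwise-complete observations.

    Returns 0 (with a warning) for fewer than three complete pairs or a
    zero-variance vector.
    """
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    obs = ~(np.isnan(g) | np.isnan(p))
    g, p = g[obs], p[obs]
    if len(g) < 3 or g.std() == 0 or p.std() == 0:
        log.warning("correlation_score: degenerate input; score 0")
        return 0.0
    return float(abs(np.corrcoef(g, p)[0, 1]))


def _link_potential_from_scores(
    assoc: np.ndarray,
    corr: np.ndarray,
    cfg: LinkPotentialConfig,
) -> np.ndarray:
    """Link potentials for one variant against many traits.

    assoc: (n_transcripts,) association scores with the variant.
    corr: (n_transcripts, n_traits) correlation scores with each trait.
    """
    corr = np.atleast_2d(corr.T).T  # ensure 2-D (n_transcripts, n_traits)
    n_tr, n_traits = corr.shape
    qs = np.arange(1, cfg.n_groups) / cfg.n_groups
    cutoffs = np.quantile(assoc, qs)
    best = np.zeros(n_traits)
    for cut in cutoffs:
        high = assoc > cut
        n1 = int(high.sum())
        n0 = n_tr - n1
        if n1 < 2 or n0 < 2:
            continue
        c1, c0 = corr[high], corr[~high]
        m1, m0 = c1.mean(axis=0), c0.mean(axis=0)
        t, df = _pooled_t(
            m1, c1.var(axis=0, ddof=1), n1, m0, c0.var(axis=0, ddof=1), n0, cfg.equal_var
        )
        score = _neglog10_t_sf(t, df, two_sided=not cfg.one_sided)
        score = np.where(_negligible_diff(m1, m0) | np.isnan(t), 0.0, score)
        best = np.maximum(best, score)
    return best


def link_potential(
    v: np.ndarray,
    t: np.ndarray,
    expr: LabeledMatrix | np.ndarray,
    cfg: LinkPotentialConfig | None = None,
) -> float:
    """Link-potential score for one genotype vector and one trait vector.

    Requires at least ``2 * n_groups`` transcripts for a meaningful partition.
    """
    cfg = cfg or LinkPotentialConfig()
    values = expr.values if isinstance(expr, LabeledMatrix) else np.asarray(expr, dtype=float)
    if values.shape[0] < 2 * cfg.n_groups:
        raise ValueError(f"need >= {2 * cfg.n_groups} transcripts, got {values.shape[0]}")
    assoc = np.array([association_score(row, v) for row in values])
    corr = np.array([correlation_score(row, t) for row in values])
    return float(_link_potential_from_scores(assoc, corr[:, None], cfg)[0])


def association_matrix(ds: AlignedDataset, two_sided: bool = True, equal_var: bool = True) -> np.ndarray:
    """(n_variants, n_transcripts) association scores, vectorized over transcripts."""
    expr = ds.expression.values
    out = np.zeros((ds.genotypes.n_variants, expr.shape[0]))
    for i, v in enumerate(ds.genotypes.genotypes.values):
        known = ~np.isnan(v)
        mask1 = known & (v == 1)
        mask0 = known & (v == 0)
        out[i] = _group_t_scores(expr, mask0, mask1, two_sided, equal_var)
    return out


def _group_t_scores(expr, mask0, mask1, two_sided, equal_var):
    """Association scores of every transcript row for one allele split."""
    scores = np.zeros(expr.shape[0])
    e0, e1 = expr[:, mask0], expr[:, mask1]
    n0 = (~np.isnan(e0)).sum(axis=1)
    n1 = (~np.isnan(e1)).sum(axis=1)
    ok = (n0 >= 2) & (n1 >= 2)
    if not ok.any():
        return scores
    with np.errstate(invalid="ignore"):
        m0 = np.nanmean(e0, axis=1)
        m1 = np.nanmean(e1, axis=1)
        v0 = np.nanvar(e0, axis=1, ddof=1)
        v1 = np.nanvar(e1, axis=1, ddof=1)
    t, df = _pooled_t(m1, v1, np.maximum(n1, 2), m0, v0, np.maximum(n0, 2), equal_var)
    good = ok & ~np.isnan(t) & ~_negligible_diff(m1, m0)
    scores[good] = _neglog10_t_sf(t[good], np.asarray(df, dtype=float)[good] if np.ndim(df) else df, two_sided)
    return scores


def correlation_matrix(ds: AlignedDataset) -> np.ndarray:
    """(n_transcripts, n_traits) absolute Pearson correlations, pairwise-complete."""
    expr = ds.expression.values
    traits = ds.traits.values
    n_g, n_t = expr.shape[0], traits.shape[0]
    out = np.zeros((n_g, n_t))
    expr_nan = np.isnan(expr)
    for j in range(n_t):
        p = traits[j]
        p_obs = ~np.isnan(p)
        if not expr_nan.any():
            mask = p_obs
            e = expr[:, mask]
            pv = p[mask]
            if len(pv) < 3 or pv.std() == 0:
                continue
            ec = e - e.mean(axis=1, keepdims=True)
            pc = pv - pv.mean()
            denom = np.sqrt((ec**2).sum(axis=1) * (pc**2).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (ec @ pc) / denom
            out[:, j] = np.where(np.isfinite(r), np.abs(r), 0.0)
        else:
            for i in range(n_g):
                out[i, j] = correlation_score(expr[i], p)
    return out


def build_bipartite_graph(ds: AlignedDataset, cfg: LinkPotentialConfig | None = None) -> BipartiteGraph:
    """Compute the full variants x traits link-potential graph."""
    cfg = cfg or LinkPotentialConfig()
    if ds.expression.shape[0] < 2 * cfg.n_groups:
        raise ValueError("too few transcripts for the link-potential partition")
    assoc = association_matrix(ds)
    corr = correlation_matrix(ds)
    weights = np.zeros((assoc.shape[0], corr.shape[1]))
    for i in range(assoc.shape[0]):
        weights[i] = _link_potential_from_scores(assoc[i], corr, cfg)
    return BipartiteGraph(weights, list(ds.genotypes.variant_ids), list(ds.traits.row_ids))


def ld_correlation(geno: VariantTable, focal: str) -> np.ndarray:
    """Pearson correlation of every variant's genotype vector with the focal variant's.

    Monomorphic variants get correlation 0 with a warning.
    """
    f = geno.genotypes.values[geno.index_of(focal)]
    out = np.zeros(geno.n_variants)
    for i, v in enumerate(geno.genotypes.values):
        obs = ~(np.isnan(f) | np.isnan(v))
        if obs.sum() < 2 or f[obs].std() == 0 or v[obs].std() == 0:
            log.warning("ld_correlation: degenerate pair at %s", geno.variant_ids[i])
            continue
        out[i] = np.corrcoef(f[obs], v[obs])[0, 1]
    return out
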