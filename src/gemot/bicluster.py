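"""Stage I: seed-and-improve search for heavy biclusters in the link-potential
graph, constrained so each module's variants form one consecutive genomic run.

A seed is any (variant, trait) pair whose link potential exceeds the seed
threshold ``c_s``.  A member is kept only while its average link potential
over the opposite side exceeds the improvement threshold ``c_i``.  Because
membership is decided on averages, the search is robust to an additive
rescaling of all weights together with the thresholds.

Variant additions are restricted to positions adjacent to the module's
current run on its chromosome, which preserves the single-genomic-interval
structure by construction; a final heaviest-consecutive-run trim guards the
invariant for any externally supplied module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gemot.data import VariantTable
from gemot.linkage import BipartiteGraph

log = logging.getLogger(__name__)


@dataclass
class BiclusterConfig:
    c_s: float = 180.0
    c_i: float = 90.0
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not (self.c_s >= self.c_i > 0):
            raise ValueError("require c_s >= c_i > 0")


@dataclass
class BipartiteModule:
    """A consecutive run of variants plus a set of traits, with mean link potential."""

    variant_ids: list[str]
    trait_ids: list[str]
    interval: tuple[str, int, int]
    mean_weight: float

    def key(self) -> tuple:
        return (tuple(self.variant_ids), tuple(sorted(self.trait_ids)))


def seed_clusters(graph: BipartiteGraph, cfg: BiclusterConfig) -> list[tuple[str, str]]:
    """All (variant, trait) pairs with weight > c_s, by descending weight;
    ties broken lexicographically on (variant_id, trait_id)."""
    vi, ti = np.nonzero(graph.weights > cfg.c_s)
    seeds = [
        (float(graph.weights[i, j]), graph.variant_ids[i], graph.trait_ids[j])
        for i, j in zip(vi, ti)
    ]
    seeds.sort(key=lambda s: (-s[0], s[1], s[2]))
    return [(v, t) for _, v, t in seeds]


def _chrom_bounds(geno: VariantTable | None, n_variants: int) -> list[tuple[int, int]]:
    """Half-open [lo, hi) index ranges of each chromosome block (one block if no metadata)."""
    if geno is None:
        return [(0, n_variants)]
    bounds = []
    start = 0
    for i in range(1, geno.n_variants + 1):
        if i == geno.n_variants or geno.chromosome[i] != geno.chromosome[start]:
            bounds.append((start, i))
            start = i
    return bounds


def refine_bicluster(
    graph: BipartiteGraph,
    seed: tuple[str, str],
    cfg: BiclusterConfig,
    geno: VariantTable | None = None,
) -> BipartiteModule | None:
    """Grow and prune a bicluster from one seed to a fixed point.

    Alternates (a) additions -- every non-member trait with mean weight over
    the current variants > c_i, then run-adjacent variants likewise -- with
    (b) removals of members whose mean over the opposite side is <= c_i
    (variants are only trimmed from the ends of the run).  Returns None if
    either side empties.
    """
    W = graph.weights
    v_seed = graph.variant_ids.index(seed[0])
    t_seed = graph.trait_ids.index(seed[1])
    blocks = _chrom_bounds(geno, len(graph.variant_ids))
    blo, bhi = next((b for b in blocks if b[0] <= v_seed < b[1]))

    lo, hi = v_seed, v_seed + 1  # half-open run [lo, hi)
    traits = {t_seed}
    for _ in range(cfg.max_iter):
        changed = False
        run = np.arange(lo, hi)
        # (a) trait additions
        t_means = W[run].mean(axis=0)
        for j in np.nonzero(t_means > cfg.c_i)[0]:
            if j not in traits:
                traits.add(int(j))
                changed = True
        t_idx = sorted(traits)
        # (a) variant additions at the run's ends
        while lo - 1 >= blo and W[lo - 1, t_idx].mean() > cfg.c_i:
            lo -= 1
            changed = True
        while hi < bhi and W[hi, t_idx].mean() > cfg.c_i:
            hi += 1
            changed = True
        run = np.arange(lo, hi)
        # (b) trait removals
        t_means = W[run].mean(axis=0)
        for j in list(traits):
            if t_means[j] <= cfg.c_i:
                traits.discard(j)
                changed = True
        if not traits:
            return None
        t_idx = sorted(traits)
        # (b) variant removals; survivors trimmed to the heaviest consecutive run
        v_means = {i: W[i, t_idx].mean() for i in range(lo, hi)}
        keep = [i for i in range(lo, hi) if v_means[i] > cfg.c_i]
        if not keep:
            return None
        if len(keep) < hi - lo:
            seg = heaviest_consecutive_run(np.array([v_means.get(i, 0.0) for i in range(len(graph.variant_ids))]), keep)
            lo, hi = seg[0], seg[-1] + 1
            changed = True
        if not changed:
            break
    else:
        log.warning("refine_bicluster: no fixed point within max_iter=%d", cfg.max_iter)

    variant_ids = [graph.variant_ids[i] for i in range(lo, hi)]
    trait_ids = [graph.trait_ids[j] for j in sorted(traits)]
    if geno is not None:
        chrom = geno.chromosome[geno.index_of(variant_ids[0])]
        start = geno.position_bp[geno.index_of(variant_ids[0])]
        end = geno.position_bp[geno.index_of(variant_ids[-1])]
    else:
        chrom, start, end = "NA", lo + 1, hi
    mean_w = float(W[np.ix_(range(lo, hi), sorted(traits))].mean())
    return BipartiteModule(variant_ids, trait_ids, (chrom, start, end), mean_w)


def heaviest_consecutive_run(
    weights_row_means: np.ndarray, indices: list[int]
) -> list[int]:
    """Among maximal consecutive index runs, the one with the largest total weight."""
    runs: list[list[int]] = []
    for i in sorted(indices):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return max(runs, key=lambda r: weights_row_means[r].sum())


def find_bipartite_modules(
    graph: BipartiteGraph,
    geno: VariantTable | None = None,
    cfg: BiclusterConfig | None = None,
) -> list[BipartiteModule]:
    """Refine every seed, collapse exact duplicates, sort by descending mean weight."""
    cfg = cfg or BiclusterConfig()
    seen: set[tuple] = set()
    modules: list[BipartiteModule] = []
    for seed in seed_clusters(graph, cfg):
        mod = refine_bicluster(graph, seed, cfg, geno)
        if mod is None:
            continue
        if mod.key() in seen:
            continue
        seen.add(mod.key())
        modules.append(mod)
    modules.sort(key=lambda m: (-m.mean_weight, m.variant_ids[0], tuple(m.trait_ids)))
    return modules
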