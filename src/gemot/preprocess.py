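"""Preprocessing: Z-score normalization, mean-variance gene filtering, and
strain alignment with a minimum-overlap rule for traits.

These mirror the standard preparation of a recombinant-inbred panel: log-scale
expression is filtered to genes more variable than their intensity-matched
expectation, every feature row is standardized, and the three data layers are
restricted to their common strains, dropping traits observed in too few
strains (default fewer than 15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from gemot.data import AlignedDataset, LabeledMatrix, VariantTable

log = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    skipped_rows: list[str] = field(default_factory=list)


def zscore_normalize(m: LabeledMatrix, report: NormalizationReport | None = None) -> LabeledMatrix:
    """Standardize each row to mean 0, sd 1 (n-1 denominator) over non-missing entries.

    Rows with fewer than two non-missing values or zero variance pass through
    unchanged and are recorded in ``report`` (and the module log).
    """
    if m.values.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    out = m.values.copy()
    skipped: list[str] = []
    for i, row in enumerate(out):
        obs = ~np.isnan(row)
        if obs.sum() < 2:
            skipped.append(m.row_ids[i])
            continue
        sd = np.std(row[obs], ddof=1)
        if sd == 0:
            skipped.append(m.row_ids[i])
            continue
        out[i, obs] = (row[obs] - np.mean(row[obs])) / sd
    if skipped:
        log.warning("zscore_normalize: %d constant/short rows passed through unchanged", len(skipped))
    if report is not None:
        report.skipped_rows = skipped
    return LabeledMatrix(out, list(m.row_ids), list(m.col_ids))


def filter_variable_genes(
    expr: LabeledMatrix,
    window: int = 100,
    use_median: bool = False,
) -> LabeledMatrix:
    """Keep genes whose variance exceeds the expectation for their mean intensity.

    Genes are ordered by row mean; each gene's expected variance is the mean
    (optionally median) of row variances within a centered sliding window of
    ``window`` genes (truncated at the ends); genes whose observed variance is
    strictly larger are retained, in their original order.
    """
    n = expr.shape[0]
    if window < 3 or window > n:
        raise ValueError(f"window must be in [3, {n}], got {window}")
    means = np.nanmean(expr.values, axis=1)
    variances = np.nanvar(expr.values, axis=1, ddof=1)
    order = np.argsort(means, kind="stable")
    sorted_var = variances[order]
    half = window // 2
    keep = np.zeros(n, dtype=bool)
    center = np.median if use_median else np.mean
    for rank, gene_idx in enumerate(order):
        lo = max(0, rank - half)
        hi = min(n, rank + half + 1)
        expected = center(sorted_var[lo:hi])
        # strict inequality, with a relative guard against float jitter when
        # observed and expected variances are numerically identical
        keep[gene_idx] = variances[gene_idx] > expected * (1.0 + 1e-9) + 1e-300
    kept_ids = [expr.row_ids[i] for i in range(n) if keep[i]]
    log.info("filter_variable_genes: kept %d of %d genes (window=%d)", len(kept_ids), n, window)
    return expr.subset_rows(kept_ids)


def align_strains(
    geno: VariantTable,
    expr: LabeledMatrix,
    traits: LabeledMatrix,
    min_overlap: int = 15,
) -> AlignedDataset:
    """Restrict all layers to their common strains (sorted lexicographically)
    and drop traits with fewer than ``min_overlap`` non-missing values there.
    """
    common = sorted(set(geno.genotypes.col_ids) & set(expr.col_ids) & set(traits.col_ids))
    if not common:
        raise ValueError("no strains shared by genotype, expression, and trait matrices")
    geno_a = geno.subset_cols(common)
    expr_a = expr.subset_cols(common)
    traits_a = traits.subset_cols(common)
    n_obs = (~np.isnan(traits_a.values)).sum(axis=1)
    kept = [t for t, n in zip(traits_a.row_ids, n_obs) if n >= min_overlap]
    dropped = len(traits_a.row_ids) - len(kept)
    if dropped:
        log.info("align_strains: dropped %d traits with < %d strains observed", dropped, min_overlap)
    return AlignedDataset(geno_a, expr_a, traits_a.subset_rows(kept), common)
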