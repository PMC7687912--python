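"""Phenotype construction: initiation level and directionality index.

Raw per-tTRE window counts become two association phenotypes. The level
phenotype is depth-normalized (reads per million over tTRE windows),
matched to a median-of-ratios reference distribution by quantile
normalization. The directionality index is the log2 ratio of plus- to
minus-strand window counts, quantile-normalized the same way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "rpm_normalize",
    "median_of_ratios_reference",
    "quantile_normalize",
    "directionality_index",
    "level_phenotype",
    "directionality_phenotype",
]


def rpm_normalize(window_counts: pd.DataFrame,
                  per_sample_totals: pd.Series | None = None) -> pd.DataFrame:
    """Reads-per-million over the tTRE windows, per individual.

    value = count / (total / 1e6), where the total defaults to each sample's
    summed window counts. Zero totals are an error.
    """
    if per_sample_totals is None:
        per_sample_totals = window_counts.sum(axis=0)
    totals = per_sample_totals.reindex(window_counts.columns)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive library totals for samples: {bad}")
    return window_counts / (totals / 1e6)


def median_of_ratios_reference(matrix: pd.DataFrame) -> tuple[pd.Series, np.ndarray]:
    """Median-of-ratios size factors and the pooled reference distribution.

    For each row the ratio of each sample's value to the row's arithmetic
    mean is taken; a sample's size factor is its median ratio over rows.
    Rows that are all zero are excluded from factor computation. The
    reference distribution is the rank-wise mean of the scaled matrix's
    sorted columns — the target for quantile normalization.
    """
    if matrix.shape[1] < 2:
        raise ValueError("median-of-ratios needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if (values.sum(axis=0) == 0).any():
        bad = list(matrix.columns[values.sum(axis=0) == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    row_means = values.mean(axis=1)
    keep = row_means > 0
    if not keep.any():
        raise ValueError("all rows are zero; cannot compute size factors")
    ratios = values[keep] / row_means[keep, None]
    factors = pd.Series(np.median(ratios, axis=0), index=matrix.columns, name="size_factor")
    scaled = values / factors.to_numpy()[None, :]
    reference = np.sort(scaled, axis=0).mean(axis=1)
    return factors, reference


def quantile_normalize(matrix: pd.DataFrame, reference: np.ndarray) -> pd.DataFrame:
    """Replace each column by reference values at matching ranks.

    Ties within a column receive the mean of the reference values at the
    tied ranks, so the transform is deterministic and idempotent. The
    output's ``kind`` depends on what went in (level or directionality);
    the caller tags it.
    """
    reference = np.sort(np.asarray(reference, dtype=float))
    if len(reference) != matrix.shape[0]:
        raise ValueError(
            f"reference length {len(reference)} != number of rows {matrix.shape[0]}")
    out = np.empty(matrix.shape)
    for j in range(matrix.shape[1]):
        col = matrix.iloc[:, j].to_numpy(dtype=float)
        # average rank -> mean of tied reference quantiles
        ranks = rankdata(col, method="average") - 1
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def directionality_index(plus_counts, minus_counts, pseudocount: float = 1.0):
    """log2((plus + pc) / (minus + pc)) — positive means plus-dominant.

    The ratio of raw counts cancels sequencing depth; a pseudocount of 1
    (default) keeps zero-count windows finite. Antisymmetric under strand
    swap.
    """
    plus_arr = np.asarray(plus_counts, dtype=float)
    minus_arr = np.asarray(minus_counts, dtype=float)
    if (plus_arr < 0).any() or (minus_arr < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount == 0 and ((plus_arr == 0).any() or (minus_arr == 0).any()):
        raise ValueError("pseudocount 0 with zero counts gives undefined log ratio")
    di = np.log2(plus_arr + pseudocount) - np.log2(minus_arr + pseudocount)
    if isinstance(plus_counts, pd.DataFrame):
        return pd.DataFrame(di, index=plus_counts.index, columns=plus_counts.columns)
    return di


def level_phenotype(plus_counts: pd.DataFrame, minus_counts: pd.DataFrame) -> pd.DataFrame:
    """Full initiation-level pipeline: strand sum -> RPM -> quantile norm.

    The reference distribution comes from median-of-ratios scaling of the
    RPM matrix.
    """
    total = plus_counts + minus_counts
    rpm = rpm_normalize(total)
    _, reference = median_of_ratios_reference(rpm)
    out = quantile_normalize(rpm, reference)
    out.attrs["kind"] = "level"
    return out


def directionality_phenotype(plus_counts: pd.DataFrame, minus_counts: pd.DataFrame,
                             pseudocount: float = 1.0) -> pd.DataFrame:
    """Full directionality pipeline: raw-count log2 ratio -> quantile norm.

    Raw counts are used for the ratio (depth cancels); the quantile-
    normalization reference is the rank-wise mean of the DI matrix itself.
    """
    di = directionality_index(plus_counts, minus_counts, pseudocount)
    reference = np.sort(di.to_numpy(), axis=0).mean(axis=1)
    out = quantile_normalize(di, reference)
    out.attrs["kind"] = "directionality"
    return out
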