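"""Normalisation and label-level aggregation of locus counts.

TPM and CPM follow the standard definitions; size factors use the
median-of-ratios (RLE) estimator; the expressed-locus filter keeps a
feature when it averages at least one read per embryo over all samples
pooled. Expression log-ratios use a pseudocount of 0.5 throughout so that
features silent in one condition still get a finite ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CountMatrix, SampleSheet, TELocus

PSEUDOCOUNT = 0.5


@dataclass
class ExpressionTable:
    """Features x samples non-negative real expression values."""

    values: pd.DataFrame
    unit: str  # "TPM" | "CPM" | "RLE"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def compute_tpm(m: CountMatrix) -> ExpressionTable:
    """Transcripts per million: length-normalised rate rescaled to 1e6 per sample.

    An all-zero sample yields an all-zero column (with a warning) rather
    than NaNs.
    """
    rate = m.counts.div(m.lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with zero total counts: {list(totals.index[zero_cols])}", stacklevel=2
        )
    safe = totals.replace(0, np.nan)
    tpm = rate.div(safe, axis=1) * 1e6
    return ExpressionTable(tpm.fillna(0.0), unit="TPM")


def compute_cpm(m: CountMatrix) -> ExpressionTable:
    """Counts per million of the column total."""
    totals = m.counts.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with zero total counts: {list(totals.index[zero_cols])}", stacklevel=2
        )
    safe = totals.replace(0, np.nan)
    cpm = m.counts.div(safe, axis=1) * 1e6
    return ExpressionTable(cpm.fillna(0.0), unit="CPM")


def rle_size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios (RLE) size factors, rescaled to geometric mean 1.

    The per-feature reference is the geometric mean across samples;
    features with a zero in any sample are excluded from both the
    reference and the medians.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature has positive counts in every sample; cannot estimate RLE factors")
    pos = counts[all_positive]
    log_ref = np.log(pos).mean(axis=1)
    log_ratios = np.log(pos) - log_ref[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def filter_expressed(m: CountMatrix, min_mean_count: float = 1.0) -> CountMatrix:
    """Keep features with at least ``min_mean_count`` reads on average per sample.

    The average is over all samples pooled (both conditions together);
    the boundary is inclusive ("at least one read on average").
    """
    mean = m.counts.sum(axis=1) / m.counts.shape[1] if m.counts.shape[1] else m.counts.sum(axis=1)
    keep = mean >= min_mean_count
    return CountMatrix(m.counts.loc[keep], m.lengths.loc[keep])


def aggregate_by_label(
    expr: ExpressionTable, loci: list[TELocus], level: str = "subfamily"
) -> ExpressionTable:
    """Sum member-locus expression per subfamily or family label.

    Every feature id in ``expr`` must map to a locus; labels whose members
    are all absent from ``expr`` get 0.
    """
    if level not in {"subfamily", "family"}:
        raise ValueError(f"level must be subfamily or family, got {level!r}")
    label_of = {lc.locus_id: getattr(lc, level) for lc in loci}
    unmapped = [fid for fid in expr.feature_ids if fid not in label_of]
    if unmapped:
        raise KeyError(f"feature ids with no locus annotation: {unmapped[:5]}")
    labels = pd.Series([label_of[f] for f in expr.feature_ids], index=expr.values.index)
    agg = expr.values.groupby(labels).sum()
    all_labels = sorted({getattr(lc, level) for lc in loci})
    agg = agg.reindex(all_labels, fill_value=0.0)
    return ExpressionTable(agg, unit=expr.unit)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch t-test returning (t, p); degenerate zero-variance
    inputs give p=1 when means agree and p=0 otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        equal = np.isclose(x.mean(), y.mean())
        return (0.0, 1.0) if equal else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def family_ratio_test(
    agg: ExpressionTable,
    sheet: SampleSheet,
    numerator: str = "SCNT",
    denominator: str = "IVF",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-label log2 expression ratio between conditions with a Welch t-test.

    ratio = log2((mean_num + c) / (mean_den + c)) on the aggregated
    expression unit; p from a two-tailed Welch t-test on the per-embryo
    aggregated values.
    """
    num_samples, den_samples = sheet.require_groups(numerator, denominator)
    num = agg.values[num_samples]
    den = agg.values[den_samples]
    ratio = np.log2((num.mean(axis=1) + pseudocount) / (den.mean(axis=1) + pseudocount))
    pvals = [
        welch_t_test(num.loc[label].to_numpy(), den.loc[label].to_numpy())[1]
        for label in agg.values.index
    ]
    return pd.DataFrame(
        {"log2_ratio": ratio, "p": pvals}, index=agg.values.index
    ).rename_axis("label")
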