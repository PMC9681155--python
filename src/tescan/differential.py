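"""Negative-binomial differential testing of TE loci and genes.

The model for each feature is a two-group negative binomial on
size-factor-normalised counts:

    K_is / f_s  ~approx~  NB(mean mu_g(i,s), dispersion alpha_i)

with a shared per-feature dispersion estimated by method of moments from
the within-group variances (no shrinkage). The reported effect is

    log2FC_i = log2((mu_hat_SCNT + c) / (mu_hat_IVF + c)),  c = 0.5,

tested with a Wald statistic whose standard error comes from the NB
mean-variance relation Var(K) = mu + alpha mu^2 by the delta method, and
a two-sided normal p-value. P-values are adjusted by Benjamini-Hochberg,
and loci are classified SCNT-low / SCNT-high at |log2FC| >= 1 and
adjusted p < 0.1.

This is a deliberately transparent re-implementation of the NB testing
idea; it does not reproduce any particular package's dispersion shrinkage
or outlier handling, and its contract is the classification rule, not
numerical identity with other NB fitters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import CountMatrix, SampleSheet, TELocus
from .quantify import PSEUDOCOUNT, filter_expressed, rle_size_factors

DISPERSION_FLOOR = 1e-8

KLASS_LOW = "SCNT_low"
KLASS_HIGH = "SCNT_high"
KLASS_UNCHANGED = "unchanged"
KLASS_UNTESTED = "untested"


class TEDifferentialModel:
    """Two-group NB differential-expression model for a count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Features x samples integer counts.
    sample_sheet : SampleSheet
        Condition labels; the contrast is ``numerator`` over ``denominator``
        (default SCNT over IVF).
    size_factors : pd.Series, optional
        Per-sample positive factors; estimated by RLE when omitted.
    min_mean_count : float
        Expressed-feature filter (mean reads per sample, all samples
        pooled); features failing it are reported as ``untested``.
    """

    def __init__(
        self,
        counts: CountMatrix,
        sample_sheet: SampleSheet,
        size_factors: pd.Series | None = None,
        numerator: str = "SCNT",
        denominator: str = "IVF",
        pseudocount: float = PSEUDOCOUNT,
        min_mean_count: float = 1.0,
    ) -> None:
        self.counts = counts
        self.sample_sheet = sample_sheet
        self.numerator = numerator
        self.denominator = denominator
        self.pseudocount = pseudocount
        self.min_mean_count = min_mean_count
        sample_sheet.require_groups(numerator, denominator)
        if size_factors is None:
            size_factors = rle_size_factors(counts)
        if (size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        self.size_factors = size_factors.reindex(counts.sample_ids)
        if self.size_factors.isna().any():
            raise ValueError("size factors missing for some samples")

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        conditions: pd.Series | dict,
        lengths: pd.Series | None = None,
        **kwargs,
    ) -> "TEDifferentialModel":
        """Build from a plain DataFrame plus a sample->condition mapping."""
        if lengths is None:
            lengths = pd.Series(1000, index=counts.index)
        cond = pd.Series(conditions).reindex(counts.columns)
        sheet = SampleSheet(
            pd.DataFrame({"sample_id": counts.columns, "condition": cond.to_numpy()})
        )
        return cls(CountMatrix(counts, lengths), sheet, **kwargs)

    def fit(self) -> "TEDifferentialResults":
        m = self.counts
        norm = m.counts.div(self.size_factors, axis=1)
        num_ids = self.sample_sheet.samples_in(self.numerator)
        den_ids = self.sample_sheet.samples_in(self.denominator)
        x = norm[num_ids].to_numpy(dtype=float)  # numerator group (SCNT)
        y = norm[den_ids].to_numpy(dtype=float)
        n_x, n_y = x.shape[1], y.shape[1]

        mu_x = x.mean(axis=1)
        mu_y = y.mean(axis=1)
        var_x = x.var(axis=1, ddof=1)
        var_y = y.var(axis=1, ddof=1)

        # Method-of-moments dispersion pooled within groups:
        # Var = mu + alpha mu^2  =>  alpha = (Var - mu) / mu^2
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (n_x - 1) * (var_x - mu_x) + (n_y - 1) * (var_y - mu_y)
            den = (n_x - 1) * mu_x**2 + (n_y - 1) * mu_y**2
            alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), DISPERSION_FLOOR)
        alpha = np.maximum(alpha, DISPERSION_FLOOR)

        c = self.pseudocount
        log2fc = np.log2((mu_x + c) / (mu_y + c))
        # Delta method on log2 of the shifted group means. Normalised counts
        # K_s/f_s have Var = mu/f_s + alpha mu^2, hence the mean-1/f factor.
        f = self.size_factors
        inv_f_x = float(np.mean(1.0 / f.loc[num_ids]))
        inv_f_y = float(np.mean(1.0 / f.loc[den_ids]))
        var_mean_x = (mu_x * inv_f_x + alpha * mu_x**2) / n_x
        var_mean_y = (mu_y * inv_f_y + alpha * mu_y**2) / n_y
        se = np.sqrt(var_mean_x / (mu_x + c) ** 2 + var_mean_y / (mu_y + c) ** 2) / math.log(2)

        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        p = 2 * stats.norm.sf(np.abs(wald))
        # Features with zero counts everywhere carry no information.
        degenerate = (mu_x == 0) & (mu_y == 0)
        p = np.where(degenerate & (se == 0), np.nan, p)

        mean_per_sample = m.counts.sum(axis=1).to_numpy() / m.counts.shape[1]
        tested = (mean_per_sample >= self.min_mean_count) & ~np.isnan(p)

        table = pd.DataFrame(
            {
                "base_mean": norm.mean(axis=1).to_numpy(),
                "log2fc": log2fc,
                "se": se,
                "dispersion": alpha,
                "p": np.where(tested, p, np.nan),
            },
            index=m.counts.index,
        ).rename_axis("feature_id")

        padj = np.full(len(table), np.nan)
        mask = tested
        if mask.any():
            padj[mask] = bh_adjust(table.loc[mask, "p"].to_numpy())
        table["padj"] = padj
        table["klass"] = classify_differential(table["log2fc"], table["padj"])
        table.loc[~mask, "klass"] = KLASS_UNTESTED
        return TEDifferentialResults(self, table)


@dataclass
class TEDifferentialResults:
    """Fitted per-feature estimates, tests and SCNT-low/high classes."""

    model: TEDifferentialModel
    table: pd.DataFrame

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    @property
    def padj(self) -> pd.Series:
        return self.table["padj"]

    @property
    def klass(self) -> pd.Series:
        return self.table["klass"]

    def features_in_class(self, klass: str) -> list[str]:
        return list(self.table.index[self.table["klass"] == klass])

    def summary(self, top: int = 10) -> str:
        counts = self.table["klass"].value_counts()
        lines = [
            "TE differential expression (NB Wald test)",
            "=" * 48,
            f"contrast:        {self.model.numerator} / {self.model.denominator}",
            f"features:        {len(self.table)}",
            f"tested:          {int((self.table['klass'] != KLASS_UNTESTED).sum())}",
            f"{KLASS_LOW}:        {int(counts.get(KLASS_LOW, 0))}",
            f"{KLASS_HIGH}:       {int(counts.get(KLASS_HIGH, 0))}",
            f"thresholds:      |log2FC| >= 1, BH-adjusted p < 0.1",
            f"dispersion:      method-of-moments, no shrinkage",
            "",
            self.table.sort_values("padj").head(top).to_string(float_format="%.4g"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table[["base_mean", "log2fc", "p", "padj", "klass"]]
        out.to_csv(path, sep="\t", float_format="%.6g")


def nb_wald_test(
    m: CountMatrix,
    sheet: SampleSheet,
    factors: pd.Series | None = None,
    numerator: str = "SCNT",
    denominator: str = "IVF",
) -> pd.DataFrame:
    """Per-feature (log2fc, p) from the NB Wald model; functional wrapper
    around :class:`TEDifferentialModel`."""
    res = TEDifferentialModel(
        m, sheet, size_factors=factors, numerator=numerator, denominator=denominator
    ).fit()
    return res.table


def bh_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving and monotone."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def classify_differential(
    log2fc: pd.Series | np.ndarray,
    padj: pd.Series | np.ndarray,
    log2fc_cut: float = 1.0,
    padj_cut: float = 0.1,
) -> np.ndarray:
    """SCNT_low iff log2fc <= -cut and padj < padj_cut; SCNT_high symmetric;
    otherwise unchanged. Missing padj -> untested."""
    lfc = np.asarray(log2fc, dtype=float)
    pa = np.asarray(padj, dtype=float)
    klass = np.full(lfc.shape, KLASS_UNCHANGED, dtype=object)
    sig = ~np.isnan(pa) & (pa < padj_cut)
    klass[sig & (lfc <= -log2fc_cut)] = KLASS_LOW
    klass[sig & (lfc >= log2fc_cut)] = KLASS_HIGH
    klass[np.isnan(pa)] = KLASS_UNTESTED
    return klass


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention behind reported integer
    percentages such as 45% for 497/1109)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_of(n: int, total: int) -> int | None:
    """Integer percent n/total, rounded half away from zero; None when the
    stratum is empty."""
    if total == 0:
        return None
    return round_half_away(100.0 * n / total)


def composition_summary(
    diff: pd.DataFrame,
    loci: list[TELocus],
    level: str = "family",
) -> pd.DataFrame:
    """Counts and integer percentages per family/subfamily within the
    expressed / SCNT_low / SCNT_high strata.

    ``diff`` is the table from :meth:`TEDifferentialModel.fit` (or any frame
    with a ``klass`` column indexed by locus id).
    """
    label_of = {lc.locus_id: getattr(lc, level) for lc in loci}
    klass = diff["klass"]
    strata = {
        "expressed": klass != KLASS_UNTESTED,
        KLASS_LOW: klass == KLASS_LOW,
        KLASS_HIGH: klass == KLASS_HIGH,
    }
    rows = []
    labels = sorted({getattr(lc, level) for lc in loci})
    for stratum, mask in strata.items():
        ids = diff.index[mask]
        total = len(ids)
        lab_counts: dict[str, int] = {lab: 0 for lab in labels}
        for fid in ids:
            lab = label_of.get(fid)
            if lab is not None:
                lab_counts[lab] += 1
        for lab in labels:
            n = lab_counts[lab]
            pct = percent_of(n, total)
            rows.append(
                {
                    "stratum": stratum,
                    level: lab,
                    "n": n,
                    "n_total": total,
                    "percent": pct if pct is not None else "—",
                }
            )
    return pd.DataFrame(rows)
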