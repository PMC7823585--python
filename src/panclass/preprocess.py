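"""Count normalization and transformation.

Raw gene-by-sample count matrices are scaled with TMM (trimmed mean of
M-values) factors, transformed to log2(CPM + 0.5), filtered for low
expression within each cohort, and z-scored per gene within cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

VALID_UNITS = ("counts", "CPM", "logCPM", "TPM-like", "zscore")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values tagged with cohort and unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns.
    cohort : str
        Cohort identifier.
    unit : str
        One of ``counts``, ``CPM``, ``logCPM``, ``TPM-like``, ``zscore``.
    """

    values: pd.DataFrame
    cohort: str = "cohort"
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate gene ids {dups[:5]}; average duplicates at load time"
            )
        if self.unit == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors, geometric mean 1."""

    factors: pd.Series
    reference: str = field(default="")

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(float)
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            raise ValueError("normalization factors must be finite and positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"factors must have geometric mean 1 (got {gm})")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """One TMM factor: weighted trimmed mean of M-values of obs against ref.

    M and A are computed on library-size-normalized fractions over genes
    positive in both samples; 30% of M extremes and 5% of A extremes are
    trimmed from each tail and the remaining M are averaged with inverse
    asymptotic-variance (precision) weights.
    """
    pos = (obs > 0) & (ref > 0)
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    if o.size == 0:
        return 1.0
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # asymptotic variance of M (delta method, binomial counts)
    v = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_l) & (rM <= hi_l) & (rA >= lo_s) & (rA <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = np.mean(M[keep])
    return float(2.0**f)


def tmm_factors(counts: ExpressionMatrix) -> NormalizationFactors:
    """TMM scaling factors for every sample of a count matrix.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions. Factors are rescaled to have
    geometric mean 1.
    """
    if counts.unit != "counts":
        raise ValueError(f"tmm_factors needs counts, got unit {counts.unit!r}")
    X = counts.values.to_numpy(float)
    lib = X.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        bad = counts.sample_ids[zero].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if counts.n_samples == 1:
        warnings.warn("single sample: TMM factor set to 1", UserWarning)
        return NormalizationFactors(
            pd.Series([1.0], index=counts.sample_ids), reference=str(counts.sample_ids[0])
        )
    f75 = np.quantile(X / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = X[:, ref_idx]
    raw = np.array(
        [
            1.0
            if s == ref_idx
            else _tmm_pair(X[:, s], ref, lib[s], lib[ref_idx])
            for s in range(counts.n_samples)
        ]
    )
    raw = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(
        pd.Series(raw, index=counts.sample_ids),
        reference=str(counts.sample_ids[ref_idx]),
    )


def log_cpm(counts: ExpressionMatrix, factors: NormalizationFactors) -> ExpressionMatrix:
    """log2(CPM + 0.5) with effective (factor-scaled) library sizes."""
    if counts.unit != "counts":
        raise ValueError(f"log_cpm needs counts, got unit {counts.unit!r}")
    if not counts.sample_ids.equals(factors.factors.index):
        raise ValueError("sample sets of counts and factors do not match")
    X = counts.values.to_numpy(float)
    lib = X.sum(axis=0)
    eff = lib * factors.factors.to_numpy(float)
    cpm = X / eff * 1e6
    out = pd.DataFrame(
        np.log2(cpm + 0.5), index=counts.gene_ids, columns=counts.sample_ids
    )
    return ExpressionMatrix(out, cohort=counts.cohort, unit="logCPM")


def cpm(counts: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million using raw library sizes (no TMM factor)."""
    X = counts.values.to_numpy(float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = counts.sample_ids[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    return pd.DataFrame(X / lib * 1e6, index=counts.gene_ids, columns=counts.sample_ids)


def filter_low_expression(counts: ExpressionMatrix, cpm_threshold: float = 1.0) -> pd.Series:
    """Boolean keep-mask per gene for one cohort.

    A gene is discarded iff the number of samples with CPM below the
    threshold is strictly greater than half the cohort size ("less than
    1 CPM in more than half of the samples"). CPM uses raw library sizes.
    """
    if counts.n_samples == 0:
        raise ValueError(f"empty cohort {counts.cohort!r}")
    c = cpm(counts)
    n_low = (c.to_numpy() < cpm_threshold).sum(axis=1)
    keep = n_low <= counts.n_samples / 2.0
    return pd.Series(keep, index=counts.gene_ids, name="keep")


def zscore_rows(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Row-wise z-score of a feature-by-sample frame; constant rows map to 0."""
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    X = values.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    # rows constant up to rounding (sd of a few ulps) count as constant too
    scale = np.maximum(np.abs(X).max(axis=1, keepdims=True), 1e-300)
    const = (sd <= 1e-12 * scale).ravel()
    sd = np.where(const[:, None], 0.0, sd)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) mapped to z = 0", UserWarning
        )
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Z[const, :] = 0.0
    return pd.DataFrame(Z, index=values.index, columns=values.columns)


def zscore_within_cohort(x: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene (x − mean)/SD within the cohort, sample SD (ddof=1)."""
    if x.unit == "counts":
        raise ValueError("z-scoring raw counts is not meaningful; transform first")
    if x.n_samples < 2:
        raise ValueError(f"cohort {x.cohort!r} has fewer than 2 samples")
    return ExpressionMatrix(zscore_rows(x.values), cohort=x.cohort, unit="zscore")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    # convenience utility only; not validated against any array pipeline
    ranks = values.rank(axis=0, method="average")
    means = np.sort(values.to_numpy(float), axis=0).mean(axis=1)
    n = values.shape[0]
    interp = np.interp(ranks.to_numpy(), np.arange(1, n + 1), means)
    return pd.DataFrame(interp, index=values.index, columns=values.columns)
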