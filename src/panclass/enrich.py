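"""Single-sample gene-set enrichment (GSVA-style) and class comparisons.

Per gene, a cross-sample kernel CDF statistic is computed; per sample, genes
are ranked by that statistic and the ranks symmetrized about the midpoint; a
weighted Kolmogorov–Smirnov-like random walk over the ranked gene list gives
one enrichment score per (gene set, sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, poisson, rankdata
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix


@dataclass
class GeneSetCollection:
    """Named gene sets with a source label."""

    sets: dict[str, list[str]]
    source: str = ""

    def filtered(self, universe: pd.Index, min_size: int = 15, max_size: int = 500) -> "GeneSetCollection":
        """Intersect with the expression universe; keep sets of min..max genes."""
        out: dict[str, list[str]] = {}
        uni = set(universe)
        for name, genes in self.sets.items():
            inter = [g for g in dict.fromkeys(genes) if g in uni]
            if min_size <= len(inter) <= max_size:
                out[name] = inter
        return GeneSetCollection(out, source=self.source)


@dataclass
class EnrichmentMatrix:
    """Gene-set × sample enrichment scores plus the parameter record."""

    values: pd.DataFrame
    cohort: str = "cohort"
    params: dict = field(default_factory=dict)


def _kernel_cdf(X: np.ndarray, kernel: str) -> np.ndarray:
    """Cross-sample kernel CDF statistic per gene (rows of X)."""
    p, n = X.shape
    Z = np.empty_like(X, dtype=float)
    if kernel == "gaussian":
        sd = X.std(axis=1, ddof=1)
        h = np.maximum(sd / 4.0, 1e-12)  # zero-bandwidth guard for constant genes
        for g in range(p):
            d = (X[g][:, None] - X[g][None, :]) / h[g]
            Z[g] = norm.cdf(d).mean(axis=1)
    elif kernel == "poisson":
        for g in range(p):
            Z[g] = poisson.cdf(X[g][:, None], X[g][None, :] + 0.5).mean(axis=1)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return Z


def _walk_scores(
    Z: np.ndarray,
    masks: np.ndarray,
    tau: float,
    es_mode: str,
) -> np.ndarray:
    """Random-walk enrichment scores.

    Z: gene×sample kernel statistics; masks: set×gene booleans.
    Returns set×sample scores.
    """
    p, n = Z.shape
    m = masks.shape[0]
    out = np.empty((m, n))
    mid = (p + 1) / 2.0
    for s in range(n):
        z = Z[:, s]
        r = rankdata(z)  # average ranks for ties
        w = np.abs(r - mid) ** tau
        order = np.argsort(-z, kind="stable")  # walk from highest statistic down
        w_ord = w[order]
        for k in range(m):
            in_set = masks[k][order]
            size = int(in_set.sum())
            w_in = np.where(in_set, w_ord, 0.0)
            denom_in = w_in.sum()
            if denom_in == 0:
                # all weights zero (fully tied sample); walk undefined -> 0
                out[k, s] = 0.0
                continue
            inc = np.cumsum(w_in) / denom_in
            dec = np.cumsum(~in_set) / max(p - size, 1)
            nu = inc - dec
            if es_mode == "max_diff":
                out[k, s] = max(nu.max(), 0.0) + min(nu.min(), 0.0)
            elif es_mode == "max_abs":
                out[k, s] = nu[int(np.argmax(np.abs(nu)))]
            else:
                raise ValueError(f"unknown es_mode {es_mode!r}")
    return out


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    kernel: str = "gaussian",
    tau: float = 1.0,
    es_mode: str = "max_diff",
    min_size: int = 15,
    max_size: int = 500,
) -> EnrichmentMatrix:
    """Single-sample enrichment scores for every retained gene set.

    Sets are intersected with the matrix and kept if their intersection has
    between ``min_size`` and ``max_size`` genes (production defaults 15–500;
    relax for toy inputs). Sets with no genes in the matrix are dropped with
    a warning.
    """
    if expr.n_samples < 3:
        raise ValueError("kernel CDF needs at least 3 samples")
    empty = [
        name for name, genes in sets.sets.items()
        if not set(genes) & set(expr.gene_ids)
    ]
    if empty:
        warnings.warn(f"dropping {len(empty)} set(s) with no genes in matrix: {empty[:5]}", UserWarning)
    kept = sets.filtered(expr.gene_ids, min_size=min_size, max_size=max_size)
    if not kept.sets:
        raise ValueError("no gene sets retained after size filtering")
    X = expr.values.to_numpy(float)
    Z = _kernel_cdf(X, kernel)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    names = list(kept.sets)
    masks = np.zeros((len(names), expr.n_genes), dtype=bool)
    for k, name in enumerate(names):
        for g in kept.sets[name]:
            masks[k, gene_pos[g]] = True
    scores = _walk_scores(Z, masks, tau, es_mode)
    df = pd.DataFrame(scores, index=names, columns=expr.sample_ids)
    return EnrichmentMatrix(
        df,
        cohort=expr.cohort,
        params={"kernel": kernel, "tau": tau, "es_mode": es_mode,
                "min_size": min_size, "max_size": max_size},
    )


def enrichment_class_test(
    enrich: EnrichmentMatrix | pd.DataFrame,
    classes: pd.Series,
    min_per_class: int = 2,
) -> pd.DataFrame:
    """Two-sided rank-sum test of C2 vs C1 scores per gene set.

    ``classes`` maps sample id to "C1"/"C2"; samples without a class are
    ignored. Returns statistic, p, BH-adjusted p (within this cohort) and
    direction = sign(median C2 − median C1).
    """
    values = enrich.values if isinstance(enrich, EnrichmentMatrix) else enrich
    cohort = enrich.cohort if isinstance(enrich, EnrichmentMatrix) else "cohort"
    classes = classes.dropna()
    c1 = [s for s in values.columns if classes.get(s) == "C1"]
    c2 = [s for s in values.columns if classes.get(s) == "C2"]
    if len(c1) < min_per_class or len(c2) < min_per_class:
        raise ValueError(
            f"cohort {cohort!r}: need >= {min_per_class} samples per class "
            f"(got C1={len(c1)}, C2={len(c2)})"
        )
    rows = []
    for name in values.index:
        x1 = values.loc[name, c1].to_numpy(float)
        x2 = values.loc[name, c2].to_numpy(float)
        res = mannwhitneyu(x2, x1, alternative="two-sided")
        rows.append(
            {
                "feature": name,
                "statistic": res.statistic,
                "p": res.pvalue,
                "direction": float(np.sign(np.median(x2) - np.median(x1))),
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["cohort"] = cohort
    out["n_C1"] = len(c1)
    out["n_C2"] = len(c2)
    return out
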