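"""Nearest-centroid subtype calling with permutation-based confidence.

Each sample's panel-gene profile is correlated with every subtype centroid;
a permutation null (shuffling the sample's own panel values) yields a
p-value per subtype, BH-adjusted within the sample. A sample is *assigned*
iff its best-correlated subtype is the unique significant one, *ambiguous*
if several subtypes are significant, and *unassigned* otherwise. Assigned
LumA samples form class C1; assigned LumB/Her2e/Basal form C2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

DEFAULT_SUBTYPES = ("LumA", "LumB", "Her2e", "Basal")
#: subtypes mapped to class none (e.g. the published five-centroid variant)
NEUTRAL_SUBTYPES = frozenset({"Normal", "Normal-like"})

CLASS_OF_SUBTYPE = {
    "LumA": "C1",
    "LumB": "C2",
    "Her2e": "C2",
    "Basal": "C2",
}


@dataclass
class CentroidProfile:
    """Panel-gene × subtype matrix of reference values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate panel genes in centroid profile")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 subtypes")
        if self.values.isna().any().any():
            raise ValueError("centroid profile contains missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class SubtypeCall:
    """Per-sample classification outcome."""

    sample_id: str
    correlations: pd.Series
    p_values: pd.Series
    p_adjusted: pd.Series
    status: str  # assigned | ambiguous | unassigned
    subtype: str | None
    klass: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.status not in ("assigned", "ambiguous", "unassigned"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status != "assigned" and self.klass is not None:
            raise ValueError("non-assigned calls must have class none")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, np.nan, sd)
    return (X - mu) / sd


def _prepare(profile: pd.Series, centroids: CentroidProfile, method: str):
    """Align panel genes, optionally rank-transform, standardize centroids."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    common = centroids.gene_ids.intersection(profile.index)
    n_missing = len(centroids.gene_ids) - len(common)
    if len(common) < 3:
        raise ValueError("need at least 3 panel genes common to profile and centroids")
    if n_missing > 0.2 * len(centroids.gene_ids):
        warnings.warn(
            f"{n_missing}/{len(centroids.gene_ids)} panel genes missing from profile",
            UserWarning,
        )
    x = profile.loc[common].to_numpy(float)
    C = centroids.values.loc[common].to_numpy(float)
    if method == "spearman":
        x = rankdata(x)
        C = np.apply_along_axis(rankdata, 0, C)
    Cs = _standardize_rows(C.T)  # subtypes x genes
    return x, Cs, list(centroids.subtypes)


def centroid_correlations(
    profile: pd.Series, centroids: CentroidProfile, method: str = "spearman"
) -> pd.Series:
    """One correlation per subtype; spearman uses average ranks for ties.

    A constant profile has undefined correlation: all values are NaN and the
    caller must treat the sample as unassigned.
    """
    x, Cs, subtypes = _prepare(profile, centroids, method)
    p = x.size
    xs = _standardize_rows(x[None, :])[0]
    if np.isnan(xs).all():
        warnings.warn(f"constant profile {profile.name!r}: correlations undefined", UserWarning)
        return pd.Series(np.nan, index=subtypes, name=profile.name)
    r = Cs @ xs / p
    return pd.Series(r, index=subtypes, name=profile.name)


def _perm_matrix(x: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    P = np.tile(x, (B, 1))
    return rng.permuted(P, axis=1)


def permutation_confidence(
    profile: pd.Series,
    centroids: CentroidProfile,
    B: int = 10_000,
    alpha: float = 0.01,
    method: str = "spearman",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> SubtypeCall:
    """Subtype call with permutation p-values for one sample.

    The null shuffles the sample's panel values across genes, destroying the
    gene–centroid matching while preserving the value distribution. For
    subtype k, p = (1 + #{permuted correlations ≥ observed_k}) / (B + 1);
    with ``exhaustive=True`` all p! permutations are enumerated instead
    (panels of ≤ 8 genes only).
    """
    if not exhaustive and B < 100:
        raise ValueError("B must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    name = str(profile.name) if profile.name is not None else "sample"
    x, Cs, subtypes = _prepare(profile, centroids, method)
    p = x.size
    xs = _standardize_rows(x[None, :])[0]
    if np.isnan(xs).all() or np.isnan(Cs).any():
        warnings.warn(f"degenerate profile/centroids for {name!r}: unassigned", UserWarning)
        nan = pd.Series(np.nan, index=subtypes)
        return SubtypeCall(name, nan, pd.Series(1.0, index=subtypes),
                           pd.Series(1.0, index=subtypes), "unassigned", None)
    obs = Cs @ xs / p

    if exhaustive:
        if p > 8:
            raise ValueError("exhaustive enumeration limited to panels of <= 8 genes")
        P = np.array(list(_iter_permutations(xs)))
        n_perm = P.shape[0]
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        P = _perm_matrix(xs, B, rng)
        n_perm = B
    perm_r = P @ Cs.T / p  # n_perm x K
    # tolerance so exact ties (e.g. the identity permutation) count as >=
    ge = perm_r >= obs[None, :] - 1e-9
    pvals = (1.0 + ge.sum(axis=0)) / (n_perm + 1.0)

    padj = multipletests(pvals, method="fdr_bh")[1]
    sig = padj < alpha
    best = int(np.argmax(obs))
    if np.sum(obs == obs[best]) > 1:
        warnings.warn(f"correlation tie for sample {name!r}; lowest subtype index wins", UserWarning)
    n_sig = int(sig.sum())
    if n_sig == 0:
        status, subtype = "unassigned", None
    elif n_sig == 1 and sig[best]:
        status, subtype = "assigned", subtypes[best]
    elif n_sig == 1:
        # significant subtype is not the best-correlated one
        status, subtype = "unassigned", None
    else:
        status, subtype = "ambiguous", None
    return SubtypeCall(
        sample_id=name,
        correlations=pd.Series(obs, index=subtypes),
        p_values=pd.Series(pvals, index=subtypes),
        p_adjusted=pd.Series(padj, index=subtypes),
        status=status,
        subtype=subtype,
    )


def assign_classes(calls: list[SubtypeCall]) -> tuple[list[SubtypeCall], float]:
    """Fill the C1/C2 class of assigned calls; returns (calls, unassigned fraction).

    Assigned LumA → C1; assigned LumB/Her2e/Basal → C2; Normal-like and all
    non-assigned statuses → class none.
    """
    n_not_assigned = 0
    for call in calls:
        if call.status != "assigned":
            call.klass = None
            n_not_assigned += 1
            continue
        st = call.subtype
        if st in CLASS_OF_SUBTYPE:
            call.klass = CLASS_OF_SUBTYPE[st]
        elif st in NEUTRAL_SUBTYPES:
            call.klass = None
        else:
            raise ValueError(f"unknown subtype name {st!r}")
    frac = n_not_assigned / len(calls) if calls else math.nan
    return calls, frac


def median_center_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-gene median across the cohort's samples."""
    return values.sub(values.median(axis=1), axis=0)


def classify_cohort(
    expr: ExpressionMatrix,
    centroids: CentroidProfile,
    B: int = 10_000,
    alpha: float = 0.01,
    method: str = "spearman",
    seed: int | None = None,
    median_center: bool = True,
) -> pd.DataFrame:
    """Classify every sample of a cohort; returns a tidy calls table.

    Panel genes are median-centered within the cohort before correlation
    (standard practice for cross-platform nearest-centroid use). Each sample
    gets an independent child seed, so calls do not depend on sample order.
    """
    panel = centroids.gene_ids.intersection(expr.gene_ids)
    vals = expr.values.loc[panel]
    if median_center:
        vals = median_center_rows(vals)
    seeds = np.random.SeedSequence(seed).spawn(expr.n_samples)
    calls = []
    for i, s in enumerate(expr.sample_ids):
        call = permutation_confidence(
            vals[s], centroids, B=B, alpha=alpha, method=method,
            rng=np.random.default_rng(seeds[i]),
        )
        calls.append(call)
    calls, unassigned_frac = assign_classes(calls)
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "cohort": expr.cohort, "status": c.status,
               "subtype": c.subtype, "class": c.klass}
        for st in centroids.subtypes:
            row[f"r_{st}"] = c.correlations[st]
            row[f"p_{st}"] = c.p_values[st]
            row[f"padj_{st}"] = c.p_adjusted[st]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["unassigned_fraction"] = unassigned_frac
    return out
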