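"""Per-cohort differential expression (moderated t) and cross-cohort consistency.

Each cohort with at least 8 samples per class gets a per-gene two-group
linear model on logCPM with empirical-Bayes variance moderation; features
significant (BH-adjusted p < 0.05) and concordant (C2 > C1) in at least
``min_cohorts`` cohorts form the core list, and those passing in more than
half the cohorts form the broad list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

_trigamma = lambda x: polygamma(1, x)  # noqa: E731
_tetragamma = lambda x: polygamma(2, x)  # noqa: E731


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / _tetragamma(x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of (d0, s0²) to sample variances on the log scale.

    Models s² ~ s0² F(df, d0): with z = log s², E z = log s0² + ψ(df/2) −
    log(df/2) − ψ(d0/2) + log(d0/2) and Var z = ψ'(df/2) + ψ'(d0/2).
    Returns (d0, s0²); d0 = inf when the log-variances show no excess spread.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive sample variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0


def moderated_de(
    logcpm: ExpressionMatrix | pd.DataFrame,
    classes: pd.Series,
    min_per_class: int = 8,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group comparison (C2 − C1) per gene.

    ``classes`` maps sample id to "C1"/"C2". ``prior_df`` overrides the
    fitted prior degrees of freedom d0 (0 recovers ordinary t statistics).
    Returns a gene-indexed frame with lfc, t, p, p_adj, direction.
    """
    values = logcpm.values if isinstance(logcpm, ExpressionMatrix) else logcpm
    cohort = logcpm.cohort if isinstance(logcpm, ExpressionMatrix) else "cohort"
    classes = classes.dropna()
    c1 = [s for s in values.columns if classes.get(s) == "C1"]
    c2 = [s for s in values.columns if classes.get(s) == "C2"]
    n1, n2 = len(c1), len(c2)
    if n1 < min_per_class or n2 < min_per_class:
        raise ValueError(
            f"cohort {cohort!r}: need >= {min_per_class} samples per class "
            f"(got C1={n1}, C2={n2})"
        )
    X1 = values[c1].to_numpy(float)
    X2 = values[c2].to_numpy(float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    if np.all(s2 == 0):
        raise ValueError("zero within-group variance for every gene")

    if prior_df is None:
        d0, s0 = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0 = fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    lfc = m2 - m1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm as _norm

        p = 2.0 * _norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "t": t,
            "p": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
            "direction": np.sign(lfc),
        },
        index=values.index,
    )
    out.attrs.update(
        {"cohort": cohort, "n_C1": n1, "n_C2": n2, "d0": d0,
         "method": "moderated-t on logCPM (voom weights not reproduced)"}
    )
    return out


def cross_cohort_consistency(
    results: dict[str, pd.DataFrame],
    min_cohorts: int = 30,
    require_direction: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count, per feature, the cohorts where it is significant (and concordant).

    Each value of ``results`` must be a feature-indexed frame with columns
    ``p_adj`` and ``direction`` over a common feature universe. A feature is
    *core* when it passes adjusted p < alpha (and, if required, direction
    C2 > C1) in at least ``min_cohorts`` cohorts, and *broad* when it passes
    in more than half of them.
    """
    if not results:
        raise ValueError("need at least one eligible cohort")
    names = list(results)
    universe = results[names[0]].index
    offenders = [n for n in names if not results[n].index.equals(universe)]
    if offenders:
        raise ValueError(f"inconsistent feature universes in cohorts: {offenders}")
    n_cohorts = len(names)
    hits = np.zeros(len(universe), dtype=int)
    dir_sum = np.zeros(len(universe))
    for n in names:
        df = results[n]
        ok = df["p_adj"].to_numpy() < alpha
        if require_direction:
            ok &= df["direction"].to_numpy() > 0
        hits += ok.astype(int)
        dir_sum += np.where(ok, df["direction"].to_numpy(), 0.0)
    out = pd.DataFrame(
        {
            "n_cohorts": n_cohorts,
            "n_significant": hits,
            "direction": np.sign(dir_sum),
            "is_core": hits >= min_cohorts,
            "is_broad": hits > n_cohorts / 2.0,
        },
        index=universe,
    )
    out.attrs.update(
        {"min_cohorts": min_cohorts, "alpha": alpha,
         "require_direction": require_direction}
    )
    return out
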