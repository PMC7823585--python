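"""Prognostic evaluation: Cox models, the random-gene V-score null, and
class × immune-infiltrate interaction with deviance comparison.

The univariate Cox fit is a direct Newton solve of the partial likelihood
(Efron tie handling) — thousands of replicate fits are needed for the
V-score, so per-fit overhead matters. The multi-covariate interaction model
delegates to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .preprocess import ExpressionMatrix, zscore_rows


@dataclass
class CoxFit:
    """Univariate Cox fit summary (covariate effect per unit)."""

    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    log_likelihood: float
    converged: bool = True
    warning: str | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci(self) -> tuple[float, float]:
        d = 1.959963984540054 * self.se
        return (float(np.exp(self.log_hr - d)), float(np.exp(self.log_hr + d)))


@dataclass
class VScoreResult:
    observed_log_hr: float
    observed_p: float
    n_replicates: int
    v_score: float
    seed: int
    n_failures: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def observed_hr(self) -> float:
        return float(np.exp(self.observed_log_hr))


def _cox_newton(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> CoxFit:
    """Newton fit of a single-covariate Cox partial likelihood (Efron ties)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    x, time, event = x[order], time[order], event[order]
    n = x.size
    n_events = int(event.sum())

    # group boundaries over distinct times (time is sorted descending)
    starts = np.flatnonzero(np.r_[True, time[1:] != time[:-1]])
    ends = np.r_[starts[1:], n] - 1
    ev = event.astype(float)
    d_per_group = np.add.reduceat(ev, starts)
    has_death = d_per_group > 0
    sum_xd_total = float((ev * x).sum())
    x2 = x * x

    def fgh(beta: float) -> tuple[float, float, float]:
        theta = np.exp(beta * x)
        A = np.cumsum(theta)[ends]
        B = np.cumsum(theta * x)[ends]
        C = np.cumsum(theta * x2)[ends]
        a = np.add.reduceat(ev * theta, starts)
        b = np.add.reduceat(ev * theta * x, starts)
        c = np.add.reduceat(ev * theta * x2, starts)
        ll = beta * sum_xd_total
        grad = sum_xd_total
        hess = 0.0
        d = d_per_group[has_death]
        A_, B_, C_ = A[has_death], B[has_death], C[has_death]
        a_, b_, c_ = a[has_death], b[has_death], c[has_death]
        singles = d == 1
        if singles.any():
            den = A_[singles]
            m1 = B_[singles] / den
            ll -= float(np.log(den).sum())
            grad -= float(m1.sum())
            hess -= float((C_[singles] / den - m1**2).sum())
        multi = np.flatnonzero(~singles)
        for k in multi:  # Efron correction for tied deaths (rare path)
            dk = int(d[k])
            f = np.arange(dk) / dk
            den = A_[k] - f * a_[k]
            m1 = (B_[k] - f * b_[k]) / den
            m2 = (C_[k] - f * c_[k]) / den
            ll -= float(np.log(den).sum())
            grad -= float(m1.sum())
            hess -= float((m2 - m1**2).sum())
        return ll, grad, hess

    beta = 0.0
    converged = False
    warn_msg = None
    ll = np.nan
    for _ in range(max_iter):
        ll, g, h = fgh(beta)
        if h >= 0:  # degenerate information
            break
        step = -g / h
        beta_new = beta + step
        if abs(beta_new) > 50:
            warn_msg = "monotone likelihood (complete separation?)"
            beta = beta_new
            break
        beta = beta_new
        if abs(step) < tol:
            converged = True
            break
    ll, g, h = fgh(beta)
    if h < 0:
        se = float(np.sqrt(-1.0 / h))
    else:
        se = np.inf
        warn_msg = warn_msg or "non-identifiable covariate"
    if warn_msg:
        warnings.warn(warn_msg, UserWarning)
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * norm.sf(abs(z)))
    return CoxFit(
        log_hr=float(beta), se=se, p=p, n=n, n_events=n_events,
        log_likelihood=float(ll), converged=converged, warning=warn_msg,
    )


def cox_class_model(records: pd.DataFrame, min_events: int = 10) -> CoxFit:
    """Univariate Cox fit of survival on the C1/C2 class (HR is C2 vs C1).

    ``records`` needs columns time, event, class (values "C1"/"C2").
    """
    df = records.dropna(subset=["time", "event", "class"])
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    classes = set(df["class"])
    if not {"C1", "C2"} <= classes:
        raise ValueError(f"both classes required, got {sorted(classes)}")
    n_events = int(df["event"].sum())
    if n_events < min_events:
        raise ValueError(f"cohort has {n_events} events; needs >= {min_events}")
    x = (df["class"] == "C2").to_numpy(float)
    return _cox_newton(x, df["time"].to_numpy(float), df["event"].to_numpy(int))


def random_gene_classification(
    expr: ExpressionMatrix | pd.DataFrame,
    n_genes: int = 50,
    n_target: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 10,
) -> pd.Series:
    """Binary labels from a random gene set: PC1 median split, then subsample.

    ``n_genes`` genes are drawn without replacement, z-scored per gene, and
    the samples' first principal component is split at its median (ties go to
    the low side); the labelled set is then subsampled without replacement to
    ``n_target`` samples. PC1 polarity is fixed by forcing the largest-loading
    gene's loading positive.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if rng is None:
        rng = np.random.default_rng(seed)
    p, n = values.shape
    if p < n_genes:
        raise ValueError(f"matrix has {p} genes; needs >= {n_genes}")
    if n_target is None:
        n_target = n
    if n_target > n:
        raise ValueError("n_target exceeds the number of samples")
    for _ in range(max_retries):
        pick = rng.choice(p, size=n_genes, replace=False)
        Z = zscore_rows(values.iloc[pick]).to_numpy(float)  # genes x samples
        M = Z.T  # samples x genes, columns already mean 0
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        if S[0] <= 1e-12:
            continue  # constant PC1: resample genes
        v = Vt[0]
        if v[int(np.argmax(np.abs(v)))] < 0:
            v = -v
        pc1 = M @ v
        med = np.median(pc1)
        labels = (pc1 > med).astype(int)  # exactly at the median -> low side
        keep = np.sort(rng.choice(n, size=n_target, replace=False))
        return pd.Series(labels[keep], index=values.columns[keep], name="random_class")
    raise RuntimeError("constant PC1 after repeated gene resampling")


def replicate_rng(seed: int, i: int) -> np.random.Generator:
    """Deterministic per-replicate generator (the V-score seeding contract)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def v_score(
    expr: ExpressionMatrix | pd.DataFrame,
    records: pd.DataFrame,
    observed: CoxFit | tuple[float, float],
    R: int = 5000,
    seed: int = 0,
    n_genes: int = 50,
) -> VScoreResult:
    """Proportion of random-gene classifications outperforming the observed fit.

    A replicate outperforms when |log HR| is strictly larger *and* its p-value
    strictly smaller than observed. Replicate Cox failures count as
    non-outperforming and are tallied.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if isinstance(observed, CoxFit):
        obs_abs_loghr, obs_p = abs(observed.log_hr), observed.p
    else:
        hr, obs_p = observed
        obs_abs_loghr = abs(float(np.log(hr)))
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    rec = records.set_index("sample_id") if "sample_id" in records.columns else records
    common = [s for s in values.columns if s in rec.index]
    values = values[common]
    rec = rec.loc[common]
    n_target = rec["class"].isin(["C1", "C2"]).sum() if "class" in rec.columns else len(common)

    wins = 0
    failures = 0
    for i in range(R):
        rng = replicate_rng(seed, i)
        try:
            labels = random_gene_classification(
                values, n_genes=n_genes, n_target=int(n_target), rng=rng
            )
            sub = rec.loc[labels.index]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = _cox_newton(
                    labels.to_numpy(float),
                    sub["time"].to_numpy(float),
                    sub["event"].to_numpy(int),
                )
            if not np.isfinite(fit.log_hr) or not np.isfinite(fit.p):
                failures += 1
                continue
            if abs(fit.log_hr) > obs_abs_loghr and fit.p < obs_p:
                wins += 1
        except Exception:
            failures += 1
    return VScoreResult(
        observed_log_hr=float(obs_abs_loghr),
        observed_p=float(obs_p),
        n_replicates=R,
        v_score=wins / R,
        seed=seed,
        n_failures=failures,
        diagnostics={"n_target": int(n_target), "n_genes": n_genes},
    )


def infiltrate_interaction(
    records: pd.DataFrame,
    cell_type: str,
    min_events: int = 10,
) -> dict:
    """Cox model with class, dichotomized infiltrate, and their interaction.

    The infiltrate fraction is split high/low at the within-cohort median
    (ties to low). Returns the interaction Wald p, the likelihood-ratio
    (deviance) p of the complete model against the infiltrate-only model,
    and per-class HRs for the infiltrate effect.
    """
    from lifelines import CoxPHFitter

    df = records.dropna(subset=["time", "event", "class", cell_type]).copy()
    if df.empty:
        raise ValueError("no usable records")
    for cls in ("C1", "C2"):
        stratum = df[df["class"] == cls]
        if stratum.empty:
            raise ValueError(f"empty stratum: class {cls}")
        if stratum["event"].sum() < min_events:
            warnings.warn(
                f"class {cls} has {int(stratum['event'].sum())} events (< {min_events})",
                UserWarning,
            )
    med = df[cell_type].median()
    df["inf_high"] = (df[cell_type] > med).astype(float)
    df["class2"] = (df["class"] == "C2").astype(float)
    df["interaction"] = df["inf_high"] * df["class2"]

    full = CoxPHFitter()
    full.fit(df[["time", "event", "class2", "inf_high", "interaction"]],
             duration_col="time", event_col="event")
    reduced = CoxPHFitter()
    reduced.fit(df[["time", "event", "inf_high"]], duration_col="time", event_col="event")

    deviance = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    deviance = max(float(deviance), 0.0)
    dev_p = float(chi2.sf(deviance, df=2))

    per_class = {}
    for cls in ("C1", "C2"):
        stratum = df[df["class"] == cls]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = _cox_newton(
                stratum["inf_high"].to_numpy(float),
                stratum["time"].to_numpy(float),
                stratum["event"].to_numpy(int),
            )
        per_class[cls] = {"hr": fit.hr, "p": fit.p, "log_hr": fit.log_hr}

    return {
        "cell_type": cell_type,
        "interaction_p": float(full.summary.loc["interaction", "p"]),
        "interaction_coef": float(full.summary.loc["interaction", "coef"]),
        "deviance": deviance,
        "deviance_p": dev_p,
        "per_class_hr": per_class,
        "threshold": float(med),
    }
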