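"""Per-drug, per-cohort linear models of lnIC50 on class with diagnostic gates.

For each drug within a cohort, lnIC50 is modelled as a two-group linear model
on class (equivalent to the equal-variance t-test); residual normality
(Shapiro–Wilk) and variance homogeneity (Levene) are checked, p-values are
BH-adjusted within the cohort, and a drug is flagged only when it passes all
three gates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import levene, shapiro, ttest_ind
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("cell_line", "cohort", "drug", "lnIC50")


def drug_class_scan(
    responses: pd.DataFrame,
    classes: pd.Series,
    alpha: float = 0.01,
    nominal: bool = False,
    diag_alpha: float = 0.05,
    levene_center: str = "median",
    min_per_class: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every (cohort, drug) pair for a class effect on lnIC50.

    ``classes`` maps cell line id to "C1"/"C2". The significance gate uses the
    BH-adjusted model p by default; ``nominal=True`` gates on the raw p
    instead. Returns (per-drug table, per-cohort direction summary); the
    summary counts flagged drugs with higher lnIC50 in C2 (C2-resistant) and
    in C1.
    """
    missing = set(REQUIRED_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    if levene_center not in ("median", "mean"):
        raise ValueError("levene_center must be 'median' or 'mean'")
    dup = responses.duplicated(subset=["cell_line", "drug"])
    if dup.any():
        raise ValueError("duplicate (cell line, drug) records")
    classes = classes.dropna()

    rows = []
    for (cohort, drug), grp in responses.groupby(["cohort", "drug"], sort=True):
        cls = grp["cell_line"].map(classes)
        y1 = grp.loc[cls == "C1", "lnIC50"].to_numpy(float)
        y2 = grp.loc[cls == "C2", "lnIC50"].to_numpy(float)
        if len(y1) < min_per_class or len(y2) < min_per_class:
            rows.append(
                {"cohort": cohort, "drug": drug, "n_C1": len(y1), "n_C2": len(y2),
                 "effect": np.nan, "p": np.nan, "shapiro_p": np.nan,
                 "levene_p": np.nan, "skipped": "fewer than "
                 f"{min_per_class} lines in a class"}
            )
            continue
        t = ttest_ind(y2, y1, equal_var=True)
        resid = np.concatenate([y1 - y1.mean(), y2 - y2.mean()])
        if np.ptp(resid) == 0:
            sw_p = np.nan
        else:
            sw_p = float(shapiro(resid).pvalue)
        lev_p = float(levene(y1, y2, center=levene_center).pvalue)
        rows.append(
            {"cohort": cohort, "drug": drug, "n_C1": len(y1), "n_C2": len(y2),
             "effect": float(y2.mean() - y1.mean()), "p": float(t.pvalue),
             "shapiro_p": sw_p, "levene_p": lev_p, "skipped": ""}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no (cohort, drug) pairs to analyze")

    out["p_adj"] = np.nan
    for cohort, idx in out.groupby("cohort").groups.items():
        sub = out.loc[idx]
        ok = sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "p_adj"] = multipletests(
                sub.loc[ok, "p"].to_numpy(), method="fdr_bh"
            )[1]

    gate_p = out["p"] if nominal else out["p_adj"]
    out["significant"] = (
        (gate_p < alpha)
        & (out["shapiro_p"] > diag_alpha)
        & (out["levene_p"] > diag_alpha)
    ).fillna(False)

    sig = out[out["significant"]]
    summary = (
        pd.DataFrame(
            {
                "n_significant": sig.groupby("cohort").size(),
                "n_C2_resistant": sig[sig["effect"] > 0].groupby("cohort").size(),
                "n_C1_resistant": sig[sig["effect"] < 0].groupby("cohort").size(),
            }
        )
        .reindex(out["cohort"].unique())
        .fillna(0)
        .astype(int)
    )
    summary.index.name = "cohort"
    return out, summary
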