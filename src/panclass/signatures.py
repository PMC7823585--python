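"""Signature scoring and tumor–normal paired differences.

Two scoring modes: ``mean_z`` — the per-sample average of z-scored feature
values over the signature; ``ca20`` — the per-sample *sum* of expression
values centered by the cohort-wide median and scaled by the cohort-wide SD
(both computed over all values of all genes in the cohort). Paired
differences are D = V_tumor − V_normal per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

SCORING_MODES = ("mean_z", "ca20")


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    mode: str = "mean_z"

    def __post_init__(self) -> None:
        if self.mode not in SCORING_MODES:
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if len(self.genes) < 1:
            raise ValueError(f"signature {self.name!r} has no genes")

    def resolve(self, universe: pd.Index) -> "GeneSignature":
        """Drop genes missing from the matrix (with a warning)."""
        present = [g for g in self.genes if g in set(universe)]
        missing = len(self.genes) - len(present)
        if missing:
            warnings.warn(
                f"signature {self.name!r}: {missing} gene(s) not in matrix, dropped",
                UserWarning,
            )
        if not present:
            raise ValueError(f"signature {self.name!r}: no genes left after intersection")
        return GeneSignature(self.name, present, self.mode)


def signature_value(z: ExpressionMatrix | pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Mean of z-scored feature values over the signature, per sample."""
    if sig.mode != "mean_z":
        raise ValueError(f"signature {sig.name!r} is not a mean_z signature")
    if isinstance(z, ExpressionMatrix):
        if z.unit != "zscore":
            raise ValueError("signature_value expects z-scored input (unit 'zscore')")
        values = z.values
    else:
        values = z
    sig = sig.resolve(values.index)
    v = values.loc[sig.genes].mean(axis=0)
    v.name = sig.name
    return v


def ca20_value(expr: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Sum of cohort-standardized expression over signature genes, per sample.

    The centering median m and scaling SD σ are computed over *all* values
    of *all* genes in the cohort matrix, not per gene.
    """
    if sig.mode != "ca20":
        raise ValueError(f"signature {sig.name!r} is not a ca20 signature")
    sig = sig.resolve(expr.gene_ids)
    flat = expr.values.to_numpy(float).ravel()
    m = float(np.median(flat))
    sigma = float(np.std(flat, ddof=1))
    if sigma == 0:
        raise ValueError("cohort-wide SD is zero; CA20 score undefined")
    v = ((expr.values.loc[sig.genes] - m) / sigma).sum(axis=0)
    v.name = sig.name
    return v


def paired_difference(scores: pd.Series, pairing: pd.DataFrame) -> pd.Series:
    """D = V_tumor − V_normal per participant.

    ``pairing`` needs columns sample_id, participant_id, is_tumor (bool/0-1).
    Participants lacking either member are skipped with a warning.
    """
    required = {"sample_id", "participant_id", "is_tumor"}
    if not required <= set(pairing.columns):
        raise ValueError(f"pairing table needs columns {sorted(required)}")
    diffs = {}
    skipped = []
    for pid, grp in pairing.groupby("participant_id"):
        tum = grp.loc[grp["is_tumor"].astype(bool), "sample_id"]
        nor = grp.loc[~grp["is_tumor"].astype(bool), "sample_id"]
        t = [s for s in tum if s in scores.index]
        n = [s for s in nor if s in scores.index]
        if len(t) == 1 and len(n) == 1:
            diffs[pid] = float(scores[t[0]] - scores[n[0]])
        elif len(t) > 1 or len(n) > 1:
            raise ValueError(f"participant {pid!r} has multiple tumor or normal samples")
        else:
            skipped.append(pid)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} participant(s) missing a pair member", UserWarning)
    out = pd.Series(diffs, name=scores.name)
    out.index.name = "participant_id"
    return out


def class_signature_test(
    values: pd.Series,
    classes: pd.Series,
    min_per_class: int = 2,
) -> dict:
    """Two-sided rank-sum comparison of C1 vs C2 values (unpaired).

    C1 and C2 are independent groups, so the unpaired test is used even
    though some sources describe a signed-rank test for this contrast.
    """
    classes = classes.dropna()
    x1 = values[[s for s in values.index if classes.get(s) == "C1"]].to_numpy(float)
    x2 = values[[s for s in values.index if classes.get(s) == "C2"]].to_numpy(float)
    if len(x1) < min_per_class or len(x2) < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} observations per class (got {len(x1)}, {len(x2)})"
        )
    res = mannwhitneyu(x2, x1, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "direction": float(np.sign(np.median(x2) - np.median(x1))),
        "n_C1": len(x1),
        "n_C2": len(x2),
    }


def paired_signed_rank_test(differences: pd.Series) -> dict:
    """Exact-when-possible one-sample Wilcoxon signed-rank test of D against 0."""
    d = differences.to_numpy(float)
    d = d[d != 0]
    if d.size == 0:
        return {"statistic": np.nan, "p": 1.0, "n": 0}
    res = wilcoxon(d, alternative="two-sided", mode="exact" if d.size <= 25 else "approx")
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "n": int(d.size)}


def adjust_within_groups(p: pd.Series, groups: pd.Series) -> pd.Series:
    """BH adjustment applied separately within each grouping label."""
    out = pd.Series(np.nan, index=p.index)
    for _, idx in p.groupby(groups).groups.items():
        out.loc[idx] = multipletests(p.loc[idx].to_numpy(), method="fdr_bh")[1]
    return out


def bundled_signature(name: str) -> GeneSignature:
    """Load one of the signatures shipped with the package.

    ``tp53`` and ``esc`` carry real gene lists; ``proliferation``, ``ca20``
    and ``rb`` are placeholders (cited lists not reprinted) and raise.
    """
    from .io import read_signature_file

    ref = resources.files("panclass").joinpath(f"data/signatures/{name}.txt")
    with resources.as_file(ref) as path:
        return read_signature_file(path)
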