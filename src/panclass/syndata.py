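"""Synthetic multi-cohort RNA-seq data with the structure the pipeline assumes.

Counts are negative binomial around gene/cohort/library-specific means; a
~50-gene panel follows one of four subtype centroids, a core gene module is
upregulated in the class-2 latent group (LumB/Her2e/Basal), optional paired
normal samples lack both effects, survival is exponential with a class
effect, lnIC50 is normal with a class shift, and infiltrate fractions are
Dirichlet with an optional class-dependent hazard effect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classify import DEFAULT_SUBTYPES, CentroidProfile
from .preprocess import ExpressionMatrix


@dataclass
class SimConfig:
    """Parameters of one synthetic multi-cohort dataset."""

    n_cohorts: int = 3
    samples_per_cohort: int = 60
    n_genes: int = 500
    n_panel_genes: int = 50
    n_core_genes: int = 30
    subtype_proportions: tuple[float, float, float, float] = (0.5, 0.2, 0.15, 0.15)
    centroid_separation: float = 1.0
    core_effect: float = 1.0
    nb_dispersion: float = 0.1
    paired_normal_fraction: float = 0.0
    survival_log_hr: float = 0.7
    censoring_rate: float = 0.3
    drug_effect: float = -1.0
    seed: int = 0
    # plumbing knobs beyond the minimal contract
    n_drugs: int = 10
    n_cell_types: int = 3
    library_cv: float = 0.3
    cohort_effect_sd: float = 0.3
    baseline_hazard: float = 0.1
    infiltrate_log_hr: tuple[float, float] = (0.0, 0.0)  # (class 1, class 2), first cell type

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "samples_per_cohort", "n_genes", "n_panel_genes",
                     "n_core_genes", "n_drugs", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        props = np.asarray(self.subtype_proportions, float)
        if props.size != 4 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("subtype_proportions must be 4 non-negative values summing to 1")
        if self.n_panel_genes + self.n_core_genes > self.n_genes:
            raise ValueError("panel and core gene roles overlap: n_panel + n_core > n_genes")
        if self.nb_dispersion <= 0 or not np.isfinite(self.nb_dispersion):
            raise ValueError("nb_dispersion must be finite and positive")
        if not 0.0 <= self.paired_normal_fraction <= 1.0:
            raise ValueError("paired_normal_fraction must be in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.centroid_separation < 0:
            raise ValueError("centroid_separation must be non-negative")
        if self.baseline_hazard <= 0 or self.library_cv < 0 or self.cohort_effect_sd < 0:
            raise ValueError("scale parameters must be positive")


@dataclass
class SimulatedData:
    """Everything :func:`generate_dataset` produces."""

    config: SimConfig
    cohorts: dict[str, ExpressionMatrix]
    truth: pd.DataFrame
    clinical: pd.DataFrame
    drugs: pd.DataFrame
    centroids: CentroidProfile
    baseline_means: pd.Series
    cohort_factors: pd.DataFrame  # gene x cohort multipliers
    library_factors: pd.Series  # per sample


def generate_centroids(n_panel_genes: int, separation: float, seed: int = 0) -> CentroidProfile:
    """Panel-gene × 4 log2-scale centroid matrix.

    A shared "proliferation block" (40% of the panel) is elevated in
    LumB/Her2e/Basal and depressed in LumA, so the C1/C2 contrast is
    realizable; each subtype additionally gets a private block so the three
    class-2 centroids stay mutually near-orthogonal. ``separation = 0`` gives
    four identical columns.
    """
    if n_panel_genes < 2:
        raise ValueError("need at least 2 panel genes")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    p = n_panel_genes
    C = np.zeros((p, 4))
    n_block = max(p * 2 // 5, 1)
    priv_sizes = np.full(4, (p - n_block) // 4)
    start = n_block
    block = slice(0, n_block)
    C[block, 0] = -separation
    C[block, 1:] = separation
    for k in range(4):
        sl = slice(start, start + priv_sizes[k])
        C[sl, :] -= 0.5 * separation
        C[sl, k] += 2.0 * separation
        start += priv_sizes[k]
    # small jitter keeps columns distinct gene-wise without moving the geometry
    C += 0.05 * separation * rng.standard_normal(C.shape)
    genes = [f"panel_{i:03d}" for i in range(p)]
    return CentroidProfile(pd.DataFrame(C, index=genes, columns=list(DEFAULT_SUBTYPES)))


def _censoring_horizon(rate: float, lam: float) -> float:
    """T_max of uniform censoring giving overall censoring ≈ rate at hazard lam."""
    # P(censored) = E[exp(-lam * C)] = (1 - exp(-u)) / u with u = lam * T_max
    f = lambda u: (1.0 - np.exp(-u)) / u - rate  # noqa: E731
    u = brentq(f, 1e-9, 1e9)
    return u / lam


def generate_dataset(config: SimConfig) -> SimulatedData:
    """Simulate counts, truth, clinical and drug tables for every cohort."""
    rng = np.random.default_rng(config.seed)
    p, n = config.n_genes, config.samples_per_cohort
    genes = (
        [f"panel_{i:03d}" for i in range(config.n_panel_genes)]
        + [f"core_{i:03d}" for i in range(config.n_core_genes)]
        + [f"bg_{i:04d}" for i in range(p - config.n_panel_genes - config.n_core_genes)]
    )
    panel_idx = np.arange(config.n_panel_genes)
    core_idx = np.arange(config.n_panel_genes, config.n_panel_genes + config.n_core_genes)

    centroids = generate_centroids(
        config.n_panel_genes, config.centroid_separation, seed=config.seed
    )
    base = 2.0 ** rng.uniform(5.0, 9.0, size=p)  # ~32..512 expected counts
    sigma_lib = float(np.sqrt(np.log1p(config.library_cv**2)))
    r = 1.0 / config.nb_dispersion  # Var = mu + phi mu^2

    cohorts: dict[str, ExpressionMatrix] = {}
    truth_rows, clin_rows, drug_rows = [], [], []
    cohort_factors = {}
    lib_factors = {}
    drug_base = rng.normal(0.0, 1.0, size=config.n_drugs)
    subtypes = np.asarray(DEFAULT_SUBTYPES)
    props = np.asarray(config.subtype_proportions, float)
    inf_hr = np.asarray(config.infiltrate_log_hr, float)

    for c in range(config.n_cohorts):
        cid = f"cohort{c:02d}"
        cf = rng.lognormal(mean=0.0, sigma=config.cohort_effect_sd, size=p)
        cohort_factors[cid] = cf
        sub_idx = rng.choice(4, size=n, p=props)
        klass = np.where(sub_idx == 0, 1, 2)  # class 1 iff LumA
        n_paired = int(round(config.paired_normal_fraction * n))
        paired = rng.choice(n, size=n_paired, replace=False) if n_paired else np.array([], int)

        sample_ids = [f"{cid}_s{i:03d}" for i in range(n)]
        normal_ids = [f"{cid}_n{i:03d}" for i in paired]
        all_ids = sample_ids + normal_ids
        libf = rng.lognormal(mean=-(sigma_lib**2) / 2.0, sigma=sigma_lib, size=len(all_ids))
        for sid, lf in zip(all_ids, libf):
            lib_factors[sid] = lf

        # log2 effect matrix: genes x samples (tumors then normals)
        eff = np.zeros((p, len(all_ids)))
        Cvals = centroids.values.to_numpy()
        for i in range(n):
            eff[panel_idx, i] = Cvals[:, sub_idx[i]]
            if klass[i] == 2:
                eff[core_idx, i] += config.core_effect
        # normals: no subtype, no core effect (baseline zeros)

        mu = base[:, None] * cf[:, None] * libf[None, :] * 2.0**eff
        counts = rng.negative_binomial(r, r / (r + mu))
        cohorts[cid] = ExpressionMatrix(
            pd.DataFrame(counts, index=genes, columns=all_ids), cohort=cid, unit="counts"
        )

        # infiltrates (Dirichlet over cell types), tumors only
        inf = rng.dirichlet(np.ones(config.n_cell_types) * 2.0, size=n)

        # survival: exponential with class (and optional infiltrate) log-hazard
        log_hr = config.survival_log_hr * (klass == 2).astype(float)
        log_hr += np.where(klass == 2, inf_hr[1], inf_hr[0]) * (
            inf[:, 0] - float(np.median(inf[:, 0]))
        )
        lam = config.baseline_hazard * np.exp(log_hr)
        event_t = rng.exponential(1.0 / lam)
        if config.censoring_rate > 0:
            t_max = _censoring_horizon(config.censoring_rate, config.baseline_hazard)
            cens_t = rng.uniform(0.0, t_max, size=n)
            time = np.minimum(event_t, cens_t)
            event = (event_t <= cens_t).astype(int)
        else:
            time, event = event_t, np.ones(n, int)
        time = np.maximum(time, 1e-9)

        for i, sid in enumerate(sample_ids):
            pid = f"{cid}_p{i:03d}"
            truth_rows.append(
                {"sample_id": sid, "cohort": cid, "subtype": subtypes[sub_idx[i]],
                 "true_class": int(klass[i]), "participant_id": pid, "is_tumor": 1}
            )
            row = {"sample_id": sid, "cohort": cid, "time": float(time[i]),
                   "event": int(event[i]),
                   "class": "C1" if klass[i] == 1 else "C2"}
            for ct in range(config.n_cell_types):
                row[f"celltype_{ct}"] = float(inf[i, ct])
            clin_rows.append(row)
            for d in range(config.n_drugs):
                drug_rows.append(
                    {"cell_line": sid, "cohort": cid, "drug": f"drug_{d:02d}",
                     "lnIC50": float(
                         drug_base[d]
                         + config.drug_effect * (klass[i] == 2)
                         + rng.normal(0.0, 1.0)
                     )}
                )
        for i, nid in zip(paired, normal_ids):
            truth_rows.append(
                {"sample_id": nid, "cohort": cid, "subtype": subtypes[sub_idx[i]],
                 "true_class": int(klass[i]), "participant_id": f"{cid}_p{i:03d}",
                 "is_tumor": 0}
            )

    truth = pd.DataFrame(truth_rows)
    dup = truth.groupby(["participant_id", "is_tumor"]).size()
    assert (dup <= 1).all(), "participant appears twice with the same tumor flag"
    return SimulatedData(
        config=config,
        cohorts=cohorts,
        truth=truth,
        clinical=pd.DataFrame(clin_rows),
        drugs=pd.DataFrame(drug_rows),
        centroids=centroids,
        baseline_means=pd.Series(base, index=genes, name="baseline_mean"),
        cohort_factors=pd.DataFrame(cohort_factors, index=genes),
        library_factors=pd.Series(lib_factors, name="library_factor"),
    )


def write_dataset(sim: SimulatedData, outdir: str | Path) -> None:
    """Write cohort count TSVs, truth/clinical/drug tables and the config JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cid, em in sim.cohorts.items():
        em.values.to_csv(out / f"counts_{cid}.tsv", sep="\t", index_label="gene_id")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    sim.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    sim.drugs.to_csv(out / "drugs.tsv", sep="\t", index=False)
    sim.centroids.values.to_csv(out / "centroids.tsv", sep="\t", index_label="gene_id")
    cfg = asdict(sim.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("subtype_proportions", "infiltrate_log_hr"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
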