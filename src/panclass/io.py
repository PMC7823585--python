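"""Readers and writers for the plain-text formats used across the pipeline.

All matrices travel as TSV with genes in rows (first column = gene id) and a
header row of sample ids; gene sets as standard GMT; signatures as one gene
per line with an optional ``# {json}`` header carrying name and scoring mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .preprocess import ExpressionMatrix


def read_matrix_tsv(path: str | Path, cohort: str | None = None, unit: str = "counts") -> ExpressionMatrix:
    """Read a gene×sample TSV matrix; duplicate gene ids are averaged."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    if cohort is None:
        cohort = Path(path).stem
    return ExpressionMatrix(df, cohort=cohort, unit=unit)


def write_matrix_tsv(em: ExpressionMatrix | pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df = em.values if isinstance(em, ExpressionMatrix) else em
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, tab-separated gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_signature_file(path: str | Path):
    """Read a signature file: optional ``# {json}`` header, one gene per line.

    Returns a :class:`panclass.signatures.GeneSignature`.
    """
    from .signatures import GeneSignature

    meta: dict = {}
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                payload = line.lstrip("#").strip()
                if payload.startswith("{"):
                    meta.update(json.loads(payload))
                continue
            genes.append(line)
    if meta.get("placeholder"):
        raise ValueError(
            f"signature file {path} is a placeholder (the published gene list is "
            "not redistributable here); supply your own gene list"
        )
    name = meta.get("name", Path(path).stem)
    mode = meta.get("mode", "mean_z")
    return GeneSignature(name=name, genes=genes, mode=mode)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def read_drug_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_line", "cohort", "drug", "lnIC50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    return df
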