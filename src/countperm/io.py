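"""File formats: genotype/phenotype TSV, PLINK .raw, count-table JSON, results TSV.

Readers validate and reject out-of-domain values rather than coercing
them; every writer produces files its paired reader round-trips
bit-exactly for integer data. The PLINK additive ``.raw`` dialect is
translated at the boundary (case/control phenotype 1/2 -> 0/1, -9/NA ->
missing), so internal code only ever sees {0, 1} phenotypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import MISSING, CountTable, GenotypeMatrix
from .scan import ScanRecord

__all__ = [
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_plink_raw",
    "read_count_table_json",
    "write_count_table_json",
    "write_scan_tsv",
    "load_config",
]

NA_TOKEN = "NA"


def _parse_coded(raw: pd.DataFrame, allowed: set[int], what: str, path) -> np.ndarray:
    values = np.full(raw.shape, MISSING, dtype=np.int64)
    str_vals = raw.astype(str).to_numpy()
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            tok = str_vals[r, c].strip()
            if tok in (NA_TOKEN, "nan", "<NA>", ""):
                continue
            try:
                v = int(tok)
            except ValueError:
                v = None
            if v is None or v not in allowed:
                raise ValueError(
                    f"{path}: invalid {what} value {tok!r} at data line {r + 1}"
                )
            values[r, c] = v
    return values


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: header of SNP ids, first column sample ids, body 0/1/2/NA."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no SNP columns found")
    values = _parse_coded(df, {0, 1, 2}, "genotype", path)
    return GenotypeMatrix(
        values=values,
        snp_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.snp_ids
    ).astype(object)
    df[df == MISSING] = NA_TOKEN
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_phenotype_tsv(path) -> np.ndarray:
    """Read a single-column phenotype TSV with header; values 0/1/NA."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: phenotype file must have exactly one column")
    return _parse_coded(df, {0, 1}, "phenotype", path).ravel()


def write_phenotype_tsv(phenotype: np.ndarray, path, column: str = "phenotype") -> None:
    col = np.asarray(phenotype).astype(object)
    col[col == MISSING] = NA_TOKEN
    pd.DataFrame({column: col}).to_csv(path, sep="\t", index=False)


PLINK_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_plink_raw(path) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a PLINK additive-coded ``.raw`` export.

    Expects the whitespace-delimited header ``FID IID PAT MAT SEX
    PHENOTYPE`` followed by SNP columns; genotypes are 0/1/2 minor-allele
    dosages with NA for missing. The case/control phenotype is remapped
    1 -> 0 (control), 2 -> 1 (case), -9/NA -> missing; any other
    phenotype value (e.g. quantitative) is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if list(df.columns[:6]) != PLINK_META_COLUMNS:
        raise ValueError(
            f"{path}: expected header starting with {' '.join(PLINK_META_COLUMNS)}"
        )
    snp_cols = list(df.columns[6:])
    if not snp_cols:
        raise ValueError(f"{path}: no SNP columns after the six metadata columns")
    genotypes = _parse_coded(df[snp_cols], {0, 1, 2}, "genotype", path)
    phenotype = np.full(len(df), MISSING, dtype=np.int64)
    for r, tok in enumerate(df["PHENOTYPE"].astype(str)):
        tok = tok.strip()
        if tok in (NA_TOKEN, "nan", ""):
            continue
        if tok == "1":
            phenotype[r] = 0
        elif tok == "2":
            phenotype[r] = 1
        elif tok == "-9":
            continue
        else:
            raise ValueError(
                f"{path}: unsupported PHENOTYPE value {tok!r} at data line "
                f"{r + 1}; only case/control coding (1/2, -9/NA missing) is supported"
            )
    sample_ids = (df["FID"].astype(str) + "_" + df["IID"].astype(str)).tolist()
    return (
        GenotypeMatrix(values=genotypes, snp_ids=snp_cols, sample_ids=sample_ids),
        phenotype,
    )


def read_count_table_json(path) -> CountTable:
    """Read a count table stored as JSON layers ``{"layer0": 3x3, "layer1": 3x3}``."""
    with open(path) as fh:
        obj = json.load(fh)
    for key in ("layer0", "layer1"):
        if key not in obj:
            raise ValueError(f"{path}: missing field {key!r}")
        layer = np.asarray(obj[key])
        if layer.shape != (3, 3):
            raise ValueError(f"{path}: {key} must be a 3x3 array, got {layer.shape}")
    table = CountTable.from_layers(obj["layer0"], obj["layer1"])
    if table.total == 0:
        raise ValueError(f"{path}: count table is empty (total = 0)")
    return table


def write_count_table_json(table: CountTable, path) -> None:
    obj = {
        "layer0": table.layer(0).tolist(),
        "layer1": table.layer(1).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def write_scan_tsv(records: list[ScanRecord], path) -> None:
    """Write scan results as TSV: snp1, snp2, measure name/value, p-value, n_perm."""
    df = pd.DataFrame(
        {
            "snp1": [r.snp1_id for r in records],
            "snp2": [r.snp2_id for r in records],
            "measure": [r.observed.name for r in records],
            "value": [float(r.observed.value) for r in records],
            "p_value": [r.p_empirical for r in records],
            "n_perm": [r.n_perm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML config whose sections mirror the CLI subcommand flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of sections to options")
    return cfg
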