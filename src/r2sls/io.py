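"""Plain-text readers and writers.

All formats are tab-separated text with a header row; metadata lines are
'#'-prefixed and missing values are written as "NA", following GWAS
summary-file conventions.  No binary genotype formats are handled here.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import FitResult
from .data import TwoSampleData
from .exceptions import DegenerateInputError
from .summary import LDPanel, SummaryDataset

logger = logging.getLogger(__name__)

_NA = "NA"


def _detect_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if "\t" in line:
                return "\t"
            if "," in line:
                return ","
            return r"\s+"
    raise DegenerateInputError(f"{path}: empty file")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a delimited numeric matrix with a header row; returns (array, columns)."""
    df = pd.read_csv(path, sep=_detect_sep(path), engine="python", comment="#")
    return df.to_numpy(dtype=float), list(df.columns)


def read_vector(path) -> np.ndarray:
    """Read a single-column delimited file with a header row."""
    arr, cols = read_matrix(path)
    if arr.shape[1] != 1:
        raise ValueError(f"{path}: expected one column, found {len(cols)}")
    return arr[:, 0]


def read_two_sample(x1_path, z1_path, y2_path, z2_path) -> TwoSampleData:
    """Assemble a TwoSampleData from four delimited files, checking IV alignment."""
    x1 = read_vector(x1_path)
    y2 = read_vector(y2_path)
    Z1, cols1 = read_matrix(z1_path)
    Z2, cols2 = read_matrix(z2_path)
    if cols1 != cols2:
        raise DegenerateInputError(
            "IV columns of Z1 and Z2 do not match in name/order; "
            f"first difference near {next((a for a, b in zip(cols1, cols2) if a != b), '<length>')!r}"
        )
    return TwoSampleData(x1=x1, Z1=Z1, y2=y2, Z2=Z2)


def read_summary_tsv(path) -> SummaryDataset:
    """Read GWAS summary statistics: columns snp, beta, se|var, n [, alleles].

    Rows with missing or non-finite values are dropped with a logged count;
    duplicate SNP ids raise an error naming the id.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    required = {"snp", "beta", "n"}
    missing = required - set(df.columns)
    if missing:
        raise DegenerateInputError(f"{path}: missing required column(s) {sorted(missing)}")
    if "var" in df.columns:
        var = df["var"].astype(float)
    elif "se" in df.columns:
        var = df["se"].astype(float) ** 2
    else:
        raise DegenerateInputError(f"{path}: need an 'se' or 'var' column")
    work = pd.DataFrame(
        {
            "snp": df["snp"].astype(str),
            "beta": df["beta"].astype(float),
            "var": var,
            "n": df["n"].astype(float),
        }
    )
    has_alleles = {"effect_allele", "other_allele"} <= set(df.columns)
    if has_alleles:
        work["effect_allele"] = df["effect_allele"].astype(str)
        work["other_allele"] = df["other_allele"].astype(str)
    ok = np.isfinite(work["beta"]) & np.isfinite(work["var"]) & np.isfinite(work["n"])
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d rows with missing/non-finite values", path, dropped)
    work = work[ok]
    dup = work["snp"][work["snp"].duplicated()]
    if not dup.empty:
        raise DegenerateInputError(f"{path}: duplicate SNP id {dup.iloc[0]!r}")
    return SummaryDataset(
        ids=work["snp"].to_numpy(dtype=object),
        beta=work["beta"].to_numpy(),
        var=work["var"].to_numpy(),
        n=work["n"].to_numpy(),
        effect_allele=work["effect_allele"].to_numpy(dtype=object) if has_alleles else None,
        other_allele=work["other_allele"].to_numpy(dtype=object) if has_alleles else None,
    )


def read_panel(path, kind: str = "genotype") -> LDPanel:
    """Read a reference panel: standardized genotype TSV or precomputed LD TSV.

    Both carry SNP ids as the header row; an LD file is a square matrix.
    """
    arr, cols = read_matrix(path)
    ids = np.asarray(cols, dtype=object)
    if kind == "genotype":
        return LDPanel(ids=ids, genotypes=arr)
    if kind == "ld":
        if arr.shape[0] != arr.shape[1]:
            raise DegenerateInputError(f"{path}: LD matrix must be square, got {arr.shape}")
        return LDPanel(ids=ids, corr=arr)
    raise ValueError("panel kind must be 'genotype' or 'ld'")


def write_fit_tsv(result: FitResult, path, meta: Optional[dict] = None) -> None:
    """Write a one-row fit result with '#'-prefixed metadata lines."""
    row = result.to_row()
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(row.keys()) + "\n")
        fh.write("\t".join(_fmt(v) for v in row.values()) + "\n")


def _fmt(v):
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, float):
        return _NA if not np.isfinite(v) else f"{v:.10g}"
    return str(v)


def load_yaml_config(path) -> dict:
    """Read a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DegenerateInputError(f"{path}: configuration must be a mapping")
    return cfg
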