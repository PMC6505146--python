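"""Readers and writers for the package's tabular file formats.

All on-disk formats are plain CSV (genotype matrix, marker map, plot-level
phenotypes, daily weather, EC matrix) plus JSON for the simulation truth.
VCF genotype input is supported through cyvcf2 when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GenotypeMatrix

__all__ = [
    "read_genotypes_csv", "write_genotypes_csv", "read_genotypes_vcf",
    "read_phenotypes", "read_weather", "read_seasons", "write_ec", "read_ec",
    "write_truth",
]


def read_genotypes_csv(geno_path, map_path=None) -> GenotypeMatrix:
    """Genotype CSV: first column line IDs, remaining columns marker dosages."""
    dosage = pd.read_csv(geno_path, index_col=0)
    if map_path is not None:
        mp = pd.read_csv(map_path)
    else:
        mp = pd.DataFrame({"marker": dosage.columns, "chrom": np.nan, "pos": np.nan})
    return GenotypeMatrix(dosage, mp)


def write_genotypes_csv(geno: GenotypeMatrix, geno_path, map_path=None) -> None:
    geno.dosage.to_csv(geno_path, index_label="line")
    if map_path is not None:
        geno.map.to_csv(map_path, index=False)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Biallelic-SNP dosages (alt-allele count) from a VCF file."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    names, chroms, poss, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        names.append(name)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    dosage = pd.DataFrame(np.array(rows).T, index=samples, columns=names)
    mp = pd.DataFrame({"marker": names, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(dosage, mp)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"year", "genotype"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    return df


def read_weather(paths, years=None) -> dict:
    """One daily-weather CSV per year -> dict year -> DataFrame."""
    paths = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    out = {}
    for i, p in enumerate(paths):
        df = pd.read_csv(p, parse_dates=["date"])
        yr = years[i] if years is not None else _infer_year(p, df)
        out[yr] = df
    return out


def _infer_year(path: Path, df: pd.DataFrame):
    stem = path.stem
    for tok in stem.replace("-", "_").split("_"):
        if tok.isdigit() and len(tok) == 4:
            return int(tok)
    return int(pd.to_datetime(df["date"]).dt.year.iloc[0])


def read_seasons(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["sowing", "harvest"])
    need = {"year", "sowing", "harvest", "ft_days"}
    if not need <= set(df.columns):
        raise ValueError(f"seasons table needs columns {sorted(need)}")
    return df


def write_ec(ec_raw: pd.DataFrame, path) -> None:
    ec_raw.to_csv(path, index_label="year")


def read_ec(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)
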