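"""Readers and writers for the plain-text formats used across the package.

Formats: numeric genotype TSV (header of marker names, first column the
individual id, dosages 0/1/2, "NA" missing) with a companion map TSV
(marker, chrom, pos); HapMap text (diploid calls converted to the count of
the alphabetically second allele); square kinship CSV with an id header row
and column; phenotype TSV (id, value, "NA" missing); prediction TSV and a
JSON run summary.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix, KinshipMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
    "write_predictions",
    "write_summary",
]

_MISSING = "NA"


def read_genotypes(path, map_path=None, format: str = "numeric_tsv") -> GenotypeMatrix:
    """Load a genotype matrix from ``numeric_tsv`` or ``hapmap`` text."""
    if format == "numeric_tsv":
        if map_path is None:
            raise ValueError("numeric_tsv requires a companion map file")
        return _read_numeric(path, map_path)
    if format == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_numeric(path, map_path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_MISSING])
    except pd.errors.ParserError as e:
        raise ValueError(f"inconsistent column counts in {path}: {e}") from e
    if df.index.duplicated().any():
        raise ValueError("duplicated individual ids")
    if df.columns.duplicated().any():
        raise ValueError("duplicated marker names")
    mp = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    mp = mp[["marker", "chrom", "pos"]]
    if list(mp["marker"]) != list(df.columns):
        mp = mp.set_index("marker").loc[list(df.columns)].reset_index()
    return GenotypeMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), mp)


def _read_hapmap(path) -> GenotypeMatrix:
    n_bad = 0
    markers, chroms, poss, cols = [], [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = [h.strip() for h in header[11:]]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated individual ids")
        for ln, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 11 + len(ids):
                raise ValueError(f"inconsistent column count at line {ln}")
            markers.append(f[0])
            alleles = sorted(a for a in f[1].split("/") if a)
            second = alleles[1] if len(alleles) > 1 else None
            chroms.append(f[2])
            poss.append(int(f[3]))
            row = np.full(len(ids), np.nan)
            for i, call in enumerate(f[11:]):
                call = call.strip().upper()
                if second is not None and len(call) == 2 and set(call) <= set(alleles):
                    row[i] = call.count(second)
                else:
                    n_bad += 1
            cols.append(row)
    if len(set(markers)) != len(markers):
        raise ValueError("duplicated marker names")
    if n_bad:
        warnings.warn(f"{n_bad} unparseable genotype calls set to missing")
    codes = np.asarray(cols).T
    mp = pd.DataFrame({"marker": markers, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(ids, codes, mp)


def write_genotypes(G: GenotypeMatrix, path, map_path) -> None:
    df = pd.DataFrame(G.codes, index=pd.Index(G.ids, name="id"), columns=G.marker_map["marker"])
    df.to_csv(path, sep="\t", na_rep=_MISSING, float_format="%g")
    G.marker_map.to_csv(map_path, sep="\t", index=False)


def read_phenotypes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING], dtype={0: str})
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0], name=df.columns[1])
    s.index.name = "id"
    return s


def write_phenotypes(y: pd.Series, path) -> None:
    y.rename("phenotype").to_frame().to_csv(path, sep="\t", na_rep=_MISSING)


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_kinship(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.ids, columns=K.ids).to_csv(path)


def write_predictions(pred: pd.Series, status: pd.Series, path) -> None:
    """Prediction TSV with a reference/inference status column."""
    df = pd.DataFrame({"prediction": pred, "status": status})
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
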