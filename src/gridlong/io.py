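"""Readers, writers and run configuration.

Canonical interchange formats are delimited text: genotypes as a matrix with
one row per individual (first column the subject id, remaining columns SNP
dosages), phenotypes in long format (subject_id, time, value, extra
covariates), profiles and chains as TSV tables.  VCF input is supported when
cyvcf2 is installed.  All writes are atomic (temp file + rename) and every
CLI run emits a JSON manifest sufficient to reproduce it.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_phenotypes",
    "read_genotypes",
    "read_genotypes_vcf",
    "write_table",
    "write_manifest",
    "load_config",
    "atomic_write",
]


@contextmanager
def atomic_write(path):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype table: subject_id, time, value [, covariates].

    Wide layouts (one column per time point) are rejected; duplicate
    (subject, time) rows and non-numeric traits raise with row context.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"subject_id", "time", "value"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: phenotype file must be long format with columns "
            f"subject_id, time, value (got {list(df.columns)}); wide layouts "
            "must be melted to one row per observation first"
        )
    for col in ("time", "value"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: non-numeric entry in column {col!r}: {err}")
    dup = df.duplicated(["subject_id", "time"])
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise ValueError(f"{path}: duplicate (subject, time) rows at lines {rows}")
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Genotype matrix: rows = individuals, header = SNP ids, first column the
    subject id; additive codes 0/1/2 or dosages in [0, 2]."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df = df.set_index(df.columns[0])
    return df.apply(pd.to_numeric)


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Additive dosage matrix from a (biallelic-site) VCF via cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from err
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append(dosage)
    return pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="subject_id"), columns=ids
    )


def write_table(path, table: pd.DataFrame) -> None:
    with atomic_write(path) as fh:
        table.to_csv(fh, sep="\t", index=False)


def write_manifest(path, manifest: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with atomic_write(path) as fh:
        json.dump(manifest, fh, indent=2, default=_default, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
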