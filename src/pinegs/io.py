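"""Readers and writers for the pipeline's plain-text formats.

Dialects
--------
- Pedigree CSV: header ``id,sire,dam``; ``0`` or empty = unknown parent.
- Genotype TSV: rows = individuals (first column ``id``), columns = marker
  ids, cells in {0, 1, 2, NA}. An optional VCF reader converts diploid GT
  fields to alternate-allele dosage (``./.`` = missing).
- Phenotype CSV: ``clone,site,rep,set,block,trait,value``.
- Relationship matrices: labelled dense TSV.

All read/write pairs round-trip: read(write(x)) == x.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pinegs.mixed_model import PHENO_COLUMNS
from pinegs.pedigree import Pedigree


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.strip().lower() for c in df.columns}
    if not {"id", "sire", "dam"} <= cols:
        raise ValueError(f"{path}: pedigree CSV must have header id,sire,dam")
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree.from_frame(df)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.map(str)
    vals = df.apply(pd.to_numeric, errors="coerce").values
    ok = (df.isna().values & np.isnan(vals)) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(
            f"{path}: invalid genotype {df.iat[r, c]!r} at line {r + 2}, "
            f"marker {df.columns[c]!r} (expected 0/1/2/NA)"
        )
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def write_genotypes_tsv(G: pd.DataFrame, path) -> None:
    out = G.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into an individuals x markers dosage DataFrame (needs cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    markers, rows = [], []
    for v in vcf:
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        markers.append(mid)
        # gt_types: 0=hom-ref 1=het 2=hom-alt 3=unknown
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
    vcf.close()
    if not markers:
        raise ValueError(f"{path}: VCF contains no variants")
    return pd.DataFrame(np.column_stack(rows), index=samples, columns=markers)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype CSV missing columns {missing}")
    bad = df["value"].apply(lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number))))
    if bad.any():
        raise ValueError(f"{path}: non-numeric value at line {int(bad.idxmax()) + 2}")
    for c in ("clone", "site", "rep", "set", "block", "trait"):
        df[c] = df[c].astype(str)
    return df[PHENO_COLUMNS]


def write_phenotypes_csv(pheno: pd.DataFrame, path) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, index=False)


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def write_matrix_tsv(K: pd.DataFrame, path) -> None:
    out = K.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
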