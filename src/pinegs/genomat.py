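"""Genotype-matrix QC and the genomic relationship matrix.

Genotypes are held in a pandas DataFrame: rows = individuals, columns =
markers, values = alternate-allele dosage in {0, 1, 2} with NaN for missing.

The genomic relationship matrix follows the VanRaden method-1 construction:
dosages are centred by twice the reference allele frequency and normalized by
2 * sum_j p_j (1 - p_j), so that for an unrelated, Hardy-Weinberg population
the diagonal averages 1 and off-diagonals average 0 -- directly comparable to
the pedigree numerator relationship matrix A.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def call_rate(G: pd.DataFrame) -> pd.Series:
    """Per-marker fraction of non-missing genotypes."""
    return G.notna().mean(axis=0).rename("call_rate")


def allele_freq(G: pd.DataFrame, reference: list[str] | None = None) -> pd.Series:
    """Alternate-allele frequency per marker.

    Frequencies are computed on the ``reference`` individuals when given
    (e.g. a panel of unrelated trees, as is standard for founder allele
    frequencies), otherwise on all individuals. Missing genotypes are
    excluded marker-wise.
    """
    sub = G.loc[list(reference)] if reference is not None else G
    counts = sub.notna().sum(axis=0)
    bad = counts[counts == 0]
    if len(bad):
        raise ValueError(
            f"allele_freq: markers with no non-missing reference genotype: {list(bad.index[:10])}"
        )
    return (sub.sum(axis=0, skipna=True) / (2.0 * counts)).rename("p")


def minor_allele_freq(p: pd.Series) -> pd.Series:
    return np.minimum(p, 1.0 - p).rename("maf")


def filter_maf(G: pd.DataFrame, p: pd.Series, min_maf: float = 0.03) -> pd.DataFrame:
    """Drop markers whose minor allele frequency is below ``min_maf``.

    A marker with MAF exactly equal to the threshold is retained (only
    strictly smaller frequencies are excluded).
    """
    maf = minor_allele_freq(p.loc[G.columns])
    keep = maf >= min_maf
    if not keep.any():
        logger.warning("filter_maf: no markers pass min_maf=%s", min_maf)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_maf: excluded %d of %d markers (MAF < %s)", dropped, len(keep), min_maf)
    return G.loc[:, keep[keep].index]


def impute_mean(G: pd.DataFrame, means: pd.Series | None = None) -> pd.DataFrame:
    """Replace missing genotypes by the marker mean dosage.

    ``means`` (e.g. reference-set means ``2*p``) overrides the column means;
    by default the mean over the non-missing genotyped individuals is used.
    """
    if means is None:
        if G.notna().sum(axis=0).eq(0).any():
            bad = G.columns[G.notna().sum(axis=0) == 0]
            raise ValueError(f"impute_mean: markers with all genotypes missing: {list(bad[:10])}")
        means = G.mean(axis=0, skipna=True)
    return G.fillna(means.loc[G.columns])


def build_G(G: pd.DataFrame, p: pd.Series) -> pd.DataFrame:
    """Genomic relationship matrix G = W W' / (2 * sum p_j (1-p_j)).

    ``G`` must be imputed (no missing values); ``W`` is the dosage matrix
    centred column-wise by 2 p_j.
    """
    M = G.values.astype(float)
    if np.isnan(M).any():
        raise ValueError("build_G: genotype matrix contains missing values; impute first")
    pv = p.loc[G.columns].values.astype(float)
    denom = 2.0 * np.sum(pv * (1.0 - pv))
    if denom <= 0:
        raise ValueError("build_G: all markers fixed (2*sum p(1-p) = 0)")
    W = M - 2.0 * pv
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=G.index, columns=G.index)


def blend(K: pd.DataFrame, weight: float = 0.01) -> pd.DataFrame:
    """Blend a relationship matrix toward the identity: (1-w) K + w I.

    Standard stabilization when K must be inverted and is (near-)singular.
    """
    n = len(K)
    return pd.DataFrame(
        (1.0 - weight) * K.values + weight * np.eye(n), index=K.index, columns=K.index
    )


def min_eigenvalue(K: pd.DataFrame) -> float:
    return float(np.linalg.eigvalsh((K.values + K.values.T) / 2.0)[0])
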