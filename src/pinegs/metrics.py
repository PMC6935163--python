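"""Heritabilities, breeding-value accuracy from PEV, and %VA.

Three narrow-sense heritability definitions are reported per site i:

    h2_a(i)  = s2_a / (s2_a + s2_d + s2_e_i)                   (pedigree, ABLUP)
    h2_m(i)  = s2_m / (s2_m + s2_a* + s2_d + s2_e_i)           (marker, GBLUP)
    h2_am(i) = (s2_m + s2_a*) / (s2_m + s2_a* + s2_d + s2_e_i) (combined, GBLUP)

Individual accuracy is r_i = sqrt(1 - PEV_i / ((1 + F_i) s2)), with s2 the
additive variance tied to the breeding values (s2_a for ABLUP, s2_m for
GBLUP), and %VA = s2_m / (s2_m + s2_a*) * 100 is the share of additive
variance captured by markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pinegs.mixed_model import VarianceComponents


def _resid(vc: VarianceComponents, site: str) -> float:
    try:
        return vc[f"residual:{site}"]
    except KeyError:
        raise KeyError(f"no residual variance for site {site!r}") from None


def h2_pedigree(vc: VarianceComponents, site: str) -> float:
    """Pedigree-based heritability at one site (ABLUP components)."""
    num = vc["additive"]
    den = num + vc.get("clone", 0.0) + _resid(vc, site)
    if den <= 0:
        raise ZeroDivisionError("h2_pedigree: zero denominator")
    return num / den


def h2_marker(vc: VarianceComponents, site: str) -> float:
    """Marker-based heritability at one site (GBLUP components)."""
    den = vc["marker"] + vc.get("polygenic", 0.0) + vc.get("clone", 0.0) + _resid(vc, site)
    if den <= 0:
        raise ZeroDivisionError("h2_marker: zero denominator")
    return vc["marker"] / den


def h2_combined(vc: VarianceComponents, site: str) -> float:
    """Combined marker + residual-polygenic heritability at one site (GBLUP)."""
    num = vc["marker"] + vc.get("polygenic", 0.0)
    den = num + vc.get("clone", 0.0) + _resid(vc, site)
    if den <= 0:
        raise ZeroDivisionError("h2_combined: zero denominator")
    return num / den


def h2_table(vc: VarianceComponents, model: str = "ablup") -> pd.DataFrame:
    """Per-site heritabilities plus their unweighted cross-site average."""
    sites = sorted(vc.per_site("residual"))
    rows = {}
    for s in sites:
        if model == "ablup":
            rows[s] = {"h2_a": h2_pedigree(vc, s)}
        else:
            rows[s] = {"h2_m": h2_marker(vc, s), "h2_am": h2_combined(vc, s)}
    out = pd.DataFrame(rows).T
    out.loc["average"] = out.mean()
    return out


def accuracy(pev, F, sigma2_ref: float, tol: float = 1e-8):
    """Breeding-value accuracy r = sqrt(1 - PEV / ((1 + F) s2_ref)).

    ``pev`` and ``F`` may be scalars or aligned pandas Series. PEV exceeding
    the (1+F) s2 bound by more than ``tol`` raises; numerical overshoot within
    the tolerance is clamped to r = 0.
    """
    pev_arr = np.asarray(pev, dtype=float)
    F_arr = np.asarray(F, dtype=float)
    bound = (1.0 + F_arr) * sigma2_ref
    if np.any(pev_arr < -tol) or np.any(pev_arr > bound + tol):
        raise ValueError("accuracy: PEV outside [0, (1+F) sigma2]")
    ratio = np.clip(1.0 - pev_arr / bound, 0.0, 1.0)
    r = np.sqrt(ratio)
    if isinstance(pev, pd.Series):
        return pd.Series(r, index=pev.index, name="accuracy")
    return float(r) if np.ndim(r) == 0 else r


def mean_accuracy(fit, A: pd.DataFrame, individuals=None, term: str | None = None) -> float:
    """Population accuracy: mean individual accuracy over ``individuals``.

    ``term`` defaults to the model's additive term ("marker" for GBLUP,
    "additive" for ABLUP); F comes from the diagonal of the covariance used by
    that term (A for pedigree terms, so F = a_ii - 1).
    """
    term = term or ("marker" if "marker" in fit.blups else "additive")
    pev = fit.pev[term]
    if individuals is not None:
        individuals = [i for i in individuals if i in pev.index]
        pev = pev.loc[individuals]
    F = pd.Series(np.diag(A.values) - 1.0, index=A.index).reindex(pev.index).fillna(0.0)
    sigma2 = fit.vc[term]
    return float(accuracy(pev, F, sigma2).mean())


def percent_va(vc: VarianceComponents) -> float:
    """Percentage of additive genetic variance explained by markers (GBLUP)."""
    m = vc["marker"]
    a = vc.get("polygenic", 0.0)
    if m + a <= 0:
        raise ZeroDivisionError("percent_va: marker + polygenic variance is zero")
    return 100.0 * m / (m + a)
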