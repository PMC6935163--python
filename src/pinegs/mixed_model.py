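"""Linear mixed models for clonally replicated multi-site trials.

The model is the standard individual-tree evaluation model

    y = X b + Z_a u_a [+ Z_m u_m] + Z_d d + Z_r r + Z_w w + Z_b blk + e

with fixed intercept and site effects, additive genetic effects with a
pedigree (A) and/or genomic (G) covariance, a clone-level non-additive effect
d with identity covariance (identifiable thanks to clonal replication), and
replicate, set-within-replicate and incomplete-block effects plus residuals
whose variances are heterogeneous across sites (diagonal per-site structures).

Variance components are estimated by restricted maximum likelihood using
average-information (AI) updates with EM warm-up steps and EM fallback when an
AI step fails; BLUP solutions and prediction error variances (PEV) come from
Henderson's mixed-model equations at the REML estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from pinegs.genomat import blend, min_eigenvalue
from pinegs.pedigree import Pedigree, build_A, is_sorted, sort_pedigree

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["clone", "site", "rep", "set", "block", "trait", "value"]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the last iterate."""

    def __init__(self, msg, components=None, change=None):
        super().__init__(msg)
        self.components = components
        self.change = change


@dataclass(frozen=True)
class ModelSpec:
    """Which random terms to fit and which covariance feeds each genetic term.

    ``genetic`` maps term names to covariance keys ("A" or "G" by convention);
    ``clone_effect`` adds the identity-covariance non-additive clone term;
    ``env_terms`` are the per-site heterogeneous design strata.
    """

    genetic: tuple[tuple[str, str], ...]
    clone_effect: bool = True
    env_terms: tuple[str, ...] = ("rep", "set", "block")
    name: str = "custom"

    @staticmethod
    def ablup() -> "ModelSpec":
        return ModelSpec(genetic=(("additive", "A"),), name="ablup")

    @staticmethod
    def gblup() -> "ModelSpec":
        return ModelSpec(genetic=(("marker", "G"), ("polygenic", "A")), name="gblup")


@dataclass
class RandomTerm:
    name: str
    Z: np.ndarray                 # n x q incidence
    levels: list[str]
    K: np.ndarray | None          # q x q covariance for genetic terms, else identity
    groups: np.ndarray            # q ints: variance-parameter group per level
    group_names: list[str]        # one per group ("" -> single homogeneous group)

    @property
    def labels(self) -> list[str]:
        if self.group_names == [""]:
            return [self.name]
        return [f"{self.name}:{g}" for g in self.group_names]


@dataclass
class DesignBundle:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    terms: list[RandomTerm]
    obs_site: np.ndarray          # n ints
    site_names: list[str]
    obs_index: pd.Index           # row identity of observations

    @property
    def param_labels(self) -> list[str]:
        labels: list[str] = []
        for t in self.terms:
            labels.extend(t.labels)
        labels.extend(f"residual:{s}" for s in self.site_names)
        return labels

    def param_sizes(self) -> np.ndarray:
        """Level counts per variance parameter (EM denominators)."""
        q = []
        for t in self.terms:
            if t.group_names == [""]:
                q.append(t.Z.shape[1])
            else:
                q.extend(int((t.groups == g).sum()) for g in range(len(t.group_names)))
        q.extend(int((self.obs_site == i).sum()) for i in range(len(self.site_names)))
        return np.asarray(q, dtype=float)

    def structures(self) -> list[np.ndarray]:
        """V_j matrices: V(theta) = sum_j theta_j V_j."""
        n = len(self.y)
        Vs: list[np.ndarray] = []
        for t in self.terms:
            if t.K is not None:
                Vs.append(t.Z @ t.K @ t.Z.T)
            elif t.group_names == [""]:
                Vs.append(t.Z @ t.Z.T)
            else:
                for g in range(len(t.group_names)):
                    Zg = t.Z[:, t.groups == g]
                    Vs.append(Zg @ Zg.T)
        for i in range(len(self.site_names)):
            Vs.append(np.diag((self.obs_site == i).astype(float)))
        return Vs


@dataclass
class VarianceComponents:
    """Flat label -> variance mapping, e.g. {"additive": ..., "residual:S1": ...}."""

    values: dict[str, float]

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def get(self, label: str, default: float = 0.0) -> float:
        return self.values.get(label, default)

    def per_site(self, term: str) -> dict[str, float]:
        pre = term + ":"
        return {k[len(pre):]: v for k, v in self.values.items() if k.startswith(pre)}

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="variance")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(dict(self.values))


@dataclass
class ModelFit:
    spec: ModelSpec
    vc: VarianceComponents
    beta: pd.Series
    blups: dict[str, pd.Series]
    pev: dict[str, pd.Series]
    loglik: float | None
    n_iter: int
    converged: bool
    design: DesignBundle | None = field(default=None, repr=False)

    @property
    def ebv(self) -> pd.Series:
        """Predicted additive genetic merit: â (ABLUP) or m̂ (GBLUP)."""
        key = "marker" if "marker" in self.blups else "additive"
        return self.blups[key]

    @property
    def total_ebv(self) -> pd.Series:
        """m̂ + â* for GBLUP models (falls back to â for ABLUP)."""
        if "marker" in self.blups and "polygenic" in self.blups:
            m = self.blups["marker"]
            a = self.blups["polygenic"].reindex(m.index).fillna(0.0)
            return (m + a).rename("total_ebv")
        return self.ebv


def _hier_labels(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    lab = df[cols[0]].astype(str)
    for c in cols[1:]:
        lab = lab + "|" + df[c].astype(str)
    return lab


def build_design(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    covariances: dict[str, pd.DataFrame],
) -> DesignBundle:
    """Assemble y, X and the incidence matrix of every random term.

    ``pheno`` holds one trait (columns clone/site/rep/set/block/value); all
    ramets of a clone map to a single level of each genetic and clone term.
    Environmental strata are nested site -> rep -> set -> block; a stratum
    whose column is absent (or entirely missing) is dropped with a warning.
    """
    df = pheno.copy()
    df = df[df["value"].notna()]
    if df.empty:
        raise ValueError("build_design: no non-missing phenotypes")
    df = df.reset_index(drop=True)
    n = len(df)
    df["clone"] = df["clone"].astype(str)
    df["site"] = df["site"].astype(str)

    site_names = sorted(df["site"].unique())
    site_code = {s: i for i, s in enumerate(site_names)}
    obs_site = df["site"].map(site_code).values

    # fixed effects: intercept + site contrasts (first site absorbed)
    X_cols = [np.ones(n)]
    fixed_names = ["intercept"]
    for s in site_names[1:]:
        X_cols.append((df["site"] == s).astype(float).values)
        fixed_names.append(f"site:{s}")
    X = np.column_stack(X_cols)

    terms: list[RandomTerm] = []
    clones = df["clone"]
    for name, key in spec.genetic:
        if key not in covariances:
            raise ValueError(f"build_design: covariance {key!r} required by term {name!r} missing")
        K = covariances[key]
        levels = [str(x) for x in K.index]
        level_idx = {c: i for i, c in enumerate(levels)}
        absent = sorted(set(clones) - set(levels))
        if absent:
            raise ValueError(
                f"build_design: clones absent from {key} labels for term {name!r}: {absent[:10]}"
            )
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), clones.map(level_idx).values] = 1.0
        terms.append(RandomTerm(name, Z, levels, np.asarray(K.values, dtype=float),
                                np.zeros(len(levels), dtype=int), [""]))

    if spec.clone_effect:
        levels = sorted(clones.unique())
        level_idx = {c: i for i, c in enumerate(levels)}
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), clones.map(level_idx).values] = 1.0
        terms.append(RandomTerm("clone", Z, levels, None,
                                np.zeros(len(levels), dtype=int), [""]))

    hierarchy = {"rep": ["site", "rep"], "set": ["site", "rep", "set"],
                 "block": ["site", "rep", "set", "block"]}
    for term in spec.env_terms:
        cols = hierarchy.get(term, ["site", term])
        if any(c not in df.columns for c in cols[1:]) or df[cols[-1]].isna().all():
            warnings.warn(f"build_design: stratum {term!r} absent from data; term dropped")
            continue
        lab = _hier_labels(df, cols)
        levels = sorted(lab.unique())
        level_idx = {c: i for i, c in enumerate(levels)}
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), lab.map(level_idx).values] = 1.0
        groups = np.array([site_code[l.split("|", 1)[0]] for l in levels])
        terms.append(RandomTerm(term, Z, levels, None, groups, site_names))

    return DesignBundle(
        y=df["value"].values.astype(float), X=X, fixed_names=fixed_names,
        terms=terms, obs_site=obs_site, site_names=site_names, obs_index=df.index,
    )


def _restricted_ll(theta, Vs, X, y):
    V = sum(t * Vj for t, Vj in zip(theta, Vs))
    try:
        L = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf
    Vi_y = cho_solve(L, y, check_finite=False)
    Vi_X = cho_solve(L, X, check_finite=False)
    M = X.T @ Vi_X
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    Xt_Vi_y = X.T @ Vi_y
    beta = np.linalg.solve(M, Xt_Vi_y)
    yPy = float(y @ Vi_y - Xt_Vi_y @ beta)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
    return -0.5 * (logdetV + logdetM + yPy)


def reml_estimate(
    design: DesignBundle,
    start: VarianceComponents | dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    method: str = "ai",
    floor_scale: float = 1e-8,
    n_em_warmup: int = 2,
) -> tuple[VarianceComponents, dict]:
    """REML variance components under the design's per-site structure.

    AI-REML (default) with EM warm-up steps and EM fallback whenever an AI
    step would decrease the restricted likelihood; ``method="em"`` forces pure
    EM updates. Components hitting the floor (1e-8 x phenotypic variance) are
    clamped there. Converges when the maximum relative component change drops
    below ``tol``; raises :class:`ConvergenceError` otherwise.
    """
    y, X = design.y, design.X
    n, p = X.shape
    if n <= p:
        raise ValueError("reml_estimate: more fixed effects than observations")
    labels = design.param_labels
    m = len(labels)
    Vs = design.structures()
    q = design.param_sizes()
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("reml_estimate: zero phenotypic variance")
    floor = floor_scale * vy

    if start is None:
        theta = np.empty(m)
        n_resid = len(design.site_names)
        theta[-n_resid:] = 0.5 * vy
        theta[: m - n_resid] = 0.5 * vy / max(m - n_resid, 1)
    else:
        sv = start.values if isinstance(start, VarianceComponents) else dict(start)
        theta = np.array([max(sv[l], floor) for l in labels])

    ll = _restricted_ll(theta, Vs, X, y)
    n_halving_max = 12
    converged = False
    it = 0
    rel_change = np.inf
    for it in range(1, max_iter + 1):
        V = sum(t * Vj for t, Vj in zip(theta, Vs))
        L = cho_factor(V, lower=True, check_finite=False)
        Vinv = cho_solve(L, np.eye(n), check_finite=False)
        XtVi = X.T @ Vinv
        M = XtVi @ X
        P = Vinv - XtVi.T @ np.linalg.solve(M, XtVi)
        Py = P @ y

        tr_PV = np.array([float(np.tensordot(P, Vj)) for Vj in Vs])
        T = np.column_stack([Vj @ Py for Vj in Vs])      # n x m
        yPVPy = T.T @ Py                                  # y'P Vj P y
        score = -0.5 * (tr_PV - yPVPy)

        em_theta = theta + theta**2 * (yPVPy - tr_PV) / q
        em_theta = np.maximum(em_theta, floor)

        new_theta = None
        if method == "ai" and it > n_em_warmup:
            AI = 0.5 * (T.T @ P @ T)
            free = ~((theta <= floor * (1 + 1e-12)) & (score < 0))
            if free.any():
                try:
                    delta = np.zeros(m)
                    delta[free] = np.linalg.solve(
                        AI[np.ix_(free, free)] + 1e-12 * np.eye(int(free.sum())),
                        score[free],
                    )
                    step = 1.0
                    for _ in range(n_halving_max):
                        cand = np.maximum(theta + step * delta, floor)
                        cand_ll = _restricted_ll(cand, Vs, X, y)
                        if cand_ll >= ll - 1e-10:
                            new_theta, ll_new = cand, cand_ll
                            break
                        step *= 0.5
                except np.linalg.LinAlgError:
                    pass
        if new_theta is None:
            new_theta = em_theta
            ll_new = _restricted_ll(new_theta, Vs, X, y)

        denom = np.maximum(np.abs(theta), floor * 10)
        rel_change = float(np.max(np.abs(new_theta - theta) / denom))
        theta, ll = new_theta, ll_new
        if rel_change < tol:
            converged = True
            break

    vc = VarianceComponents(dict(zip(labels, theta)))
    info = {"loglik": ll, "n_iter": it, "converged": converged,
            "change": rel_change, "floor": floor, "method": method}
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations "
            f"(last max relative change {rel_change:.3g})",
            components=vc, change=rel_change,
        )
    at_floor = [l for l, t in zip(labels, theta) if t <= floor * (1 + 1e-9)]
    if at_floor:
        logger.info("reml_estimate: components at floor: %s", at_floor)
    logger.info("reml_estimate: converged in %d iterations (logL=%.4f)", it, ll)
    return vc, info


def _term_slices(design: DesignBundle, p: int):
    out = {}
    start = p
    for t in design.terms:
        out[t.name] = slice(start, start + t.Z.shape[1])
        start += t.Z.shape[1]
    return out, start


def solve_mme(design: DesignBundle, vc: VarianceComponents) -> ModelFit:
    """Solve Henderson's mixed-model equations at the given components.

    Returns GLS fixed-effect estimates, BLUPs for every random term, and PEV
    (the corresponding diagonal of the inverse coefficient matrix) for the
    genetic and clone terms. A singular genetic covariance is blended toward
    the identity (0.99 K + 0.01 I) before inversion, with a log message.
    """
    y, X = design.y, design.X
    n, p = X.shape
    theta = np.array([vc[l] for l in design.param_labels])
    if np.any(theta <= 0):
        raise ValueError("solve_mme: all variance components must be strictly positive")

    n_resid = len(design.site_names)
    resid = theta[-n_resid:]
    r_inv = 1.0 / resid[design.obs_site]

    Zs = [t.Z for t in design.terms]
    W = np.column_stack([X] + Zs) if Zs else X
    slices, total = _term_slices(design, p)

    Dinv = np.zeros((total - p, total - p))
    k = 0
    off = 0
    for t in design.terms:
        qt = t.Z.shape[1]
        sl = slice(off, off + qt)
        if t.K is not None:
            sigma2 = theta[k]
            K = t.K
            try:
                Kc = cho_factor(K, lower=True, check_finite=False)
                Kinv = cho_solve(Kc, np.eye(qt), check_finite=False)
            except np.linalg.LinAlgError:
                logger.info("solve_mme: %s covariance singular; blending 0.99K + 0.01I", t.name)
                Kb = 0.99 * K + 0.01 * np.eye(qt)
                Kinv = np.linalg.inv(Kb)
            Dinv[sl, sl] = Kinv / sigma2
            k += 1
        else:
            ngroups = len(t.group_names)
            lv_theta = theta[k: k + ngroups][t.groups]
            Dinv[sl, sl] = np.diag(1.0 / lv_theta)
            k += ngroups
        off += qt

    WtRi = W.T * r_inv
    C = WtRi @ W
    C[p:, p:] += Dinv
    rhs = WtRi @ y
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "solve_mme: singular coefficient matrix; consider blending the "
            "genetic covariance toward the identity"
        ) from e
    sol = Cinv @ rhs

    beta = pd.Series(sol[:p], index=design.fixed_names, name="beta")
    blups: dict[str, pd.Series] = {}
    pev: dict[str, pd.Series] = {}
    for t in design.terms:
        sl = slices[t.name]
        blups[t.name] = pd.Series(sol[sl], index=t.levels, name=t.name)
        if t.K is not None or t.name == "clone":
            pev[t.name] = pd.Series(np.diag(Cinv)[sl.start: sl.stop], index=t.levels, name="pev")
    return ModelFit(spec=None, vc=vc.copy(), beta=beta, blups=blups, pev=pev,
                    loglik=None, n_iter=0, converged=True, design=design)


def _select_trait(pheno: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    if "trait" in pheno.columns:
        traits = pheno["trait"].unique()
        if trait is None:
            if len(traits) > 1:
                raise ValueError(f"multiple traits present ({list(traits)}); pass trait=")
            trait = traits[0]
        pheno = pheno[pheno["trait"] == trait]
        if pheno.empty:
            raise ValueError(f"no phenotypes for trait {trait!r}")
    return pheno


def _as_A(ped) -> pd.DataFrame:
    if isinstance(ped, Pedigree):
        if not (ped.sorted and is_sorted(ped)):
            ped = sort_pedigree(ped)
        return build_A(ped)
    return ped


def fit_ablup(
    pheno: pd.DataFrame,
    ped,
    spec: ModelSpec | None = None,
    trait: str | None = None,
    vc: VarianceComponents | None = None,
    **reml_kw,
) -> ModelFit:
    """Pedigree BLUP: REML variance components then MME solutions (EBV = â).

    ``ped`` may be a :class:`Pedigree` or a precomputed A matrix. Passing
    ``vc`` skips REML and solves at the given components.
    """
    spec = spec or ModelSpec.ablup()
    pheno = _select_trait(pheno, trait)
    A = _as_A(ped)
    design = build_design(pheno, spec, {"A": A})
    if vc is None:
        vc, info = reml_estimate(design, **reml_kw)
    else:
        info = {"loglik": None, "n_iter": 0, "converged": True}
    fit = solve_mme(design, vc)
    fit.spec = spec
    fit.loglik = info["loglik"]
    fit.n_iter = info["n_iter"]
    fit.converged = info["converged"]
    return fit


def fit_gblup(
    pheno: pd.DataFrame,
    ped,
    Gmat: pd.DataFrame,
    spec: ModelSpec | None = None,
    trait: str | None = None,
    vc: VarianceComponents | None = None,
    blend_threshold: float = 1e-6,
    **reml_kw,
) -> ModelFit:
    """Genomic BLUP with a residual polygenic term (GEBV = m̂, plus â*).

    Phenotyped clones that are not genotyped (absent from ``Gmat`` labels) are
    excluded with a warning. A near-singular G is blended 0.99 G + 0.01 I.
    """
    spec = spec or ModelSpec.gblup()
    pheno = _select_trait(pheno, trait)
    glabels = set(map(str, Gmat.index))
    mask = pheno["clone"].astype(str).isin(glabels)
    if not mask.all():
        dropped = sorted(set(pheno.loc[~mask, "clone"].astype(str)))
        warnings.warn(
            f"fit_gblup: excluding {len(dropped)} non-genotyped phenotyped clones"
        )
        pheno = pheno[mask]
    if pheno.empty:
        raise ValueError("fit_gblup: no genotyped phenotyped clones remain")
    G = Gmat
    if min_eigenvalue(G) < blend_threshold:
        logger.info("fit_gblup: G near-singular; blending 0.99G + 0.01I")
        G = blend(G)
    A = _as_A(ped)
    design = build_design(pheno, spec, {"G": G, "A": A})
    if vc is None:
        vc, info = reml_estimate(design, **reml_kw)
    else:
        info = {"loglik": None, "n_iter": 0, "converged": True}
    fit = solve_mme(design, vc)
    fit.spec = spec
    fit.loglik = info["loglik"]
    fit.n_iter = info["n_iter"]
    fit.converged = info["converged"]
    return fit
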