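"""Synthetic breeding-trial generator with known truth.

Emulates the structure of clonally replicated conifer trial series: unrelated
founders genotyped at unlinked biallelic SNPs, progeny produced under a
single-pair or factorial mating design by Mendelian gene drop, clonal ramets
planted over several sites in a replicate / set / incomplete-block layout, and
phenotypes generated under the same additive + non-additive mixed model the
package fits. Pedigree-recording errors, genotyping errors and missing calls
are injected at configurable rates so that pedigree-correction and model
recovery can be tested against the retained truth.

Default study conditions: two series (60 founders / 200 progeny single-pair
over two sites; 24 founders / 200 progeny factorial over three sites), 2000
unlinked markers with founder MAF in [0.03, 0.5], 5% genotyping error, 8%
missing calls and a 50% pedigree-error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pinegs.pedigree import UNKNOWN, Pedigree, is_sorted, sort_pedigree

__all__ = [
    "SeriesConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_founders",
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "inject_pedigree_errors",
    "inject_genotype_noise",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SeriesConfig:
    """One trial series: a founder set, a mating design, and its planting sites."""

    name: str
    n_founders: int
    n_progeny: int
    mating: str  # "single_pair" | "factorial"
    sites: tuple[str, ...]
    ramets_per_site: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    series: tuple[SeriesConfig, ...] = (
        SeriesConfig("S2", 60, 200, "single_pair", ("TAR", "WOO")),
        SeriesConfig("S3", 24, 200, "factorial", ("KIN", "TAR", "WOO")),
    )
    n_unrelated: int = 40          # unrelated reference trees for allele frequencies
    n_markers: int = 2000
    maf_bounds: tuple[float, float] = (0.03, 0.5)
    n_qtl: int | None = None   # None = effects at every marker (infinitesimal mirror of GBLUP)
    sigma2_additive: float = 0.3   # total additive variance
    percent_va: float = 70.0       # share of additive variance at the markers
    sigma2_clone: float = 0.1      # non-additive (clone-level) variance
    sigma2_rep: float = 0.05
    sigma2_set: float = 0.05
    sigma2_block: float = 0.05
    sigma2_resid: float = 0.8      # per-site residual variance
    n_reps: int = 2
    n_sets: int = 2
    n_blocks: int = 4              # incomplete blocks per set
    trait: str = "score"
    base_mean: float = 5.0
    categorical: str | None = None  # None | "nine_point" | "zero_three"
    pedigree_error_rate: float = 0.5
    genotype_error_rate: float = 0.05
    missing_rate: float = 0.08
    seed: int = 20191227

    def __post_init__(self):
        for r in (self.pedigree_error_rate, self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 <= self.percent_va <= 100.0:
            raise ValueError("percent_va must lie in [0, 100]")

    @property
    def sigma2_marker(self) -> float:
        return self.sigma2_additive * self.percent_va / 100.0

    @property
    def sigma2_polygenic(self) -> float:
        return self.sigma2_additive * (1.0 - self.percent_va / 100.0)

    def founder_ids(self) -> list[str]:
        out = []
        for s in self.series:
            out += [f"{s.name}_F{k:03d}" for k in range(1, s.n_founders + 1)]
        return out

    def unrelated_ids(self) -> list[str]:
        return [f"U_{k:03d}" for k in range(1, self.n_unrelated + 1)]


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would not."""

    ped_true: Pedigree
    breeding_values: pd.Series          # total additive merit per individual
    marker_bv: pd.Series
    polygenic_bv: pd.Series
    marker_effects: pd.Series           # per-QTL allele substitution effects
    components: dict[str, float]
    site_means: dict[str, float]
    corrupted: list[str] = field(default_factory=list)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_founders(cfg: SimulationConfig, seed=None) -> pd.DataFrame:
    """Unrelated founder (and reference) genotypes at unlinked HWE markers.

    Per-marker minor allele frequencies are uniform on ``cfg.maf_bounds``; the
    alternate allele is the minor or major one with equal probability, and
    genotypes are Binomial(2, p) draws.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    ids = cfg.founder_ids() + cfg.unrelated_ids()
    lo, hi = cfg.maf_bounds
    maf = rng.uniform(lo, hi, size=cfg.n_markers)
    flip = rng.random(cfg.n_markers) < 0.5
    p = np.where(flip, 1.0 - maf, maf)
    G = rng.binomial(2, p, size=(len(ids), cfg.n_markers)).astype(float)
    markers = [f"M{j:05d}" for j in range(1, cfg.n_markers + 1)]
    return pd.DataFrame(G, index=ids, columns=markers)


def simulate_pedigree(cfg: SimulationConfig, seed=None) -> Pedigree:
    """True pedigree under each series' mating design.

    single_pair: founders are paired disjointly and progeny are split evenly
    among the pairs (odd founder counts are an error). factorial: crosses are
    drawn uniformly from the (sires x dams) grid formed by halving the founder
    list.
    """
    rng = _rng(cfg.seed + 1 if seed is None else seed)
    records: list[tuple[str, str, str]] = []
    for s in cfg.series:
        founders = [f"{s.name}_F{k:03d}" for k in range(1, s.n_founders + 1)]
        records += [(f, UNKNOWN, UNKNOWN) for f in founders]
        prog = [f"{s.name}_P{k:03d}" for k in range(1, s.n_progeny + 1)]
        if s.mating == "single_pair":
            if s.n_founders % 2:
                raise ValueError(f"series {s.name}: single_pair mating needs an even founder count")
            pairs = [(founders[2 * i], founders[2 * i + 1]) for i in range(s.n_founders // 2)]
            for k, pid in enumerate(prog):
                sire, dam = pairs[k % len(pairs)]
                records.append((pid, sire, dam))
        elif s.mating == "factorial":
            half = s.n_founders // 2
            sires, dams = founders[:half], founders[half:]
            for pid in prog:
                records.append((pid, str(rng.choice(sires)), str(rng.choice(dams))))
        else:
            raise ValueError(f"unknown mating design {s.mating!r}")
    records += [(u, UNKNOWN, UNKNOWN) for u in cfg.unrelated_ids()]
    return Pedigree(records, sorted=True)


def gene_drop(ped: Pedigree, founder_G: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Drop founder genotypes through the pedigree by Mendelian transmission.

    Each progeny receives, independently per marker, one uniformly chosen
    allele from each parent (a parent with dosage g transmits the alternate
    allele with probability g/2). Unknown-parent contributions are drawn from
    the founder allele frequencies.
    """
    rng = _rng(seed)
    if not (ped.sorted and is_sorted(ped)):
        ped = sort_pedigree(ped)
    markers = founder_G.columns
    m = len(markers)
    pfreq = founder_G.mean(axis=0).values / 2.0
    geno: dict[str, np.ndarray] = {}
    for i, s, d in ped.records:
        if s == UNKNOWN and d == UNKNOWN:
            if i in founder_G.index:
                geno[i] = founder_G.loc[i].values.astype(float)
            else:
                geno[i] = rng.binomial(2, pfreq).astype(float)
            continue
        dose = np.zeros(m)
        for par in (s, d):
            if par == UNKNOWN:
                dose += rng.binomial(1, pfreq)
            else:
                dose += rng.binomial(1, geno[par] / 2.0)
        geno[i] = dose
    return pd.DataFrame(
        np.vstack([geno[i] for i in ped.ids]), index=ped.ids, columns=markers
    )


def _polygenic_values(ped: Pedigree, sigma2: float, rng) -> pd.Series:
    """Additive values sampled down the pedigree (infinitesimal model)."""
    vals: dict[str, float] = {}
    sd = np.sqrt(sigma2) if sigma2 > 0 else 0.0
    for i, s, d in ped.records:
        known = [p for p in (s, d) if p != UNKNOWN]
        mid = 0.5 * sum(vals[p] for p in known)
        seg_var = sigma2 * (1.0 - 0.25 * len(known))
        vals[i] = mid + (rng.normal(0.0, np.sqrt(seg_var)) if seg_var > 0 else 0.0)
    return pd.Series(vals, dtype=float)


def _per_site(value, sites) -> dict[str, float]:
    if isinstance(value, dict):
        return {s: float(value[s]) for s in sites}
    return {s: float(value) for s in sites}


def _to_scores(y: np.ndarray, kind: str) -> np.ndarray:
    z = (y - y.mean()) / (y.std() or 1.0)
    if kind == "nine_point":
        return np.clip(np.rint(5.0 + 1.8 * z), 1, 9)
    if kind == "zero_three":
        return np.clip(np.rint(1.3 + 0.9 * z), 0, 3)
    raise ValueError(f"unknown categorical mapping {kind!r}")


def simulate_phenotypes(
    ped: Pedigree,
    genotypes: pd.DataFrame,
    cfg: SimulationConfig,
    seed=None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Clone-level repeated phenotypes under the additive + clonal trial model.

    Marker breeding values are a Gaussian-effect sum over ``n_qtl`` markers,
    rescaled so their variance across progeny equals the marker share of
    ``sigma2_additive``; the residual-polygenic share is sampled down the true
    pedigree. Site / replicate / set / block effects and residuals are drawn
    with the configured per-site variances. With ``cfg.categorical`` set, the
    latent Gaussian is mapped onto a 1-9 or 0-3 score scale.
    """
    rng = _rng(cfg.seed + 2 if seed is None else seed)
    all_sites = sorted({s for sc in cfg.series for s in sc.sites})

    n_qtl = genotypes.shape[1] if cfg.n_qtl is None else min(cfg.n_qtl, genotypes.shape[1])
    qtl = list(rng.choice(genotypes.columns, size=n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, size=len(qtl))
    M = genotypes[qtl].values.astype(float)
    raw = (M - M.mean(axis=0)) @ effects

    prog_ids = [i for i, s, d in ped.records if s != UNKNOWN or d != UNKNOWN]
    raw_series = pd.Series(raw, index=genotypes.index)
    sd_prog = raw_series.loc[[i for i in prog_ids if i in raw_series.index]].std()
    scale = np.sqrt(cfg.sigma2_marker) / sd_prog if sd_prog > 0 else 0.0
    marker_bv = raw_series * scale
    effects_scaled = pd.Series(effects * scale, index=qtl, name="effect")

    polygenic_bv = _polygenic_values(ped, cfg.sigma2_polygenic, rng)
    bv = marker_bv.reindex(ped.ids).fillna(0.0) + polygenic_bv.reindex(ped.ids).fillna(0.0)

    site_means = {s: cfg.base_mean + off for s, off in
                  zip(all_sites, np.linspace(-0.4, 0.4, len(all_sites)))}
    s2_rep = _per_site(cfg.sigma2_rep, all_sites)
    s2_set = _per_site(cfg.sigma2_set, all_sites)
    s2_blk = _per_site(cfg.sigma2_block, all_sites)
    s2_res = _per_site(cfg.sigma2_resid, all_sites)

    clone_dev = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.sigma2_clone), size=len(prog_ids)), index=prog_ids
    )

    rows = []
    for sc in cfg.series:
        prog = [f"{sc.name}_P{k:03d}" for k in range(1, sc.n_progeny + 1)]
        for site in sc.sites:
            rep_eff = {r: rng.normal(0, np.sqrt(s2_rep[site])) for r in range(1, cfg.n_reps + 1)}
            set_eff = {(r, w): rng.normal(0, np.sqrt(s2_set[site]))
                       for r in rep_eff for w in range(1, cfg.n_sets + 1)}
            blk_eff = {(r, w, b): rng.normal(0, np.sqrt(s2_blk[site]))
                       for (r, w) in set_eff for b in range(1, cfg.n_blocks + 1)}
            for clone in prog:
                for _ in range(sc.ramets_per_site):
                    r = int(rng.integers(1, cfg.n_reps + 1))
                    w = int(rng.integers(1, cfg.n_sets + 1))
                    b = int(rng.integers(1, cfg.n_blocks + 1))
                    val = (site_means[site] + bv[clone] + clone_dev[clone]
                           + rep_eff[r] + set_eff[(r, w)] + blk_eff[(r, w, b)]
                           + rng.normal(0, np.sqrt(s2_res[site])))
                    rows.append((clone, site, f"R{r}", f"S{w}", f"B{b}", cfg.trait, val))
    pheno = pd.DataFrame(rows, columns=["clone", "site", "rep", "set", "block", "trait", "value"])
    if cfg.categorical:
        pheno["value"] = _to_scores(pheno["value"].values, cfg.categorical)

    truth = SyntheticTruth(
        ped_true=ped,
        breeding_values=bv.rename("bv"),
        marker_bv=marker_bv.reindex(ped.ids).fillna(0.0).rename("marker_bv"),
        polygenic_bv=polygenic_bv.reindex(ped.ids).rename("polygenic_bv"),
        marker_effects=effects_scaled,
        components={
            "marker": cfg.sigma2_marker, "polygenic": cfg.sigma2_polygenic,
            "additive": cfg.sigma2_additive, "clone": cfg.sigma2_clone,
            **{f"rep:{s}": s2_rep[s] for s in all_sites},
            **{f"set:{s}": s2_set[s] for s in all_sites},
            **{f"block:{s}": s2_blk[s] for s in all_sites},
            **{f"residual:{s}": s2_res[s] for s in all_sites},
        },
        site_means=site_means,
    )
    return pheno, truth


def inject_pedigree_errors(
    ped: Pedigree, rate: float, candidates: list[str], seed=None
) -> tuple[Pedigree, list[str]]:
    """Corrupt a random ``round(rate x n_progeny)`` subset of progeny records.

    Each corrupted progeny has one or both parents replaced by a different
    candidate parent, mimicking documentation errors. Returns the corrupted
    pedigree and the list of altered progeny ids.
    """
    rng = _rng(seed)
    candidates = sorted(set(candidates))
    if len(candidates) < 2:
        raise ValueError("inject_pedigree_errors: need at least 2 candidate parents")
    parents = ped.parents
    prog = [i for i, (s, d) in parents.items() if s != UNKNOWN or d != UNKNOWN]
    n_bad = int(round(rate * len(prog)))
    bad = sorted(rng.choice(prog, size=n_bad, replace=False)) if n_bad else []
    new_parents = dict(parents)
    for pid in bad:
        s, d = parents[pid]
        both = rng.random() < 0.5
        slots = [0, 1] if both else [int(rng.integers(0, 2))]
        cur = [s, d]
        for slot in slots:
            repl = str(rng.choice(candidates))
            tries = 0
            while repl == cur[slot] and tries < 100:
                repl = str(rng.choice(candidates))
                tries += 1
            if repl == cur[slot]:
                raise ValueError("inject_pedigree_errors: cannot draw a different parent")
            cur[slot] = repl
        new_parents[pid] = (cur[0], cur[1])
    records = [(i, *new_parents[i]) for i in ped.ids]
    return Pedigree(records, sorted=False), list(map(str, bad))


def inject_genotype_noise(
    G: pd.DataFrame, error_rate: float, missing_rate: float, seed=None
) -> pd.DataFrame:
    """Add genotyping errors then missing calls, entrywise and independently.

    An erroneous entry is replaced by a uniformly chosen *different* genotype
    in {0, 1, 2}; a missing entry becomes NaN.
    """
    rng = _rng(seed)
    vals = G.values.astype(float).copy()
    if error_rate > 0:
        err = rng.random(vals.shape) < error_rate
        shift = rng.integers(1, 3, size=vals.shape)  # +1 or +2 mod 3 => different genotype
        vals = np.where(err, (vals + shift) % 3, vals)
    if missing_rate > 0:
        vals[rng.random(vals.shape) < missing_rate] = np.nan
    return pd.DataFrame(vals, index=G.index, columns=G.columns)


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None) -> dict:
    """Generate a complete study: truth, corrupted pedigree, noisy genotypes.

    Returns a dict with keys ``ped_true``, ``ped_documented``, ``genotypes``
    (noisy), ``genotypes_clean``, ``pheno``, ``truth``, ``config``.
    """
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(5)
    rngs = [np.random.default_rng(s) for s in ss]

    founders = simulate_founders(cfg, seed=rngs[0])
    ped_true = simulate_pedigree(cfg, seed=rngs[1])
    geno_clean = gene_drop(ped_true, founders, seed=rngs[2])
    pheno, truth = simulate_phenotypes(ped_true, geno_clean, cfg, seed=rngs[3])

    candidates = [f for sc in cfg.series
                  for f in [f"{sc.name}_F{k:03d}" for k in range(1, sc.n_founders + 1)]]
    ped_doc, corrupted = (
        inject_pedigree_errors(ped_true, cfg.pedigree_error_rate, candidates, seed=rngs[4])
        if cfg.pedigree_error_rate > 0 else (ped_true, [])
    )
    truth.corrupted = corrupted
    geno = inject_genotype_noise(
        geno_clean, cfg.genotype_error_rate, cfg.missing_rate, seed=rngs[4]
    )
    return {
        "ped_true": ped_true,
        "ped_documented": ped_doc,
        "genotypes": geno,
        "genotypes_clean": geno_clean,
        "pheno": pheno,
        "truth": truth,
        "config": cfg,
    }
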