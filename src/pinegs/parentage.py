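"""Exclusion-based trio parentage assignment and pedigree correction.

A trio (progeny, parent1, parent2) is *excluded* at a SNP when the progeny
genotype cannot be formed from one transmitted allele of each candidate
parent. Candidate pairs are scored by their exclusion count over an
informative marker panel and the minimum-exclusion pair is assigned, which is
the classical exclusion analysis used for pedigree reconstruction in conifer
breeding populations.

Panel selection mirrors the customary criteria: high call rate, MAF close to
0.5 (maximally informative), Hardy-Weinberg equilibrium (exact test), and no
pairwise linkage disequilibrium.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pinegs.genomat import allele_freq, call_rate, minor_allele_freq
from pinegs.pedigree import UNKNOWN, Pedigree

logger = logging.getLogger(__name__)

# _COMPAT[g1, g2, gc] is True when a child genotype gc is attainable from one
# transmitted allele of a parent with genotype g1 and one of a parent with
# genotype g2. Index 3 encodes "missing" and is permissive (markers with any
# missing member are skipped as uninformative before this table is consulted).
_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}
_COMPAT = np.ones((4, 4, 4), dtype=bool)
for _g1 in range(3):
    for _g2 in range(3):
        ok = {a + b for a in _ALLELES[_g1] for b in _ALLELES[_g2]}
        for _gc in range(3):
            _COMPAT[_g1, _g2, _gc] = _gc in ok


@dataclass
class MarkerPanel:
    """A parentage marker panel with the per-marker statistics that selected it."""

    markers: list[str]
    stats: pd.DataFrame  # index = markers, columns: call_rate, maf, hwe_p
    removed: dict[str, int] = field(default_factory=dict)  # per-criterion removal counts

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class TrioAssignment:
    progeny: str
    parent1: str
    parent2: str
    exclusions: int
    informative: int
    status: str  # confirmed | reassigned | unassigned

    @property
    def pair(self) -> frozenset:
        return frozenset((self.parent1, self.parent2))


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value for a biallelic SNP.

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, conditional on the allele counts (the standard SNP exact
    test). Returns 1.0 for monomorphic markers.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if n == 0 or n_rare == 0:
        return 1.0
    # log-probability of each possible het count with the same allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    n_common = 2 * n - n_rare

    def logp(h):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        return (
            h * np.log(2.0)
            + gammaln(n + 1) - gammaln(h + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(n_common + 1))
        )

    lp = logp(hets.astype(float))
    p = np.exp(lp - lp.max())
    p /= p.sum()
    obs = p[hets == n_het]
    if len(obs) == 0:  # inconsistent het parity (cannot happen for real data)
        return 1.0
    return float(min(1.0, p[p <= obs[0] + 1e-12].sum()))


def _hwe_pvalues(G: pd.DataFrame) -> pd.Series:
    out = {}
    for m in G.columns:
        col = G[m].dropna().astype(int)
        out[m] = hwe_exact_p(int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum()))
    return pd.Series(out, name="hwe_p")


def _ld_prune(G: pd.DataFrame, markers: list[str], order: pd.Series, r2_max: float) -> list[str]:
    """Greedy LD prune: walk markers by descending call rate, keep a marker only
    if its squared correlation with every kept marker is <= r2_max."""
    ordered = sorted(markers, key=lambda m: (-order[m], m))
    X = G[ordered].values.astype(float)
    kept_idx: list[int] = []
    for j in range(len(ordered)):
        xj = X[:, j]
        ok = True
        for i in kept_idx:
            xi = X[:, i]
            mask = ~(np.isnan(xi) | np.isnan(xj))
            if mask.sum() < 3:
                continue
            a, b = xi[mask], xj[mask]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept_idx.append(j)
    return [ordered[j] for j in kept_idx]


def select_panel(
    G: pd.DataFrame,
    call_rate_min: float = 0.75,
    maf_range: tuple[float, float] = (0.35, 0.5),
    hwe_alpha: float = 0.05,
    ld_r2_max: float = 0.2,
    max_markers: int = 704,
    reference: list[str] | None = None,
) -> MarkerPanel:
    """Select a parentage panel of highly informative, well-behaved SNPs.

    Markers must have call rate > ``call_rate_min``, MAF within ``maf_range``
    (computed on ``reference`` individuals when given), an exact HWE test
    p-value >= ``hwe_alpha``, and pass a greedy pairwise LD prune at
    ``ld_r2_max`` (higher call rate wins ties). The panel is finally capped at
    the ``max_markers`` best-call-rate markers.
    """
    cr = call_rate(G)
    p = allele_freq(G, reference=reference)
    maf = minor_allele_freq(p)

    removed: dict[str, int] = {}
    markers = list(G.columns)
    keep = [m for m in markers if cr[m] > call_rate_min]
    removed["call_rate"] = len(markers) - len(keep)
    n0 = len(keep)
    keep = [m for m in keep if maf_range[0] <= maf[m] <= maf_range[1]]
    removed["maf"] = n0 - len(keep)

    hwe = _hwe_pvalues(G[keep])
    n0 = len(keep)
    keep = [m for m in keep if hwe[m] >= hwe_alpha]
    removed["hwe"] = n0 - len(keep)

    n0 = len(keep)
    keep = _ld_prune(G, keep, cr, ld_r2_max)
    removed["ld"] = n0 - len(keep)

    if not keep:
        raise ValueError(
            "select_panel: no markers satisfy all criteria; relax the thresholds"
        )
    if len(keep) > max_markers:
        keep = sorted(keep, key=lambda m: (-cr[m], m))[:max_markers]
    keep = [m for m in G.columns if m in set(keep)]  # genotype-file order

    stats = pd.DataFrame({"call_rate": cr, "maf": maf}).loc[keep]
    stats["hwe_p"] = hwe.reindex(keep)
    logger.info("select_panel: retained %d markers (removed %s)", len(keep), removed)
    return MarkerPanel(markers=keep, stats=stats, removed=removed)


def _as_codes(v: np.ndarray) -> np.ndarray:
    """Float dosage vector -> int codes with 3 for missing."""
    out = np.full(v.shape, 3, dtype=np.int8)
    ok = ~np.isnan(v)
    out[ok] = np.rint(v[ok]).astype(np.int8)
    return out


def trio_exclusions(progeny_g, p1_g, p2_g) -> tuple[int, int]:
    """Count Mendelian exclusions for one trio over a marker panel.

    Markers with a missing genotype in any of the three members are skipped.
    Returns (exclusions, informative markers). Symmetric in the two parents.
    """
    c = _as_codes(np.asarray(progeny_g, dtype=float))
    a = _as_codes(np.asarray(p1_g, dtype=float))
    b = _as_codes(np.asarray(p2_g, dtype=float))
    if not (len(c) == len(a) == len(b)):
        raise ValueError("trio_exclusions: genotype vectors differ in length")
    informative = (c < 3) & (a < 3) & (b < 3)
    compat = _COMPAT[a, b, c]
    return int((~compat & informative).sum()), int(informative.sum())


def assign_parentage(
    progeny: str,
    candidates: list[str],
    G: pd.DataFrame,
    panel: MarkerPanel,
    documented: Pedigree,
    max_exclusion_rate: float = 0.15,
) -> TrioAssignment:
    """Assign the minimum-exclusion candidate parent pair to a progeny.

    All unordered candidate pairs are evaluated, including the same parent
    twice (selfing). Ties prefer the documented pair, then the pair with more
    informative markers, then lexicographic order. The trio is *confirmed*
    when the winning pair equals the documented one, *reassigned* otherwise,
    and *unassigned* when even the best pair's exclusion rate exceeds
    ``max_exclusion_rate``. Three genotypes enter every trio, so the default
    tolerance is about three times the typical per-genotype error rate (~5%).
    """
    if progeny not in G.index:
        raise ValueError(f"assign_parentage: progeny {progeny!r} not genotyped")
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("assign_parentage: empty candidate set")
    missing = [c for c in candidates if c not in G.index]
    if missing:
        raise ValueError(f"assign_parentage: candidates not genotyped: {missing[:10]}")

    cols = panel.markers
    child = _as_codes(G.loc[progeny, cols].values.astype(float))
    P = np.stack([_as_codes(G.loc[c, cols].values.astype(float)) for c in candidates])

    pairs = list(itertools.combinations_with_replacement(range(len(candidates)), 2))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    informative = (P[ii] < 3) & (P[jj] < 3) & (child[None, :] < 3)
    compat = _COMPAT[P[ii], P[jj], child[None, :]]
    excl = (~compat & informative).sum(axis=1)
    ninf = informative.sum(axis=1)

    doc_pair = frozenset(documented.parents.get(progeny, (UNKNOWN, UNKNOWN)))
    best = excl.min()
    tied = [k for k in range(len(pairs)) if excl[k] == best]

    def pair_labels(k):
        return tuple(sorted((candidates[ii[k]], candidates[jj[k]])))

    if len(tied) > 1:
        doc_hits = [k for k in tied if frozenset(pair_labels(k)) == doc_pair]
        if doc_hits:
            tied = doc_hits
        else:
            max_inf = max(ninf[k] for k in tied)
            tied = [k for k in tied if ninf[k] == max_inf]
            tied.sort(key=pair_labels)
        if len(tied) > 1:
            logger.info(
                "assign_parentage: %s has %d tied minimum-exclusion pairs; "
                "deterministic tie-break applied", progeny, len(tied),
            )
    k = tied[0]
    p1, p2 = pair_labels(k)
    n_inf = int(ninf[k])
    rate = (best / n_inf) if n_inf else np.inf
    if rate > max_exclusion_rate:
        status = "unassigned"
    elif frozenset((p1, p2)) == doc_pair:
        status = "confirmed"
    else:
        status = "reassigned"
    return TrioAssignment(progeny, p1, p2, int(best), n_inf, status)


def correct_pedigree(
    documented: Pedigree, assignments: list[TrioAssignment]
) -> tuple[Pedigree, dict]:
    """Substitute assigned parent pairs into the documented pedigree.

    Unassigned progeny keep their documented parents (flagged in the log).
    The summary reports the fraction of trios confirmed, the fraction of
    parent slots re-assigned, and distinct parent counts before/after.
    """
    parents = documented.parents
    known = set(documented.ids)
    for a in assignments:
        if a.progeny not in known:
            raise ValueError(f"correct_pedigree: assignment for unknown progeny {a.progeny!r}")

    new_parents = dict(parents)
    n_conf = n_reassigned_slots = n_slots = 0
    for a in assignments:
        doc = parents[a.progeny]
        if a.status == "unassigned":
            logger.warning("correct_pedigree: %s unassigned; keeping documented parents", a.progeny)
            continue
        new = (a.parent1, a.parent2)
        # multiset overlap between documented and assigned pairs
        doc_ms = sorted(doc)
        new_ms = sorted(new)
        overlap = 0
        pool = list(new_ms)
        for x in doc_ms:
            if x in pool:
                pool.remove(x)
                overlap += 1
        n_slots += 2
        n_reassigned_slots += 2 - overlap
        if a.status == "confirmed":
            n_conf += 1
            new = doc  # same unordered pair; keep documented orientation
        new_parents[a.progeny] = new

    assigned = [a for a in assignments if a.status != "unassigned"]
    parents_before = {p for i, (s, d) in parents.items() for p in (s, d) if p != UNKNOWN}
    parents_after = {p for i, (s, d) in new_parents.items() for p in (s, d) if p != UNKNOWN}
    summary = {
        "n_progeny": len(assignments),
        "n_assigned": len(assigned),
        "n_unassigned": len(assignments) - len(assigned),
        "pct_confirmed": 100.0 * n_conf / len(assignments) if assignments else float("nan"),
        "pct_parents_reassigned": 100.0 * n_reassigned_slots / n_slots if n_slots else float("nan"),
        "n_parents_before": len(parents_before),
        "n_parents_after": len(parents_after),
    }
    records = [(i, *new_parents[i]) for i in documented.ids]
    return Pedigree(records), summary


def assignment_report(assignments: list[TrioAssignment], documented: Pedigree) -> pd.DataFrame:
    """Tabular assignment report (one row per progeny)."""
    parents = documented.parents
    rows = []
    for a in assignments:
        s, d = parents.get(a.progeny, (UNKNOWN, UNKNOWN))
        rows.append(
            dict(
                progeny=a.progeny, documented_sire=s, documented_dam=d,
                assigned_p1=a.parent1, assigned_p2=a.parent2,
                exclusions=a.exclusions, informative=a.informative, status=a.status,
            )
        )
    return pd.DataFrame(rows)
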