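"""Parentage panel selection, trio exclusions and pedigree correction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pinegs import (
    Pedigree,
    SimulationConfig,
    assign_parentage,
    correct_pedigree,
    select_panel,
    simulate_dataset,
    trio_exclusions,
)
from pinegs.parentage import MarkerPanel, TrioAssignment, hwe_exact_p
from pinegs.simulate import SeriesConfig


def brute_force_exclusions(child, p1, p2):
    """Oracle: enumerate the four transmitted-allele combinations per SNP."""
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    excl = inf = 0
    for c, a, b in zip(child, p1, p2):
        if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in (c, a, b)):
            continue
        inf += 1
        possible = {x + y for x, y in itertools.product(alleles[int(a)], alleles[int(b)])}
        if int(c) not in possible:
            excl += 1
    return excl, inf


class TestTrioExclusions:
    @pytest.mark.parametrize(
        "child,p1,p2,expected",
        [
            ([2], [0], [0], (1, 1)),   # AA child of aa x aa impossible
            ([2], [2], [0], (1, 1)),   # AA x aa can only give Aa
            ([1], [2], [0], (0, 1)),
            ([1], [1], [1], (0, 1)),   # het x het allows everything
            ([np.nan], [1], [1], (0, 0)),  # missing member -> uninformative
            ([0], [1], [np.nan], (0, 0)),
        ],
    )
    def test_single_snp_cases(self, child, p1, p2, expected):
        assert trio_exclusions(child, p1, p2) == expected

    def test_symmetric_in_parents(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, a, b = (rng.integers(0, 3, 30).astype(float) for _ in range(3))
            assert trio_exclusions(c, a, b) == trio_exclusions(c, b, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(3, 40)).astype(float)
        g[rng.random(g.shape) < 0.15] = np.nan
        assert trio_exclusions(g[0], g[1], g[2]) == brute_force_exclusions(*g)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            trio_exclusions([0, 1], [0], [0])

    def test_true_trio_has_zero_exclusions_under_gene_drop(self):
        cfg = SimulationConfig(
            series=(SeriesConfig("T", 10, 30, "factorial", ("A",)),),
            n_unrelated=0, n_markers=200,
            pedigree_error_rate=0.0, genotype_error_rate=0.0, missing_rate=0.0, seed=5,
        )
        data = simulate_dataset(cfg)
        geno, ped = data["genotypes"], data["ped_true"]
        for prog, (s, d) in ped.parents.items():
            if s == "0":
                continue
            excl, inf = trio_exclusions(geno.loc[prog], geno.loc[s], geno.loc[d])
            assert excl == 0 and inf == 200


class TestPanel:
    def _geno(self, rng, n, freqs):
        return pd.DataFrame(
            rng.binomial(2, freqs, size=(n, len(freqs))).astype(float),
            index=[f"I{k}" for k in range(n)],
            columns=[f"M{j}" for j in range(len(freqs))],
        )

    def test_maf_window_applied(self):
        rng = np.random.default_rng(1)
        G = self._geno(rng, 400, np.array([0.10, 0.40, 0.50]))
        panel = select_panel(G, maf_range=(0.35, 0.5), ld_r2_max=1.0, hwe_alpha=0.0)
        assert set(panel.markers) == {"M1", "M2"}
        assert panel.removed["maf"] == 1

    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(2)
        G = self._geno(rng, 100, np.full(5, 0.4))
        G.iloc[:30, 0] = np.nan  # call rate 0.70 < 0.75
        panel = select_panel(G, ld_r2_max=1.0, hwe_alpha=0.0)
        assert "M0" not in panel.markers and panel.removed["call_rate"] == 1

    def test_duplicated_marker_pruned_by_ld(self):
        rng = np.random.default_rng(3)
        G = self._geno(rng, 200, np.full(4, 0.4))
        G["M3"] = G["M0"]  # r2 = 1 duplicate
        panel = select_panel(G, ld_r2_max=0.2, hwe_alpha=0.0)
        assert ("M0" in panel.markers) != ("M3" in panel.markers)

    def test_hwe_violating_marker_removed(self):
        rng = np.random.default_rng(4)
        G = self._geno(rng, 300, np.full(3, 0.4))
        G["M0"] = np.where(rng.random(300) < 0.45, 0.0, 2.0)  # no hets at p ~ 0.45
        panel = select_panel(G, ld_r2_max=1.0)
        assert "M0" not in panel.markers

    def test_empty_panel_raises(self):
        rng = np.random.default_rng(5)
        G = self._geno(rng, 100, np.full(3, 0.05))  # all MAF below the window
        with pytest.raises(ValueError, match="relax"):
            select_panel(G)

    def test_hwe_exact_matches_enumeration(self):
        # 57 AA / 14 Aa / 50 aa is grossly out of equilibrium
        assert hwe_exact_p(14, 57, 50) < 1e-6
        # perfectly proportioned genotypes are not rejected
        assert hwe_exact_p(50, 25, 25) > 0.3
        assert hwe_exact_p(0, 100, 0) == 1.0  # monomorphic


class TestAssignment:
    def test_minimum_exclusion_pair_wins_and_confirms(self):
        # child is het at every SNP; (S1,D1) compatible, (S2,D2) opposite homozygotes
        geno = pd.DataFrame(
            {
                "M0": [1, 0, 2, 0, 0],
                "M1": [1, 0, 2, 0, 0],
                "M2": [1, 2, 0, 2, 2],
            },
            index=["C", "S1", "D1", "S2", "D2"],
            dtype=float,
        )
        panel = MarkerPanel(markers=["M0", "M1", "M2"], stats=pd.DataFrame())
        ped = Pedigree([("C", "S1", "D1")])
        a = assign_parentage("C", ["S1", "D1", "S2", "D2"], geno, panel, ped)
        assert {a.parent1, a.parent2} == {"S1", "D1"}
        assert a.exclusions == 0 and a.status == "confirmed"

    def test_ungenotyped_progeny_rejected(self, small_dataset):
        panel = MarkerPanel(markers=list(small_dataset["genotypes"].columns[:50]),
                            stats=pd.DataFrame())
        with pytest.raises(ValueError, match="not genotyped"):
            assign_parentage("nope", ["S1_F001"], small_dataset["genotypes"],
                             panel, small_dataset["ped_true"])

    def test_gene_drop_recovery_with_genotype_error(self):
        """>= 95% of progeny recover their true pair (20 parents, 50 progeny,
        300 SNPs, 5% genotyping error)."""
        cfg = SimulationConfig(
            series=(SeriesConfig("T", 20, 50, "factorial", ("A",)),),
            n_unrelated=0, n_markers=300, maf_bounds=(0.1, 0.5),
            pedigree_error_rate=0.0, genotype_error_rate=0.05, missing_rate=0.08, seed=17,
        )
        data = simulate_dataset(cfg)
        geno, ped = data["genotypes"], data["ped_true"]
        panel = MarkerPanel(markers=list(geno.columns), stats=pd.DataFrame())
        cands = [i for i, (s, d) in ped.parents.items() if s == "0"]
        hits = total = 0
        for prog, (s, d) in ped.parents.items():
            if s == "0":
                continue
            a = assign_parentage(prog, cands, geno, panel, ped)
            total += 1
            hits += {a.parent1, a.parent2} == {s, d}
        assert hits / total >= 0.95


class TestCorrection:
    def _assignments(self, ped, results):
        out = []
        for prog, (p1, p2) in results.items():
            doc = frozenset(ped.parents[prog])
            status = "confirmed" if frozenset((p1, p2)) == doc else "reassigned"
            out.append(TrioAssignment(prog, p1, p2, 0, 100, status))
        return out

    def test_all_confirmed_identity(self):
        ped = Pedigree([("C1", "S", "D"), ("C2", "S", "D")])
        assignments = self._assignments(ped, {"C1": ("S", "D"), "C2": ("D", "S")})
        corrected, summary = correct_pedigree(ped, assignments)
        assert corrected == ped
        assert summary["pct_confirmed"] == 100.0
        assert summary["pct_parents_reassigned"] == 0.0

    def test_zero_confirmed(self):
        ped = Pedigree([("C1", "S", "D"), ("C2", "S", "D"), ("E", "0", "0"), ("F", "0", "0")])
        assignments = self._assignments(ped, {"C1": ("E", "F"), "C2": ("E", "F")})
        corrected, summary = correct_pedigree(ped, assignments)
        assert summary["pct_confirmed"] == 0.0
        assert corrected.parents["C1"] == ("E", "F")

    def test_unknown_progeny_rejected(self):
        ped = Pedigree([("C1", "S", "D")])
        with pytest.raises(ValueError, match="unknown progeny"):
            correct_pedigree(ped, [TrioAssignment("ghost", "S", "D", 0, 10, "confirmed")])

    def test_injected_error_rate_recovered(self):
        """End-to-end: 50% injected documentation errors -> confirmed fraction
        tracks 50% within binomial noise, and true pairs are recovered."""
        cfg = SimulationConfig(
            series=(SeriesConfig("T", 20, 80, "factorial", ("A",)),),
            n_unrelated=0, n_markers=300, maf_bounds=(0.1, 0.5),
            pedigree_error_rate=0.5, genotype_error_rate=0.05, missing_rate=0.08, seed=23,
        )
        data = simulate_dataset(cfg)
        geno, doc, true = data["genotypes"], data["ped_documented"], data["ped_true"]
        panel = MarkerPanel(markers=list(geno.columns), stats=pd.DataFrame())
        cands = [i for i, (s, d) in doc.parents.items() if s == "0"]
        assignments = [
            assign_parentage(prog, cands, geno, panel, doc)
            for prog, (s, d) in doc.parents.items() if s != "0"
        ]
        corrected, summary = correct_pedigree(doc, assignments)
        n = summary["n_progeny"]
        sigma = 100 * np.sqrt(0.25 / n)
        assert abs(summary["pct_confirmed"] - 50.0) <= 3.5 * sigma
        recovered = np.mean([
            corrected.parents[p] in ((s, d), (d, s))
            for p, (s, d) in true.parents.items() if s != "0"
        ])
        assert recovered >= 0.9
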