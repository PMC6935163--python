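"""Mixed-model engine: design construction, REML, and MME solutions."""

import numpy as np
import pandas as pd
import pytest

from pinegs import (
    ModelSpec,
    SimulationConfig,
    build_A,
    build_design,
    fit_ablup,
    fit_gblup,
    reml_estimate,
    simulate_dataset,
    solve_mme,
    sort_pedigree,
)
from pinegs.mixed_model import VarianceComponents
from pinegs.simulate import SeriesConfig


def _pheno(rows):
    return pd.DataFrame(rows, columns=["clone", "site", "rep", "set", "block", "trait", "value"])


def gls_oracle(design, vc):
    """Direct GLS/BLUP oracle on the observation-level covariance V.

    Independent of the MME route: builds V = sum_k Z_k D_k Z_k' + R explicitly,
    then beta = (X'V^-1 X)^-1 X'V^-1 y and u_k = D_k Z_k' V^-1 (y - X beta),
    with PEV_k = diag(D_k - D_k Z_k' P Z_k D_k).
    """
    y, X = design.y, design.X
    n = len(y)
    theta = [vc[l] for l in design.param_labels]
    k = 0
    Ds = []
    V = np.zeros((n, n))
    for t in design.terms:
        q = t.Z.shape[1]
        if t.K is not None:
            D = theta[k] * t.K
            k += 1
        else:
            ngroups = len(t.group_names)
            lv = np.array(theta[k:k + ngroups])[t.groups]
            D = np.diag(lv)
            k += ngroups
        Ds.append(D)
        V += t.Z @ D @ t.Z.T
    resid = np.array(theta[k:])
    V += np.diag(resid[design.obs_site])
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    M = XtVi @ X
    beta = np.linalg.solve(M, XtVi @ y)
    P = Vinv - XtVi.T @ np.linalg.solve(M, XtVi)
    resid_vec = y - X @ beta
    blups, pevs = {}, {}
    for t, D in zip(design.terms, Ds):
        u = D @ t.Z.T @ Vinv @ resid_vec
        pev = np.diag(D - D @ t.Z.T @ P @ t.Z @ D)
        blups[t.name] = pd.Series(u, index=t.levels)
        pevs[t.name] = pd.Series(pev, index=t.levels)
    return beta, blups, pevs


class TestBuildDesign:
    def test_clone_incidence_maps_ramets(self):
        ph = _pheno([("c1", "s1", "r1", "x", "b1", "t", 1.0),
                     ("c1", "s1", "r1", "x", "b1", "t", 2.0),
                     ("c2", "s1", "r1", "x", "b1", "t", 3.0),
                     ("c2", "s1", "r1", "x", "b1", "t", 4.0)])
        K = pd.DataFrame(np.eye(2), index=["c1", "c2"], columns=["c1", "c2"])
        d = build_design(ph, ModelSpec(genetic=(("additive", "A"),), env_terms=()), {"A": K})
        Za = d.terms[0].Z
        assert Za.shape == (4, 2)
        assert (Za.sum(axis=0) == 2).all()

    def test_single_site_absorbed_into_intercept(self):
        ph = _pheno([("c1", "s1", "r1", "x", "b1", "t", 1.0),
                     ("c2", "s1", "r1", "x", "b2", "t", 2.0)])
        K = pd.DataFrame(np.eye(2), index=["c1", "c2"], columns=["c1", "c2"])
        d = build_design(ph, ModelSpec(genetic=(("additive", "A"),)), {"A": K})
        assert d.fixed_names == ["intercept"]

    def test_unique_blocks_give_identity_incidence(self):
        rows = [(f"c{i}", "s1", "r1", "x", f"b{i}", "t", float(i)) for i in range(5)]
        K = pd.DataFrame(np.eye(5), index=[f"c{i}" for i in range(5)],
                         columns=[f"c{i}" for i in range(5)])
        d = build_design(_pheno(rows), ModelSpec(genetic=(("additive", "A"),)), {"A": K})
        blk = next(t for t in d.terms if t.name == "block")
        assert np.allclose(blk.Z, np.eye(5))

    def test_missing_clone_in_covariance_named(self):
        ph = _pheno([("c9", "s1", "r1", "x", "b1", "t", 1.0)])
        K = pd.DataFrame(np.eye(1), index=["c1"], columns=["c1"])
        with pytest.raises(ValueError, match="c9"):
            build_design(ph, ModelSpec(genetic=(("additive", "A"),)), {"A": K})

    def test_absent_stratum_dropped_with_warning(self):
        ph = _pheno([("c1", "s1", "r1", np.nan, "b1", "t", 1.0),
                     ("c2", "s1", "r2", np.nan, "b2", "t", 2.0)])
        ph["set"] = np.nan
        K = pd.DataFrame(np.eye(2), index=["c1", "c2"], columns=["c1", "c2"])
        with pytest.warns(UserWarning, match="set"):
            d = build_design(ph, ModelSpec(genetic=(("additive", "A"),)), {"A": K})
        assert "set" not in [t.name for t in d.terms]


class TestREML:
    def _oneway(self, a_values, n_per, sigma_e, rng):
        rows = []
        for i, a in enumerate(a_values):
            for j in range(n_per):
                rows.append((f"g{i}", "s1", "r", "x", "b", "t",
                             5.0 + a + rng.normal(0, sigma_e)))
        return _pheno(rows)

    def test_balanced_oneway_matches_anova_reml(self):
        """Single identity random effect: REML equals the closed-form ANOVA
        estimator sigma_a = (MSB - MSW)/n, sigma_e = MSW on balanced data."""
        rng = np.random.default_rng(42)
        g, n = 12, 6
        ph = self._oneway(rng.normal(0, 1.0, g), n, 0.7, rng)
        spec = ModelSpec(genetic=(), clone_effect=True, env_terms=())
        d = build_design(ph, spec, {})
        vc, info = reml_estimate(d)
        y = ph["value"].values.reshape(g, n)
        gm = y.mean(axis=1)
        msb = n * ((gm - gm.mean()) ** 2).sum() / (g - 1)
        msw = ((y - gm[:, None]) ** 2).sum() / (g * (n - 1))
        assert vc["residual:s1"] == pytest.approx(msw, abs=1e-6)
        assert vc["clone"] == pytest.approx((msb - msw) / n, abs=1e-6)

    def test_zero_group_variance_hits_floor(self):
        # identical value sets in every group: MSB = 0 -> boundary estimate
        rows = []
        for i in range(8):
            for j, v in enumerate([4.0, 5.0, 6.0]):
                rows.append((f"g{i}", "s1", "r", "x", "b", "t", v))
        d = build_design(_pheno(rows), ModelSpec(genetic=(), env_terms=()), {})
        vc, info = reml_estimate(d)
        assert vc["clone"] <= 2 * info["floor"]

    def test_em_and_ai_agree(self):
        rng = np.random.default_rng(3)
        ph = self._oneway(rng.normal(0, 0.8, 10), 5, 1.0, rng)
        d = build_design(ph, ModelSpec(genetic=(), env_terms=()), {})
        vc_ai, _ = reml_estimate(d, method="ai")
        vc_em, _ = reml_estimate(d, method="em", max_iter=20000, tol=1e-10)
        assert vc_ai["clone"] == pytest.approx(vc_em["clone"], abs=1e-4)
        assert vc_ai["residual:s1"] == pytest.approx(vc_em["residual:s1"], abs=1e-4)


class TestSolveMME:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_gls_oracle(self, seed, small_dataset):
        """MME solutions equal direct GLS computation on <= 50 observations."""
        rng = np.random.default_rng(seed)
        data = small_dataset
        ph = data["pheno"]
        clones = rng.choice(sorted(set(ph["clone"])), size=10, replace=False)
        sub = ph[ph["clone"].isin(clones)].head(50)
        A = build_A(sort_pedigree(data["ped_true"]))
        ids = sorted(set(sub["clone"]))
        Asub = A.loc[ids, ids]
        d = build_design(sub, ModelSpec.ablup(), {"A": Asub})
        labels = d.param_labels
        vals = {l: float(rng.uniform(0.1, 1.0)) for l in labels}
        vc = VarianceComponents(vals)
        fit = solve_mme(d, vc)
        beta, blups, pevs = gls_oracle(d, vc)
        np.testing.assert_allclose(fit.beta.values, beta, atol=1e-8)
        for name in ("additive", "clone"):
            np.testing.assert_allclose(
                fit.blups[name].values, blups[name].values, atol=1e-8
            )
            np.testing.assert_allclose(fit.pev[name].values, pevs[name].values, atol=1e-8)

    def test_floored_component_shrinks_blups_to_zero(self):
        rng = np.random.default_rng(1)
        rows = [(f"c{i}", "s1", "r", "x", "b", "t", rng.normal()) for i in range(12)]
        d = build_design(_pheno(rows), ModelSpec(genetic=(), env_terms=()), {})
        vc = VarianceComponents({"clone": 1e-10, "residual:s1": 1.0})
        fit = solve_mme(d, vc)
        assert fit.blups["clone"].abs().max() < 1e-8

    def test_duplicating_observations_preserves_fixed_effects(self):
        rng = np.random.default_rng(2)
        rows = [(f"c{i%4}", f"s{i%2}", "r", "x", "b", "t", rng.normal()) for i in range(16)]
        ph = _pheno(rows)
        K = pd.DataFrame(np.eye(4), index=[f"c{i}" for i in range(4)],
                         columns=[f"c{i}" for i in range(4)])
        spec = ModelSpec(genetic=(("additive", "A"),), env_terms=())
        vc = VarianceComponents({"additive": 0.5, "clone": 0.3,
                                 "residual:s0": 1.0, "residual:s1": 1.2})
        f1 = solve_mme(build_design(ph, spec, {"A": K}), vc)
        f2 = solve_mme(build_design(pd.concat([ph, ph]), spec, {"A": K}), vc)
        np.testing.assert_allclose(f1.beta.values, f2.beta.values, atol=1e-8)


class TestFits:
    def test_ablup_ebv_tracks_true_breeding_values(self, small_dataset):
        fit = fit_ablup(small_dataset["pheno"], small_dataset["ped_true"])
        bv = small_dataset["truth"].breeding_values
        prog = [i for i in fit.ebv.index if "_P" in i]
        r = np.corrcoef(fit.ebv[prog], bv[prog])[0, 1]
        assert r > 0.4

    def test_ebv_accuracy_increases_with_heritability(self):
        cors = []
        for s2e in (2.7, 0.35):  # h2 = 0.1 vs 0.4 with s2a=0.3, s2d=0
            cfg = SimulationConfig(
                series=(SeriesConfig("T", 20, 100, "single_pair", ("A",)),),
                n_unrelated=0, n_markers=20, percent_va=0.0,
                sigma2_additive=0.3, sigma2_clone=0.0, sigma2_resid=s2e,
                pedigree_error_rate=0.0, genotype_error_rate=0.0, missing_rate=0.0, seed=31,
            )
            data = simulate_dataset(cfg)
            fit = fit_ablup(data["pheno"], data["ped_true"])
            bv = data["truth"].breeding_values
            prog = [i for i in fit.ebv.index if "_P" in i]
            cors.append(np.corrcoef(fit.ebv[prog], bv[prog])[0, 1])
        assert 0 < cors[0] < cors[1]

    def test_pev_within_additive_bound(self, small_dataset):
        fit = fit_ablup(small_dataset["pheno"], small_dataset["ped_true"])
        A = build_A(sort_pedigree(small_dataset["ped_true"]))
        bound = np.diag(A.values) * fit.vc["additive"]
        pev = fit.pev["additive"].reindex(A.index).values
        assert (pev <= bound + 1e-8).all()
        assert (pev >= -1e-8).all()

    def test_gblup_with_g_equal_a_reproduces_ablup(self, small_dataset):
        """In the G = A limit the genomic model is the pedigree model: total
        genetic predictions coincide."""
        ph = small_dataset["pheno"]
        A = build_A(sort_pedigree(small_dataset["ped_true"]))
        afit = fit_ablup(ph, A)
        gfit = fit_gblup(ph, A, A)
        tot = gfit.total_ebv
        common = tot.index.intersection(afit.ebv.index)
        ph_clones = sorted(set(ph["clone"]))
        r = np.corrcoef(tot[ph_clones], afit.ebv[ph_clones])[0, 1]
        assert r > 0.99

    def test_nongenotyped_clones_excluded_with_warning(self, small_dataset):
        ph = small_dataset["pheno"]
        A = build_A(sort_pedigree(small_dataset["ped_true"]))
        keep = sorted(set(ph["clone"]))[:-5]
        Gsub = A.loc[keep + [i for i in A.index if i not in set(ph["clone"])],
                     keep + [i for i in A.index if i not in set(ph["clone"])]]
        with pytest.warns(UserWarning, match="non-genotyped"):
            fit = fit_gblup(ph, A, Gsub)
        assert set(ph["clone"]) - set(Gsub.index) not in [set()]
        assert fit.converged
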