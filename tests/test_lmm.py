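"""Mixed-model engine against dense GLS, ANOVA and likelihood oracles."""

import numpy as np
import pandas as pd
import pytest

from featherblup.config import SimConfig
from featherblup.lmm import (
    ModelData,
    VarianceComponents,
    assemble_mme,
    reml_fit,
    restricted_loglik,
)
from featherblup.models import spec_for
from featherblup.pedigree import build_A
from featherblup.simulate import simulate_dataset, sires_under_test

from conftest import one_way_sire_data


def vc_sire(sS2, se2, sc2=None):
    return VarianceComponents(
        genetic=np.array([[sS2]]),
        residual=np.array([[se2]]),
        cage=None if sc2 is None else np.array([[sc2]]),
        scale="sire",
        traits=("BACK45",),
    )


class TestAssembleMME:
    def test_scalar_shrinkage_closed_form(self):
        # one sire, one record, sigma2_S / sigma2_e = 1 -> s_hat = y / 2
        ped = pd.DataFrame(
            {"animal": ["S"], "sire": [None], "dam": [None], "generation": 0, "sex": "M"}
        )
        cages = pd.DataFrame(
            [{"cage_id": "C", "sire_id": "S", "mean_back45": 3.0, "surv_frac45": 1.0,
              "rt_number": "a", "farm": "f", "cross": "x", "housing_date": "d",
              "feather_gene": "g", "representative_animal_id": "R"}]
        )
        data = ModelData(pedigree=ped, cages=cages)
        mme = assemble_mme(data, spec_for("CUSiM"), "BACK45", vc_sire(1.0, 1.0), fixed=None)
        sol = mme.solve()
        assert sol[mme.partition["genetic:BACK45"][0]][0] == pytest.approx(1.5)

    def test_zero_random_variance_degenerates_to_ols(self, balanced_oneway):
        data, _ = balanced_oneway
        mme = assemble_mme(
            data, spec_for("CUSiM"), "BACK45", vc_sire(1e-12, 1.0), fixed=()
        )
        sol = mme.solve()
        mean_hat = sol[mme.partition["fixed:BACK45"][0]][0]
        assert mean_hat == pytest.approx(data.cages["mean_back45"].mean(), abs=1e-6)

    def test_matches_dense_gls_oracle(self):
        # small unbalanced sire design with related sires, fixed varcomp
        rng = np.random.default_rng(3)
        ped = pd.DataFrame(
            [("S1", None, None), ("S2", None, None), ("S3", "S1", None),
             ("S4", "S1", None), ("S5", "S2", None)],
            columns=["animal", "sire", "dam"],
        )
        ped["generation"], ped["sex"] = 0, "M"
        rows = []
        for i, s in enumerate(["S1", "S2", "S3", "S4", "S5"]):
            for j in range(2 + i % 3):
                rows.append(
                    {"cage_id": f"C{i}_{j}", "sire_id": s,
                     "mean_back45": rng.normal(), "surv_frac45": 1.0,
                     "rt_number": f"r{j % 2}", "farm": "f", "cross": "x",
                     "housing_date": "d", "feather_gene": "g",
                     "representative_animal_id": f"R{i}{j}"}
                )
        cages = pd.DataFrame(rows)
        data = ModelData(pedigree=ped, cages=cages)
        vc = vc_sire(0.4, 1.3)
        mme = assemble_mme(data, spec_for("CUSiM"), "BACK45", vc, fixed=("rt_number",))
        sol = mme.solve()

        A = build_A(ped).values
        Z = pd.get_dummies(cages["sire_id"]).reindex(columns=list(ped["animal"]), fill_value=0).to_numpy(float)
        X = np.column_stack([np.ones(len(cages)), (cages["rt_number"] == "r1").astype(float)])
        V = 0.4 * Z @ A @ Z.T + 1.3 * np.eye(len(cages))
        Vi = np.linalg.inv(V)
        y = cages["mean_back45"].to_numpy()
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 0.4 * A @ Z.T @ Vi @ (y - X @ b)
        np.testing.assert_allclose(sol[mme.partition["fixed:BACK45"][0]], b, atol=1e-8)
        np.testing.assert_allclose(sol[mme.partition["genetic:BACK45"][0]], u, atol=1e-8)


class TestRestrictedLoglik:
    def test_matches_dense_likelihood_oracle(self, balanced_oneway):
        data, _ = balanced_oneway
        sub = ModelData(pedigree=data.pedigree, cages=data.cages.iloc[:100])
        vc = vc_sire(0.25, 0.9)
        ll = restricted_loglik(sub, spec_for("CUSiM"), "BACK45", vc, fixed=())
        y = sub.cages["mean_back45"].to_numpy()
        Z = pd.get_dummies(sub.cages["sire_id"]).to_numpy(float)
        X = np.ones((100, 1))
        V = 0.25 * Z @ Z.T + 0.9 * np.eye(100)
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XVX)
        dense = -0.5 * (ldV + ldX + y @ P @ y + (100 - 1) * np.log(2 * np.pi))
        assert ll == pytest.approx(dense, abs=1e-8)

    def test_bivariate_missing_records_match_dense_oracle(self):
        # individual-level bivariate sire model on a tiny population with
        # dead birds (missing FS), against a brute-force dense covariance
        cfg = SimConfig(
            n_sires=6, pedigree_depth=2, daughters_per_sire=8, cages_per_sire=2,
            surv_rate_45=0.80, surv_rate_70=0.70, seed=13,
        )
        sim = simulate_dataset(cfg)
        data = ModelData.from_sim(sim)
        spec = spec_for("IBSiM")
        G = np.array([[0.1, 0.01], [0.01, 0.02]])
        C = np.array([[0.2, 0.005], [0.005, 0.01]])
        R = np.array([[1.1, -0.02], [-0.02, 0.05]])
        vc = VarianceComponents(genetic=G, residual=R, cage=C, scale="sire",
                                traits=("BACK45", "SURV45"))
        ll = restricted_loglik(data, spec, "BACK45", vc, fixed=("rt_number",))

        ind = data.individuals
        ped = data.pedigree
        A = build_A(ped).values
        sidx = {a: i for i, a in enumerate(ped["animal"])}
        cidx = {c: i for i, c in enumerate(ind["cage_id"].unique())}
        recs = []  # (trait, sire, cage, rt, y)
        for _, r in ind.iterrows():
            if not np.isnan(r["fs_back45"]):
                recs.append((0, r["sire_id"], r["cage_id"], r["rt_number"], r["fs_back45"], r.name))
            recs.append((1, r["sire_id"], r["cage_id"], r["rt_number"], float(r["surv45"]), r.name))
        n = len(recs)
        V = np.zeros((n, n))
        for i, (t1, s1, c1, _, _, u1) in enumerate(recs):
            for j, (t2, s2, c2, _, _, u2) in enumerate(recs):
                v = G[t1, t2] * A[sidx[s1], sidx[s2]]
                if c1 == c2:
                    v += C[t1, t2]
                if u1 == u2:
                    v += R[t1, t2]
                V[i, j] = v
        rts = sorted({r[3] for r in recs})
        X = np.zeros((n, 2 * len(rts)))
        for i, (t, _, _, rt, _, _) in enumerate(recs):
            X[i, t * len(rts) + rts.index(rt)] = 1.0
        X = X[:, X.any(axis=0)]  # levels absent from a trait's records
        y = np.array([r[4] for r in recs])
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XVX)
        dense = -0.5 * (ldV + ldX + y @ P @ y + (n - X.shape[1]) * np.log(2 * np.pi))
        assert ll == pytest.approx(dense, abs=1e-6)

    def test_record_order_invariance(self, balanced_oneway):
        data, _ = balanced_oneway
        vc = vc_sire(0.3, 1.0)
        ll1 = restricted_loglik(data, spec_for("CUSiM"), "BACK45", vc, fixed=())
        shuffled = ModelData(
            pedigree=data.pedigree,
            cages=data.cages.sample(frac=1.0, random_state=5).reset_index(drop=True),
        )
        ll2 = restricted_loglik(shuffled, spec_for("CUSiM"), "BACK45", vc, fixed=())
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_optimum_beats_perturbed_components(self, balanced_oneway):
        data, _ = balanced_oneway
        fit = reml_fit(data, spec_for("CUSiM"), "BACK45", fixed=())
        for factor in (0.9, 1.1):
            vc = vc_sire(
                factor * fit.varcomp.genetic[0, 0], fit.varcomp.residual[0, 0]
            )
            assert fit.loglik >= restricted_loglik(
                data, spec_for("CUSiM"), "BACK45", vc, fixed=()
            )


class TestREMLFit:
    def test_equals_anova_on_balanced_oneway(self, balanced_oneway):
        data, _ = balanced_oneway
        fit = reml_fit(data, spec_for("CUSiM"), "BACK45", fixed=())
        y = data.cages["mean_back45"].to_numpy().reshape(60, 8)
        msb = 8 * y.mean(axis=1).var(ddof=1)
        msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (60 * 7)
        assert fit.converged
        assert fit.varcomp.genetic[0, 0] == pytest.approx((msb - msw) / 8, abs=1e-4)
        assert fit.varcomp.residual[0, 0] == pytest.approx(msw, abs=1e-4)

    def test_null_sire_variance_hits_floor(self):
        data, _ = one_way_sire_data(n_sires=80, k=6, sigma2_S=0.0, seed=7)
        fit = reml_fit(data, spec_for("CUSiM"), "BACK45", fixed=())
        assert fit.varcomp.genetic[0, 0] < 1e-4 * fit.varcomp.phenotypic()
        assert "genetic:BACK45" in fit.boundary

    def test_blup_shrinkage_never_overdispersed(self, balanced_oneway):
        data, _ = balanced_oneway
        fit = reml_fit(data, spec_for("CUSiM"), "BACK45", fixed=())
        s_hat = fit.genetic_solutions.xs("BACK45", level=0)
        assert s_hat.var() <= fit.varcomp.genetic[0, 0] * (1 + 1e-9)

    def test_sire_and_animal_cage_models_agree(self):
        # cage-level sire and animal models are reparameterizations of the
        # same likelihood: near-perfect EBV correlation, slope ~ 1/2
        sim = simulate_dataset(SimConfig(n_sires=60, seed=11))
        data = ModelData.from_sim(sim)
        fit_s = reml_fit(data, spec_for("CUSiM"), "BACK45")
        fit_a = reml_fit(data, spec_for("CUAM"), "BACK45")
        sires = sires_under_test(sim.pedigree)
        s_hat = fit_s.sire_transmitting(sires)
        ebv = fit_a.sire_ebv(sires)
        r = np.corrcoef(s_hat, ebv)[0, 1]
        slope = np.polyfit(ebv, s_hat, 1)[0]
        assert r >= 0.99
        assert slope == pytest.approx(0.5, abs=0.05)
        assert fit_a.varcomp.genetic[0, 0] == pytest.approx(
            4 * fit_s.varcomp.genetic[0, 0], rel=0.05
        )

    def test_cage_level_phenotypic_variance_smaller(self, data60):
        # cage means average the dam/Mendelian and residual parts, so the
        # cage-level phenotypic variance must be well below the
        # individual-level one on the same data
        fit_cage = reml_fit(data60, spec_for("CUSiM"), "BACK45")
        fit_ind = reml_fit(data60, spec_for("IUAM"), "BACK45")
        assert fit_cage.varcomp.phenotypic() < fit_ind.varcomp.phenotypic()

    def test_bivariate_fixed_zero_residual_covariance(self, data60):
        fit = reml_fit(data60, spec_for("IBAM"), "BACK45")
        assert fit.varcomp.residual[0, 1] == 0.0
        assert fit.varcomp.cage is not None
        evals = np.linalg.eigvalsh(fit.varcomp.genetic)
        assert evals.min() >= -1e-10
        # dead birds keep their survival records: survival equations exceed FS ones
        assert fit.n_records == (
            data60.individuals["fs_back45"].notna().sum() + len(data60.individuals)
        )
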