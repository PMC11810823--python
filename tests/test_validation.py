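"""Cross-validation statistics: folds, proxies, accuracy, dispersion, EMMEANs."""

import numpy as np
import pandas as pd
import pytest

from featherblup.config import SimConfig
from featherblup.lmm import ModelData, VarianceComponents
from featherblup.models import spec_for
from featherblup.simulate import simulate_dataset, sires_under_test
from featherblup.validation import (
    assign_folds,
    dispersion_slope,
    emmean_compare,
    expected_accuracy,
    fold_accuracy,
    precorrect,
    r_true_proxy,
    total_heritable_ratio,
)


def vc(genetic, residual, cage=None, scale="animal"):
    return VarianceComponents(
        genetic=np.atleast_2d(float(genetic)),
        residual=np.atleast_2d(float(residual)),
        cage=None if cage is None else np.atleast_2d(float(cage)),
        scale=scale,
        traits=("BACK45",),
    )


def toy_cages(n=40, seed=0, beta_rt=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rt = f"r{i % 4}"
        rows.append(
            {"cage_id": f"C{i}", "sire_id": f"S{i % 10}",
             "mean_back45": rng.normal() + beta_rt * (i % 4),
             "n_alive45": 9, "n_original": 10,
             "rt_number": rt, "farm": "f", "cross": "x", "housing_date": "d",
             "feather_gene": "g", "representative_animal_id": f"R{i}"}
        )
    return pd.DataFrame(rows)


class TestFolds:
    def test_equal_fold_sizes(self):
        folds = assign_folds(toy_cages(100), k=10, seed=1)
        assert sorted(folds["fold"].value_counts()) == [10] * 10

    def test_near_equal_when_not_divisible(self):
        folds = assign_folds(toy_cages(47), k=10, seed=1)
        counts = folds["fold"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_deterministic_given_seed(self):
        a = assign_folds(toy_cages(60), k=10, seed=3)
        b = assign_folds(toy_cages(60), k=10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_partition_covers_all_cages(self):
        cages = toy_cages(53)
        folds = assign_folds(cages, k=10, seed=2)
        assert set(folds["cage_id"]) == set(cages["cage_id"])

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(toy_cages(10), k=1, seed=0)


class TestPrecorrect:
    def test_no_fixed_variation_gives_centered_means(self):
        cages = toy_cages(30)
        out = precorrect(cages, "BACK45", fixed=())
        expected = cages["mean_back45"] - cages["mean_back45"].mean()
        np.testing.assert_allclose(out["y_obs"], expected, atol=1e-12)
        assert abs(out["y_obs"].mean()) < 1e-12

    def test_fixed_effects_explaining_everything_give_zero(self):
        cages = toy_cages(40)
        cages["mean_back45"] = cages["rt_number"].map(
            {"r0": 1.0, "r1": 2.0, "r2": 3.0, "r3": 4.0}
        )
        out = precorrect(cages, "BACK45", fixed=("rt_number",))
        np.testing.assert_allclose(out["y_obs"], 0.0, atol=1e-10)

    def test_recovers_true_cage_deviation_on_synthetic_data(self):
        from featherblup.simulate import (
            continuous_cage_dataset,
            simulate_pedigree,
            simulate_population,
        )

        # strong sire+cage signal so the residual cage mean is a small part
        cfg = SimConfig(
            n_sires=150, sigma2_S=0.15, sigma2_c=0.35, sigma2_e=0.5, seed=19
        )
        ped = simulate_pedigree(cfg)
        ind, truth = simulate_population(cfg, ped)
        cages = continuous_cage_dataset(ind, truth)
        out = precorrect(cages, "BACK45")
        s = truth.sire_effects.set_index("animal")["s_fs"]
        c = truth.cage_effects.set_index("cage_id")["cage_effect"]
        true_dev = out["sire_id"].map(s).to_numpy() + out["cage_id"].map(c).to_numpy()
        r = np.corrcoef(out["y_obs"], true_dev)[0, 1]
        # proxy = true sire+cage deviation + residual cage-mean noise
        assert r > 0.9


class TestRTrueProxy:
    def test_hand_evaluated_value(self):
        # sigma2_A=1, sigma2_c=0.25, sigma2_e=2, n=9
        value = r_true_proxy(vc(1.0, 2.0, cage=0.25), n_bar=9)
        assert value == pytest.approx(np.sqrt(0.25 / (0.25 + 0.25 + 2.75 / 9)), abs=1e-12)
        assert value == pytest.approx(0.557, abs=5e-4)

    def test_limit_no_cage_large_groups(self):
        assert r_true_proxy(vc(1.0, 2.0, cage=0.0), n_bar=1e9) == pytest.approx(1.0, abs=1e-4)

    def test_zero_genetic_variance_degenerates(self):
        assert r_true_proxy(vc(0.0, 2.0, cage=0.25), n_bar=9) == 0.0

    def test_all_zero_components_error(self):
        with pytest.raises(ValueError):
            r_true_proxy(vc(0.0, 0.0, cage=0.0), n_bar=9)

    def test_sire_scale_equivalent(self):
        animal = r_true_proxy(vc(1.0, 2.0, cage=0.25), n_bar=9)
        sire = r_true_proxy(vc(0.25, 2.75, cage=0.25, scale="sire"), n_bar=9)
        assert animal == pytest.approx(sire, abs=1e-12)


class TestExpectedAccuracy:
    def test_cusim_hand_value(self):
        value = expected_accuracy(
            spec_for("CUSiM"), vc(0.25, 1.0, scale="sire"), d=20, n=53, m=6
        )
        assert value == pytest.approx(np.sqrt(0.25 / (0.25 + 1.0 / 6.0)), abs=1e-12)
        assert value == pytest.approx(np.sqrt(0.6), abs=1e-12)

    def test_ibam_hand_value(self):
        sA2, se2, sc2 = 1.0, 2.0, 0.25
        d, n, m = 20.0, 53.0, 6.0
        value = expected_accuracy(
            spec_for("IBAM"), vc(sA2, se2, cage=sc2), d=d, n=n, m=m
        )
        denom = sA2 / 4 + sA2 / (4 * d) + sA2 / (2 * n) + se2 / n + sc2 / m
        assert value == pytest.approx(np.sqrt((sA2 / 4) / denom), abs=1e-12)

    def test_ibsim_hand_value_and_inconsistency_error(self):
        sS2, se2, sc2 = 0.25, 2.75, 0.25
        value = expected_accuracy(
            spec_for("IBSiM"), vc(sS2, se2, cage=sc2, scale="sire"), d=20, n=53, m=6
        )
        denom = sS2 + sS2 / 20 + 2 * sS2 / 53 + (se2 - 3 * sS2) / 53 + sc2 / 6
        assert value == pytest.approx(np.sqrt(sS2 / denom), abs=1e-12)
        with pytest.raises(ValueError, match="inconsistent"):
            expected_accuracy(
                spec_for("IBSiM"), vc(1.0, 2.0, cage=0.25, scale="sire"), d=20, n=53, m=6
            )

    def test_cuam_hand_value(self):
        value = expected_accuracy(spec_for("CUAM"), vc(1.0, 2.0), d=20, n=6, m=6)
        assert value == pytest.approx(np.sqrt(0.25 / (0.25 + 2.75 / 6)), abs=1e-12)

    def test_perfect_information_limit(self):
        value = expected_accuracy(
            spec_for("IBAM"), vc(1.0, 1e-12, cage=1e-12), d=1e9, n=1e9, m=1e9
        )
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_cages_per_sire(self):
        vals = [
            expected_accuracy(spec_for("CUSiM"), vc(0.1, 1.0, scale="sire"), 20, m, m)
            for m in (2, 4, 8, 16)
        ]
        assert vals == sorted(vals)


class TestTotalHeritableRatio:
    def test_sire_model_hand_value(self):
        assert total_heritable_ratio(
            vc(0.25, 1.0, scale="sire"), spec_for("CUSiM")
        ) == pytest.approx(0.8)

    def test_animal_model_hand_value(self):
        assert total_heritable_ratio(
            vc(1.0, 2.5, cage=0.5), spec_for("IUAM")
        ) == pytest.approx(0.25)

    def test_zero_genetic_gives_zero(self):
        assert total_heritable_ratio(vc(0.0, 1.0), spec_for("IUAM")) == 0.0

    def test_zero_phenotypic_error(self):
        with pytest.raises(ValueError):
            total_heritable_ratio(vc(0.0, 0.0), spec_for("IUAM"))


class TestFoldStatistics:
    def proxies(self, n=50, seed=2, r=0.6):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = r * s + np.sqrt(1 - r * r) * noise
        frame = pd.DataFrame(
            {"cage_id": [f"C{i}" for i in range(n)],
             "sire_id": [f"S{i}" for i in range(n)], "y_obs": y}
        )
        return frame, pd.Series(s, index=frame["sire_id"])

    def test_perfect_estimates_give_high_correlation(self):
        proxies, s = self.proxies(r=0.99)
        assert fold_accuracy(s, proxies) > 0.95

    def test_permuted_estimates_give_near_zero(self):
        proxies, s = self.proxies(n=200, r=0.6, seed=3)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(s.to_numpy()), index=s.index)
        assert abs(fold_accuracy(shuffled, proxies)) < 0.15

    def test_fold_skipped_with_too_few_cages(self):
        proxies, s = self.proxies(n=2)
        assert np.isnan(fold_accuracy(s, proxies))

    def test_identity_regression_slope_one(self):
        proxies, _ = self.proxies()
        s_hat = pd.Series(proxies["y_obs"].to_numpy(), index=proxies["sire_id"])
        assert dispersion_slope(proxies, s_hat) == pytest.approx(1.0)

    def test_slope_scale_equivariance(self):
        proxies, s = self.proxies()
        b1 = dispersion_slope(proxies, s)
        b2 = dispersion_slope(proxies, 2.0 * s)
        assert b2 == pytest.approx(b1 / 2.0, rel=1e-9)

    def test_constant_estimates_skipped(self):
        proxies, s = self.proxies()
        const = pd.Series(1.0, index=s.index)
        assert np.isnan(dispersion_slope(proxies, const))


class TestEmmeans:
    def grid(self, offsets, n_folds=10, seed=4, noise=0.1):
        rng = np.random.default_rng(seed)
        block = rng.normal(0, 0.3, n_folds)  # shared fold effect
        rows = []
        for model, off in offsets.items():
            for f in range(n_folds):
                rows.append(
                    {"model": model, "fold": f + 1,
                     "value": off + block[f] + rng.normal(0, noise)}
                )
        return pd.DataFrame(rows)

    def test_single_model_is_fold_mean(self):
        df = self.grid({"CUSiM": 1.0})
        summ = emmean_compare(df)
        assert summ.table["emmean"].iloc[0] == pytest.approx(
            df["value"].mean(), abs=1e-12
        )

    def test_identical_models_share_letter(self):
        df = self.grid({"A": 0.5})
        dup = df.assign(model="B")
        summ = emmean_compare(pd.concat([df, dup], ignore_index=True))
        assert summ.contrasts["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert summ.table["letters"].nunique() == 1

    def test_injected_offset_recovered(self):
        delta = 0.8
        df = self.grid({"A": 1.0, "B": 1.0 + delta}, noise=0.05)
        summ = emmean_compare(df)
        ab = summ.contrasts.iloc[0]
        assert abs(ab["estimate"]) == pytest.approx(delta, abs=0.1)
        assert ab["significant"]
        assert summ.table["letters"].nunique() == 2

    def test_blocking_removes_fold_noise(self):
        # the fold block is huge; the pairwise SE must reflect only residual noise
        df = self.grid({"A": 0.0, "B": 0.2}, noise=0.01, seed=6)
        summ = emmean_compare(df)
        assert summ.table["se"].iloc[0] < 0.05
        assert summ.contrasts["significant"].iloc[0]

    def test_reference_comparison(self):
        df = self.grid({"A": 1.0, "B": 1.5}, noise=0.05, seed=7)
        summ = emmean_compare(df, reference=1.0)
        pA = summ.table.set_index("model").loc["A", "p_vs_ref"]
        pB = summ.table.set_index("model").loc["B", "p_vs_ref"]
        assert pA > 0.05 and pB < 0.01


class TestAccuracyConsistency:
    def test_true_sire_effects_yield_accuracy_near_one(self):
        # substituting the generator's true sire effects for the estimates
        # must drive the corrected accuracy ratio to ~1
        from featherblup.validation import IUSIM, cross_validate
        from featherblup.lmm import reml_fit
        from featherblup.validation import assign_folds, precorrect, r_true_proxy

        # the identity is asymptotic in sires and masked cages, so use
        # enough sires that component-estimate noise is a few percent
        cfg = SimConfig(n_sires=400, seed=23)
        sim = simulate_dataset(cfg)
        data = ModelData.from_sim(sim)
        truth = sim.truth.sire_effects.set_index("animal")["s_fs"]
        proxies = precorrect(sim.cages, "BACK45")
        folds = assign_folds(sim.cages, k=5, seed=23)
        n_bar = sim.cages["n_alive45"].mean()
        comp = reml_fit(data, IUSIM, "BACK45")
        r_true = r_true_proxy(comp.varcomp, n_bar)
        rs = []
        for _, cage_ids in folds.groupby("fold")["cage_id"]:
            masked = proxies[proxies["cage_id"].isin(set(cage_ids))]
            rs.append(fold_accuracy(truth, masked))
        accuracy = np.mean(rs) / r_true
        assert accuracy == pytest.approx(1.0, abs=0.2)
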