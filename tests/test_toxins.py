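"""Toxin explainability: LOOCV R^2, permutation importance, sequential
selection, transfer evaluation, correlations, and Mantel linkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metasig.catalog import ValidationError
from metasig.toxins import (
    ToxinExplainer,
    default_k_grid,
    loocv_explainability,
    pooled_contributors,
    rank_importance,
    sequential_select,
    species_toxin_correlation,
    standardize_toxin,
    transfer_evaluate,
)


def make_xy(rng, n=60, p=15, kind="single"):
    X = pd.DataFrame(
        rng.lognormal(-3, 1, size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    if kind == "single":
        # the pipeline models log-scale concentrations, so the noiseless
        # single-driver target is the driver's log-abundance
        y = pd.Series(np.log(X["f0"].values), index=X.index)
    elif kind == "noise":
        y = pd.Series(rng.normal(size=n), index=X.index)
    else:
        raise ValueError(kind)
    return X, y


class TestLoocv:
    def test_noiseless_single_driver_recovered(self, rng):
        X, y = make_xy(rng, n=100, p=10)
        # unsmoothed leaves: granularity, not noise, is the only error source
        r2 = loocv_explainability(X, y, seed=0, n_estimators=150,
                                  min_samples_leaf=1, max_features=1.0)
        assert r2 > 0.9

    def test_pure_noise_unexplainable(self, rng):
        r2s = []
        for seed in range(3):
            X, y = make_xy(np.random.default_rng(seed), n=100, p=10,
                           kind="noise")
            r2s.append(loocv_explainability(X, y, seed=seed, n_estimators=60))
        assert np.nanmean(r2s) < 0.1

    def test_seeded_determinism(self, rng):
        X, y = make_xy(rng, n=30, p=5)
        a = loocv_explainability(X, y, seed=3, n_estimators=30)
        b = loocv_explainability(X, y, seed=3, n_estimators=30)
        assert a == b

    def test_constant_target_missing(self, rng):
        X, _ = make_xy(rng, n=20, p=4)
        y = pd.Series(1.0, index=X.index)
        assert np.isnan(loocv_explainability(X, y, seed=0, n_estimators=20))

    def test_minimum_sample_contract(self, rng):
        X, y = make_xy(rng, n=8, p=3)
        with pytest.raises(ValidationError):
            loocv_explainability(X, y, seed=0)


class TestImportance:
    def test_driver_ranked_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = make_xy(rng, n=80, p=12)
            model = ToxinExplainer(n_estimators=80, random_state=seed)
            forest = model._forest().fit(X.values, y.values)
            imp = rank_importance(forest, X, y, n_repeats=5, seed=seed)
            hits += imp.index[0] == "f0"
        assert hits >= 9

    def test_null_importances_much_smaller_than_signal(self, rng):
        X, y = make_xy(rng, n=150, p=12)
        model = ToxinExplainer(n_estimators=200, random_state=0)
        f_sig = model._forest().fit(X.values, y.values)
        imp_sig = rank_importance(f_sig, X, y, n_repeats=3, seed=0)
        Xn, yn = make_xy(rng, n=150, p=12, kind="noise")
        f_null = model._forest().fit(Xn.values, yn.values)
        imp_null = rank_importance(f_null, Xn, yn, n_repeats=3, seed=0)
        assert imp_null.abs().mean() * 10 <= imp_sig.abs().mean()

    def test_constant_feature_has_exactly_zero_incmse(self, rng):
        X, y = make_xy(rng, n=40, p=6)
        X["flat"] = 1.0
        model = ToxinExplainer(n_estimators=40, random_state=0)
        forest = model._forest().fit(X.values, y.values)
        imp = rank_importance(forest, X, y, n_repeats=3, seed=0)
        assert imp["flat"] == 0.0


class TestSequentialSelect:
    def test_planted_contributors_recovered(self):
        from metasig.simulate import (SimulationConfig,
                                      noise_sd_for_signal_fraction,
                                      simulate_all)

        recalls = []
        for seed in range(2):
            cfg = SimulationConfig(
                n_species=25, n_per_arm={("C1", "HC"): 100},
                n_toxin_contributors=4, seed=seed,
                toxin_noise_sd=noise_sd_for_signal_fraction(0.6),
            )
            data = simulate_all(cfg)
            y = standardize_toxin(data["toxins"]["IS"],
                                  data["metadata"]["cohort"])
            model = ToxinExplainer(
                n_estimators=60, random_state=seed,
                k_grid=[1, 2, 3, 4, 5, 6, 8, 10],
            ).fit(data["abundance"], y)
            planted = set(data["truth"].toxin_contributors["IS"][0])
            recall = len(set(model.selected_species_) & planted) / len(planted)
            recalls.append(recall)
        assert np.mean(recalls) >= 0.75

    def test_full_grid_degenerates_to_full_model(self, rng):
        X, y = make_xy(rng, n=40, p=6)
        model = ToxinExplainer(n_estimators=40, random_state=0,
                               k_grid=[6]).fit(X, y)
        assert model.best_k_ == 6
        assert model.r2_best_ == pytest.approx(model.r2_full_, abs=0.15)

    def test_best_is_max_of_curve_and_ties_prefer_small_k(self, rng):
        X, y = make_xy(rng, n=40, p=8)
        model = ToxinExplainer(n_estimators=40, random_state=0,
                               k_grid=[1, 3, 5, 8]).fit(X, y)
        assert model.r2_best_ == max(model.r2_curve_.values())
        best_value = model.r2_curve_[model.best_k_]
        ties = [k for k, v in model.r2_curve_.items() if v == best_value]
        assert model.best_k_ == min(ties)

    def test_empty_or_out_of_range_grid_rejected(self, rng):
        X, y = make_xy(rng, n=30, p=5)
        model = ToxinExplainer(n_estimators=20, random_state=0)
        forest = model._forest().fit(X.values, y.values)
        with pytest.raises(ValidationError):
            sequential_select(forest, X, y, list(X.columns), [])
        with pytest.raises(ValidationError):
            sequential_select(forest, X, y, list(X.columns), [99])

    def test_default_grid_shape(self):
        grid = default_k_grid(300)
        assert grid[:5] == [1, 2, 3, 4, 5]
        assert max(grid) == 150
        assert 67 < max(grid)  # spans beyond the reported contributor set


class TestTransfer:
    def _two_cohorts(self, shared=True, n=80, p=20, seed=0):
        from metasig.simulate import (SimulationConfig, make_ground_truth,
                                      noise_sd_for_signal_fraction,
                                      simulate_all)

        cfg = SimulationConfig(
            n_species=p,
            n_per_arm={("A", "HC"): n, ("B", "HC"): n},
            n_toxin_contributors=4, seed=seed,
            toxin_noise_sd=noise_sd_for_signal_fraction(0.6),
        )
        data = simulate_all(cfg)
        meta = data["metadata"]
        y = standardize_toxin(data["toxins"]["IS"], meta["cohort"])
        a = meta.index[meta["cohort"] == "A"]
        b = meta.index[meta["cohort"] == "B"]
        if not shared:
            # cohort-specific contributors: rebuild cohort B's toxin from a
            # disjoint species set so nothing transfers
            from metasig.simulate import generate_toxin_concentrations

            truth2 = make_ground_truth(data["catalog"], cfg)
            rng = np.random.default_rng(seed + 99)
            used = set(data["truth"].toxin_contributors["IS"][0])
            pool = [s for s in data["catalog"]["id"] if s not in used]
            truth2.toxin_contributors = {
                "IS": (list(rng.choice(pool, 4, replace=False)),
                       list(rng.normal(size=4)))
            }
            tox_b = generate_toxin_concentrations(
                data["abundance"].loc[b], truth2, cfg
            )
            y_b = standardize_toxin(tox_b["IS"], meta.loc[b, "cohort"])
            y = pd.concat([y.loc[a], y_b])
        return data["abundance"], y, a, b

    def test_shared_contributors_transfer(self):
        table, y, a, b = self._two_cohorts(shared=True)
        res = transfer_evaluate(table.loc[a], y.loc[a], table.loc[b], y.loc[b],
                                mode="external", seed=0, n_estimators=80)
        assert res["r2_transfer"] > 0.1

    def test_cohort_specific_contributors_do_not_transfer(self):
        r2s = []
        for seed in range(3):
            table, y, a, b = self._two_cohorts(shared=False, seed=seed)
            res = transfer_evaluate(table.loc[a], y.loc[a], table.loc[b],
                                    y.loc[b], mode="external", seed=seed,
                                    n_estimators=60)
            r2s.append(res["r2_transfer"])
        assert np.nanmean(r2s) < 0.05

    def test_split70_partitions_within_cohort(self):
        table, y, a, b = self._two_cohorts(shared=True)
        res = transfer_evaluate(table.loc[a], y.loc[a], mode="split70",
                                seed=0, n_estimators=60)
        assert res["n_train"] + res["n_test"] == len(a)

    def test_overlapping_samples_rejected(self):
        table, y, a, b = self._two_cohorts(shared=True)
        with pytest.raises(ValidationError):
            transfer_evaluate(table.loc[a], y.loc[a], table.loc[a], y.loc[a],
                              mode="external", seed=0)


class TestStandardize:
    def test_affine_invariance_of_modeling_target(self, rng):
        raw = pd.Series(rng.lognormal(1, 0.5, 50),
                        index=[f"s{i}" for i in range(50)])
        cohorts = pd.Series(["A"] * 25 + ["B"] * 25, index=raw.index)
        z1 = standardize_toxin(raw, cohorts)
        z2 = standardize_toxin(raw * 7.3, cohorts)  # assay rescaling
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-12)

    def test_within_cohort_zero_mean_unit_sd(self, rng):
        raw = pd.Series(rng.lognormal(0, 1, 40),
                        index=[f"s{i}" for i in range(40)])
        cohorts = pd.Series(["A"] * 20 + ["B"] * 20, index=raw.index)
        z = standardize_toxin(raw, cohorts)
        for c in ("A", "B"):
            sub = z[cohorts == c]
            assert sub.mean() == pytest.approx(0, abs=1e-12)
            assert sub.std(ddof=0) == pytest.approx(1, abs=1e-12)


class TestCorrelation:
    def test_monotone_transform_gives_unit_rho(self, rng):
        table = pd.DataFrame({"sp": rng.lognormal(0, 1, 30)},
                             index=[f"s{i}" for i in range(30)])
        toxins = pd.DataFrame({"IS": np.exp(table["sp"])}, index=table.index)
        out = species_toxin_correlation(table, toxins)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_negated_ranks_give_minus_one(self, rng):
        table = pd.DataFrame({"sp": rng.normal(size=30)},
                             index=[f"s{i}" for i in range(30)])
        toxins = pd.DataFrame({"IS": -table["sp"].rank()}, index=table.index)
        out = species_toxin_correlation(table, toxins)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_null_pvalues_uniform(self, rng):
        table = pd.DataFrame(
            rng.normal(size=(40, 50)),
            index=[f"s{i}" for i in range(40)],
            columns=[f"sp{j}" for j in range(50)],
        )
        toxins = pd.DataFrame(rng.normal(size=(40, 4)), index=table.index,
                              columns=list("WXYZ"))
        out = species_toxin_correlation(table, toxins)
        assert stats.kstest(out["p"].values, "uniform").pvalue > 0.01

    def test_constant_vector_missing(self, rng):
        table = pd.DataFrame({"sp": np.ones(10)},
                             index=[f"s{i}" for i in range(10)])
        toxins = pd.DataFrame({"IS": rng.normal(size=10)}, index=table.index)
        out = species_toxin_correlation(table, toxins)
        assert np.isnan(out.loc[0, "rho"])


def test_pooled_contributors_union():
    class R:
        def __init__(self, s):
            self.selected_species_ = s

    out = pooled_contributors({"IS": R(["a", "b"]), "PCS": R(["b", "c"])})
    assert out == ["a", "b", "c"]
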