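import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dhglm import (DHGLM, Pedigree, Scenario, fit_dhglm, fit_dispersion_part,
                   fit_gamma_glm, leverage_report, simulate)
from dhglm.design import build_fixed_design, build_random_design
from dhglm.simulate import default_model
from _oracles import penalized_gamma_fit, reml_fit
from conftest import one_hot


class TestReductions:
    def test_homoskedastic_fit_is_exact_reml(self, homoskedastic_data):
        """With intercept-only dispersion the loop reproduces REML."""
        ds = homoskedastic_data
        m = DHGLM(response="y", mean_fixed=("x",), mean_random=("group",),
                  tol=1e-9, max_iter=500).fit(ds.table)
        X = build_fixed_design(ds.table, ("x",)).matrix
        Z = build_random_design(ds.table, "group").Z
        su, se = reml_fit(ds.table["y"].to_numpy(), X, Z)
        assert m.converged_
        assert m.sigma_u2_["group"] == pytest.approx(su, rel=1e-6)
        assert np.exp(m.disp_coef_.iloc[0]) == pytest.approx(se, rel=1e-6)
        assert np.ptp(m.phi_) == 0.0  # homoskedastic: phi constant

    def test_fixed_only_recovers_rss_over_df(self, rng):
        n = 120
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(0, 1.4, n)
        m = DHGLM(response="y", mean_fixed=("x",)).fit(df)
        X = build_fixed_design(df, ("x",)).matrix
        b = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        rss = np.sum((df["y"].to_numpy() - X @ b) ** 2)
        assert np.exp(m.disp_coef_.iloc[0]) == pytest.approx(
            rss / (n - 2), rel=1e-10)
        assert m.converged_

    def test_categorical_fixed_effect_treatment_coding(self, rng):
        n = 90
        df = pd.DataFrame({"sex": rng.choice(["f", "m"], n)})
        df["y"] = 1.0 + (df["sex"] == "m") * 0.8 + rng.normal(0, 0.5, n)
        m = DHGLM(response="y", mean_fixed=("sex",)).fit(df)
        assert list(m.coef_.index) == ["(Intercept)", "sex[m]"]
        assert m.coef_["sex[m]"] == pytest.approx(
            df.y[df.sex == "m"].mean() - df.y[df.sex == "f"].mean(), rel=1e-8)


class TestDispersionPart:
    def test_matches_penalized_likelihood_oracle(self, rng):
        n, q = 30, 3
        Xd = np.column_stack([np.ones(n), rng.normal(size=n)])
        g = rng.integers(0, q, n)
        Zd = one_hot(g, q)
        y = rng.gamma(0.5, 2.0, n) * np.exp(0.3 * Xd[:, 1])
        w = np.full(n, 0.5)
        fit = fit_dispersion_part(y, w, Xd, Zd, 0.4)
        oracle = penalized_gamma_fit(y, Xd, Zd, w, 0.4)
        assert fit.converged
        assert np.allclose(np.r_[fit.coef, fit.ranef], oracle, atol=1e-6)

    def test_shrinkage_limit_reduces_to_fixed_only_glm(self, rng):
        n, q = 25, 4
        Xd = np.column_stack([np.ones(n), rng.normal(size=n)])
        Zd = one_hot(rng.integers(0, q, n), q)
        y = rng.gamma(1.0, 2.0, n)
        w = rng.uniform(0.3, 0.5, n)
        fit = fit_dispersion_part(y, w, Xd, Zd, 1e-10)
        glm = fit_gamma_glm(y, Xd, prior_weights=w)
        assert np.max(np.abs(fit.ranef)) < 1e-8
        assert np.allclose(fit.coef, glm.coef, atol=1e-8)

    def test_pseudo_deviances_zero_at_zero_blup(self, rng):
        n, q = 20, 2
        fit = fit_dispersion_part(rng.gamma(1.0, 1.0, n), np.full(n, 0.5),
                                  np.ones((n, 1)), one_hot([0, 1] * 10, q),
                                  1e-10)
        assert np.allclose(fit.pseudo_deviances, 0.0, atol=1e-12)


class TestFullModel:
    def test_permutation_invariance(self, oneway_data):
        table = oneway_data.table
        perm = np.random.default_rng(0).permutation(len(table))
        m1 = default_model().fit(table)
        m2 = default_model().fit(table.iloc[perm])
        assert m1.sigma_u2_["group"] == pytest.approx(
            m2.sigma_u2_["group"], abs=1e-8)
        assert m1.sigma_d2_["group"] == pytest.approx(
            m2.sigma_d2_["group"], abs=1e-8)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-8)

    def test_self_consistency_at_convergence(self, oneway_data):
        m = default_model().fit(oneway_data.table)
        assert m.converged_
        tail = m.trajectory_.drop(columns="iteration").iloc[-2:].to_numpy()
        assert np.max(np.abs(tail[1] - tail[0])) < m.tol

    def test_recovers_simulation_truth_roughly(self, oneway_data):
        m = default_model().fit(oneway_data.table)
        assert 0.2 < m.sigma_u2_["group"] < 0.9
        assert 0.5 < m.sigma_d2_["group"] < 1.6
        assert m.disp_coef_["x_d"] == pytest.approx(1.5, abs=0.35)
        assert m.coef_["x"] == pytest.approx(0.5, abs=0.15)

    def test_hlik_variant_close_on_mean_part(self, oneway_data):
        mp = default_model("pql").fit(oneway_data.table)
        mh = default_model("hlik").fit(oneway_data.table)
        assert mh.converged_
        assert mh.sigma_u2_["group"] == pytest.approx(
            mp.sigma_u2_["group"], rel=0.01)
        # the gamma-deviance update inflates sigma_d2 relative to the
        # squared-residual (PQL) update by roughly 2(e^{tau/2}-1)/tau - 1
        # with tau = Var(u_hat); ~15-35% at sigma_d2 = 1
        ratio = mh.sigma_d2_["group"] / mp.sigma_d2_["group"]
        assert 1.02 < ratio < 1.6

    def test_predictions_match_fitted_values(self, oneway_data):
        m = default_model().fit(oneway_data.table)
        assert np.allclose(m.predict(oneway_data.table), m.fitted_, atol=1e-10)
        assert np.allclose(m.predict_variance(oneway_data.table), m.phi_,
                           rtol=1e-10)

    def test_sklearn_params_round_trip(self):
        m = default_model(tol=1e-6)
        params = m.get_params()
        assert params["tol"] == 1e-6
        m2 = DHGLM(**params)
        assert m2.get_params() == params

    def test_unconverged_flagged_not_raised(self, oneway_data):
        m = default_model(max_iter=2).fit(oneway_data.table)
        assert not m.converged_
        assert m.n_iter_ == 2

    def test_functional_wrapper(self, oneway_data):
        m = fit_dhglm(oneway_data.table, "y", mean_fixed=("x",),
                      mean_random=("group",))
        assert m.converged_

    def test_input_validation(self, oneway_data):
        with pytest.raises(TypeError):
            DHGLM(response="y").fit(np.zeros((5, 2)))
        with pytest.raises(KeyError):
            DHGLM(response="nope").fit(oneway_data.table)
        with pytest.raises(ValueError, match="variant"):
            DHGLM(response="y", variant="mcmc").fit(oneway_data.table)


class TestAnimalModel:
    @staticmethod
    def _pedigree_dataset(rng, n_founders=6, n_offspring=24, reps=3):
        recs = [(f"f{i}", "0", "0") for i in range(n_founders)]
        for k in range(n_offspring):
            s, d = rng.choice(n_founders, 2, replace=False)
            recs.append((f"o{k}", f"f{s}", f"f{d}"))
        ped = Pedigree(records=list(recs))
        ids = [f"o{k}" for k in range(n_offspring)]
        from dhglm import build_relationship_factor
        rf = build_relationship_factor(ped)
        A = rf.a_matrix()
        idx = [rf.id_index[i] for i in ids]
        u_all = rf.L @ rng.normal(0, np.sqrt(0.5), len(rf.ids))
        rows = []
        for i, animal in enumerate(ids):
            for _ in range(reps):
                rows.append({"animal": animal,
                             "y": 1.0 + u_all[idx[i]] + rng.normal(0, 1.0)})
        return ped, pd.DataFrame(rows)

    def test_animal_model_fits_and_reports_all_ids(self, rng):
        ped, df = self._pedigree_dataset(rng)
        m = DHGLM(response="y", mean_random=("animal",), pedigree=ped,
                  pedigree_for=("animal",)).fit(df)
        assert m.converged_
        assert m.sigma_u2_["animal"] > 0
        # breeding values exist for non-phenotyped founders too
        assert "f0" in m.ranef_["animal"].index

    def test_identity_pedigree_equals_plain_grouping(self, rng):
        # all animals unrelated founders: folding with L = I is a no-op
        n_g = 8
        df = pd.DataFrame({
            "g": np.repeat([f"a{i}" for i in range(n_g)], 5),
            "y": np.random.default_rng(1).normal(size=40),
        })
        ped = Pedigree(records=[(f"a{i}", "0", "0") for i in range(n_g)])
        m1 = DHGLM(response="y", mean_random=("g",), tol=1e-8).fit(df)
        m2 = DHGLM(response="y", mean_random=("g",), pedigree=ped,
                   pedigree_for=("g",), tol=1e-8).fit(df)
        assert m1.sigma_u2_["g"] == pytest.approx(m2.sigma_u2_["g"], rel=1e-6)

    def test_phenotyped_animal_missing_from_pedigree_added_as_founder(self, rng):
        ped, df = self._pedigree_dataset(rng)
        extra = pd.DataFrame({"animal": ["stranger"] * 3,
                              "y": rng.normal(size=3)})
        m = DHGLM(response="y", mean_random=("animal",), pedigree=ped,
                  pedigree_for=("animal",)).fit(pd.concat([df, extra]))
        assert "stranger" in m.ranef_["animal"].index


class TestLeverageReport:
    def test_singleton_fixed_class_flagged(self, rng):
        # one record is the only member of its own fixed-effect class
        n = 21
        df = pd.DataFrame({
            "herd": ["h1"] * 10 + ["h2"] * 10 + ["lonely"],
            "y": rng.normal(size=n),
        })
        m = DHGLM(response="y", mean_fixed=("herd",)).fit(df)
        rep = leverage_report(m)
        assert rep.records.loc[20, "leverage"] == pytest.approx(1.0, abs=1e-8)
        assert bool(rep.records.loc[20, "no_information"])
        assert not rep.records.loc[:19, "no_information"].any()

    def test_balanced_design_has_equal_leverages(self, rng):
        df = pd.DataFrame({"group": np.repeat(np.arange(4), 5),
                           "y": rng.normal(size=20)})
        m = DHGLM(response="y", mean_random=("group",)).fit(df)
        rep = leverage_report(m)
        assert rep.records["leverage"].std() < 1e-10
        assert set(rep.levels["part"]) == {"mean"}

    def test_reliability_increases_with_records_per_level(self, rng):
        sizes = [2, 5, 10, 20]
        df = pd.DataFrame({"group": np.repeat(np.arange(4), sizes),
                           "y": rng.normal(size=sum(sizes))})
        m = DHGLM(response="y", mean_random=("group",)).fit(df)
        rel = leverage_report(m).levels.set_index("level")["reliability"]
        assert np.all(np.diff(rel.loc[[0, 1, 2, 3]].to_numpy()) > 0)
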