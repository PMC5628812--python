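"""Coupling statistics: Bray-Curtis, BIO-ENV, Spearman tests, the TDI GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from benthosens import (EnvGrid, GridSpec, bioenv, bioenv_permutation_test,
                        community_dissimilarity, fit_tdi_glm,
                        predict_tdi_map, spearman_tests)


def stations(n):
    return [f"s{i:02d}" for i in range(n)]


def noise_composition(rng, n, k=8):
    comp = pd.DataFrame(rng.lognormal(size=(n, k)),
                        columns=[f"tax{j}" for j in range(k)],
                        index=stations(n))
    return comp.div(comp.sum(axis=1), axis=0)


class TestCommunityDissimilarity:
    def test_identical_compositions_distance_zero(self):
        comp = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=stations(2))
        d = community_dissimilarity(comp).d
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_compositions_distance_one(self):
        comp = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=stations(2))
        assert community_dissimilarity(comp).d[0, 1] == pytest.approx(1.0)

    def test_hand_bray_curtis(self):
        # {0.5, 0.5} vs {1, 0}: BC = (|0.5-1| + |0.5-0|) / 2 = 0.5
        comp = pd.DataFrame([[0.5, 0.5], [1.0, 0.0]], index=stations(2))
        assert community_dissimilarity(comp).d[0, 1] == pytest.approx(0.5)

    def test_empty_station_row_rejected(self):
        comp = pd.DataFrame([[0.5, 0.5], [0.0, 0.0]], index=stations(2))
        with pytest.raises(ValueError, match="empty"):
            community_dissimilarity(comp)


class TestBioEnv:
    def test_singleton_subsets_equal_direct_rank_correlation(self, rng):
        n = 18
        comp = noise_composition(rng, n)
        env = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                           index=comp.index)
        dm = community_dissimilarity(comp)
        res = bioenv(dm, env)
        comm_vec = dm.condensed()
        z = (env - env.mean()) / env.std(ddof=1)
        for var in "abc":
            from scipy.spatial.distance import pdist
            dvec = pdist(z[[var]].to_numpy())
            rho_direct = spearmanr(comm_vec, dvec)[0]
            rho_mine = dict(res.ranking)[(var,)]
            assert rho_mine == pytest.approx(rho_direct, abs=1e-12)

    def test_matches_skbio_best_per_size(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix
        n = 16
        comp = noise_composition(rng, n)
        env = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                           index=comp.index)
        dm = community_dissimilarity(comp)
        mine = bioenv(dm, env)
        theirs = skbio_distance.bioenv(DistanceMatrix(dm.d, ids=dm.labels),
                                       env)
        best_by_size = {}
        for subset, rho in mine.ranking:
            best_by_size.setdefault(len(subset), rho)
        for size, row in theirs.iterrows():
            assert best_by_size[int(row["size"])] == pytest.approx(
                row["correlation"], abs=1e-10)

    def test_recovers_generating_gradient(self, rng):
        # community built deterministically from one gradient that is
        # also offered as a candidate variable: its singleton subset
        # must score near-perfectly
        n = 30
        gradient = np.sort(rng.uniform(0, 10, n))
        comp = pd.DataFrame({
            "taxA": np.exp(-0.5 * ((gradient - 2) / 1.5) ** 2),
            "taxB": np.exp(-0.5 * ((gradient - 5) / 1.5) ** 2),
            "taxC": np.exp(-0.5 * ((gradient - 8) / 1.5) ** 2),
        }, index=stations(n))
        comp = comp.div(comp.sum(axis=1), axis=0)
        env = pd.DataFrame({"gradient": gradient,
                            "noise1": rng.normal(size=n),
                            "noise2": rng.normal(size=n)},
                           index=comp.index)
        res = bioenv(community_dissimilarity(comp), env)
        single = dict(res.ranking)[("gradient",)]
        assert single > 0.95

    def test_tie_break_prefers_smaller_then_lexicographic(self, rng):
        # duplicated variable -> identical rho for several subsets
        n = 12
        comp = noise_composition(rng, n)
        x = rng.normal(size=n)
        env = pd.DataFrame({"a": x, "b": x.copy()}, index=comp.index)
        res = bioenv(community_dissimilarity(comp), env)
        subsets = [s for s, _ in res.ranking]
        assert subsets.index(("a",)) < subsets.index(("b",))
        assert subsets.index(("b",)) < subsets.index(("a", "b"))

    def test_station_order_invariance(self, rng):
        n = 15
        comp = noise_composition(rng, n)
        env = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                           index=comp.index)
        res1 = bioenv(community_dissimilarity(comp), env)
        order = rng.permutation(n)
        comp2 = comp.iloc[order]
        res2 = bioenv(community_dissimilarity(comp2), env.iloc[order])
        assert res1.best_subset == res2.best_subset
        assert res1.best_rho == pytest.approx(res2.best_rho, abs=1e-12)

    def test_monotone_rescale_of_variable_invariance(self, rng):
        n = 15
        comp = noise_composition(rng, n)
        env = pd.DataFrame({"a": rng.uniform(1, 5, n),
                            "b": rng.normal(size=n)}, index=comp.index)
        dm = community_dissimilarity(comp)
        r1 = dict(bioenv(dm, env).ranking)[("a",)]
        env2 = env.assign(a=np.exp(env["a"]))
        r2 = dict(bioenv(dm, env2).ranking)[("a",)]
        # rank-based on the *distances*: monotone but nonlinear maps of a
        # variable perturb pairwise distances' ranks only slightly; an
        # affine rescale leaves them untouched
        env3 = env.assign(a=3.0 * env["a"] - 7.0)
        r3 = dict(bioenv(dm, env3).ranking)[("a",)]
        assert r3 == pytest.approx(r1, abs=1e-12)
        assert np.isfinite(r2)

    def test_combinatorial_guard(self, rng):
        n = 10
        comp = noise_composition(rng, n)
        env = pd.DataFrame(rng.normal(size=(n, 21)), index=comp.index,
                           columns=[f"v{j}" for j in range(21)])
        with pytest.raises(ValueError, match="max_subset_size"):
            bioenv(community_dissimilarity(comp), env)
        res = bioenv(community_dissimilarity(comp), env, max_subset_size=1)
        assert len(res.ranking) == 21


class TestBioEnvPermutation:
    def test_perfect_gradient_p_is_one_over_hundred(self, rng):
        n = 30
        gradient = np.linspace(0, 10, n)
        comp = pd.DataFrame({
            "taxA": 1.0 + gradient,
            "taxB": 11.0 - gradient,
        }, index=stations(n))
        comp = comp.div(comp.sum(axis=1), axis=0)
        env = pd.DataFrame({"gradient": gradient}, index=comp.index)
        res = bioenv(community_dissimilarity(comp), env)
        p = bioenv_permutation_test(res, n_perm=99, seed=1)
        assert p == pytest.approx(0.01)

    def test_reproducible_for_fixed_seed(self, rng):
        n = 14
        comp = noise_composition(rng, n)
        env = pd.DataFrame(rng.normal(size=(n, 2)), columns=list("ab"),
                           index=comp.index)
        res = bioenv(community_dissimilarity(comp), env)
        p1 = bioenv_permutation_test(res, n_perm=99, seed=7)
        p2 = bioenv_permutation_test(res, n_perm=99, seed=7)
        assert p1 == p2

    def test_matches_explicit_label_permutation(self, rng):
        # oracle: permute the env table rows and re-run the full search
        n = 12
        comp = noise_composition(rng, n)
        env = pd.DataFrame(rng.normal(size=(n, 2)), columns=list("ab"),
                           index=comp.index)
        dm = community_dissimilarity(comp)
        res = bioenv(dm, env)
        p_fast = bioenv_permutation_test(res, n_perm=99, seed=5)
        rng2 = np.random.default_rng(5)
        exceed = 0
        for _ in range(99):
            perm = rng2.permutation(n)
            env_perm = pd.DataFrame(env.to_numpy()[perm],
                                    columns=env.columns, index=env.index)
            best = bioenv(dm, env_perm).best_rho
            if best >= res.best_rho:
                exceed += 1
        assert p_fast == pytest.approx((1 + exceed) / 100)


class TestSpearmanTests:
    def test_perfect_monotone_pairs(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x**3})
        rho, p = spearman_tests(table)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # ranks {1,2,3,4} vs {1,2,4,3}: rho = 1 - 6*2/(4*15) = 0.8
        table = pd.DataFrame({"a": [1, 2, 3, 4], "b": [1, 2, 4, 3]})
        rho, _ = spearman_tests(table)
        assert rho.loc["a", "b"] == pytest.approx(0.8)

    def test_constant_variable_reported_missing(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        rho, p = spearman_tests(table)
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(p.loc["a", "b"])

    def test_pairwise_missing_dropped(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan],
                              "b": [1.0, 2, 3, np.nan, 5],
                              "c": [2.0, 4, 6, 8, 10]})
        rho, _ = spearman_tests(table)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(1.0)


class TestTdiGlm:
    def simulate(self, rng, n, b_risk=0.5, c_abr=-0.03, noise=0.2):
        risk = rng.uniform(0, np.sqrt(2), n)
        abrasion = rng.uniform(0, 60, n)
        log_tdi = 1.5 + b_risk * risk + c_abr * abrasion \
            + rng.normal(0, noise, n)
        return np.exp(log_tdi), risk, abrasion

    def test_exact_recovery_without_noise(self, rng):
        tdi, risk, abr = self.simulate(rng, 50, noise=0.0)
        fit = fit_tdi_glm(tdi, risk, abr)
        assert fit.params["const"] == pytest.approx(1.5, abs=1e-8)
        assert fit.params["risk"] == pytest.approx(0.5, abs=1e-8)
        assert fit.params["abrasion"] == pytest.approx(-0.03, abs=1e-8)

    def test_recovery_within_three_standard_errors(self, rng):
        tdi, risk, abr = self.simulate(rng, 200)
        fit = fit_tdi_glm(tdi, risk, abr)
        assert abs(fit.params["risk"] - 0.5) < 3 * fit.bse["risk"]
        assert abs(fit.params["abrasion"] + 0.03) < 3 * fit.bse["abrasion"]

    def test_degenerate_abrasion_drops_to_single_predictor(self, rng):
        tdi, risk, abr = self.simulate(rng, 50)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_tdi_glm(tdi, risk, np.zeros_like(abr))
        assert fit.dropped_predictors == ("abrasion",)
        assert "abrasion" not in fit.params

    def test_collinear_predictors_rejected(self, rng):
        tdi, risk, _ = self.simulate(rng, 50)
        with pytest.raises(ValueError, match="collinear"):
            fit_tdi_glm(tdi, risk, 2.0 * risk + 1.0)

    def test_prediction_consistency_and_monotonicity(self, rng):
        tdi, risk, abr = self.simulate(rng, 80)
        fit = fit_tdi_glm(tdi, risk, abr)
        # prediction at a station equals the back-transformed fitted value
        np.testing.assert_allclose(fit.predict(risk, abr),
                                   np.exp(fit.fitted), rtol=1e-10)
        # negative abrasion coefficient: more abrasion, lower prediction
        lo = fit.predict(np.full(5, 0.7), np.zeros(5))
        hi = fit.predict(np.full(5, 0.7), np.full(5, 50.0))
        assert np.all(hi < lo)

    def test_predict_map_masks_and_constant_case(self, rng):
        tdi, risk, abr = self.simulate(rng, 50)
        fit = fit_tdi_glm(tdi, risk, abr)
        fit.params[:] = 0.0
        fit.params["const"] = 1.0
        spec = GridSpec(3, 3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        risk_g = EnvGrid(spec=spec, values=rng.uniform(0, 1, (3, 3)),
                         mask=mask, name="risk")
        abr_g = EnvGrid(spec=spec, values=rng.uniform(0, 60, (3, 3)),
                        name="abrasion")
        out = predict_tdi_map(fit, risk_g, abr_g)
        assert out.mask[0, 0]
        np.testing.assert_allclose(out.values[~out.mask], np.e)

    def test_unaligned_grids_rejected(self, rng):
        tdi, risk, abr = self.simulate(rng, 50)
        fit = fit_tdi_glm(tdi, risk, abr)
        g1 = EnvGrid(spec=GridSpec(3, 3), values=np.ones((3, 3)))
        g2 = EnvGrid(spec=GridSpec(4, 4), values=np.ones((4, 4)))
        with pytest.raises(ValueError, match="align"):
            predict_tdi_map(fit, g1, g2)
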