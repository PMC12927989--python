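"""Stratified z-scores, reference covariance, Mahalanobis HDI_M."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

import myoentropy as me
from myoentropy.hdi import (
    SingularCovarianceError,
    StratumError,
    ZeroDistanceError,
    Z_COLS,
)


def make_fibers(n, seed=0, sexes=("F", "M"), types=("I", "IIA", "IIX")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "fiber_id": np.arange(n),
            "participant_id": rng.choice(["P1", "P2", "P3"], n),
            "sex": rng.choice(sexes, n),
            "fiber_type": rng.choice(types, n),
            "area_um2": rng.lognormal(8.3, 0.4, n),
            "heterogeneity": rng.uniform(0, 1, n),
            "apl": rng.normal(13.3, 3.4, n),
        }
    )


class TestStratifiedZscore:
    def test_three_values_give_unit_zscores(self):
        df = pd.DataFrame(
            {
                "fiber_id": [1, 2, 3],
                "sex": "F",
                "fiber_type": "I",
                "area_um2": [2.0, 4.0, 6.0],
                "heterogeneity": [2.0, 4.0, 6.0],
                "apl": [2.0, 4.0, 6.0],
            }
        )
        z = me.stratified_zscore(df, min_stratum_n=3)
        assert list(z["z_area"]) == [-1.0, 0.0, 1.0]

    def test_six_strata_with_both_sexes_and_three_types(self):
        z = me.stratified_zscore(make_fibers(600, seed=1), min_stratum_n=10)
        assert z["stratum"].nunique() == 6

    def test_stratum_means_zero_sd_one(self):
        z = me.stratified_zscore(make_fibers(600, seed=2), min_stratum_n=10)
        for _, g in z.groupby("stratum"):
            for c in Z_COLS:
                assert abs(g[c].mean()) < 1e-9
                assert abs(g[c].std(ddof=1) - 1) < 1e-9

    def test_constant_stratum_rejected(self):
        df = make_fibers(40, seed=3, sexes=("F",), types=("I",))
        df["heterogeneity"] = 0.5
        with pytest.raises(StratumError, match="zero variance"):
            me.stratified_zscore(df, min_stratum_n=5)

    def test_small_stratum_error_and_pool_fallback(self):
        df = make_fibers(30, seed=4)
        with pytest.raises(StratumError):
            me.stratified_zscore(df, min_stratum_n=25)
        z = me.stratified_zscore(df, min_stratum_n=25, on_small_stratum="pool")
        assert z[list(Z_COLS)].notna().all().all()


class TestReferenceModel:
    def test_diagonal_near_one_on_stratified_zscores(self):
        z = me.stratified_zscore(make_fibers(3000, seed=5), min_stratum_n=10)
        model = me.fit_reference_model(z)
        assert np.allclose(np.diag(model.covariance), 1.0, atol=0.01)

    def test_independent_features_offdiagonal_small(self):
        rng = np.random.default_rng(6)
        z = pd.DataFrame(rng.standard_normal((100_000, 3)), columns=list(Z_COLS))
        model = me.fit_reference_model(z)
        off = model.covariance[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.02).all()

    def test_collinear_features_rejected(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(200)
        z = pd.DataFrame({"z_area": a, "z_het": 2 * a, "z_apl": rng.standard_normal(200)})
        with pytest.raises(SingularCovarianceError):
            me.fit_reference_model(z)

    def test_json_roundtrip(self, tmp_path):
        z = me.stratified_zscore(make_fibers(600, seed=8), min_stratum_n=10)
        model = me.fit_reference_model(z)
        model.to_json(tmp_path / "m.json")
        back = me.ReferenceModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.covariance, model.covariance)
        assert back.features == model.features


class TestFiberHDI:
    def test_identity_covariance_is_euclidean(self):
        feats = pd.DataFrame([[3.0, 4.0, 0.0]], columns=list(Z_COLS))
        model = me.ReferenceModel(np.eye(3))
        out = me.fiber_hdi(feats, model)
        assert out["mahalanobis"].iloc[0] == pytest.approx(5.0)
        assert out["hdi"].iloc[0] == pytest.approx(np.log(5.0), abs=1e-4)

    def test_two_feature_hand_inverted_oracle(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = me.ReferenceModel(S, ("z_area", "z_het"))
        feats = pd.DataFrame([[1.0, 1.0]], columns=["z_area", "z_het"])
        out = me.fiber_hdi(feats, model)
        assert out["mahalanobis"].iloc[0] ** 2 == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert out["hdi"].iloc[0] == pytest.approx(0.5 * np.log(4.0 / 3.0), abs=1e-10)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((200, 3))
        S = np.cov(X, rowvar=False, ddof=1)
        model = me.ReferenceModel(S)
        feats = pd.DataFrame(X, columns=list(Z_COLS))
        out = me.fiber_hdi(feats, model)
        Sinv = np.linalg.inv(S)
        for i in range(0, 200, 17):
            expect = scipy_mahalanobis(X[i], np.zeros(3), Sinv)
            assert out["mahalanobis"].iloc[i] == pytest.approx(expect, abs=1e-10)

    def test_zero_distance_error_and_drop(self):
        feats = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], columns=list(Z_COLS))
        model = me.ReferenceModel(np.eye(3))
        with pytest.raises(ZeroDistanceError):
            me.fiber_hdi(feats, model)
        out = me.fiber_hdi(feats, model, on_zero_distance="drop")
        assert len(out) == 1

    def test_affine_invariance(self):
        """Invertible linear remap of features + refit leaves D_M unchanged."""
        rng = np.random.default_rng(10)
        X = rng.standard_normal((500, 3)) @ np.array(
            [[1.0, 0.3, 0.0], [0.0, 1.0, 0.2], [0.0, 0.0, 1.0]]
        )
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        feats = pd.DataFrame(X, columns=list(Z_COLS))
        feats2 = pd.DataFrame(X @ A.T, columns=list(Z_COLS))
        d1 = me.fiber_hdi(feats, me.fit_reference_model(feats))["mahalanobis"]
        d2 = me.fiber_hdi(feats2, me.fit_reference_model(feats2))["mahalanobis"]
        assert np.allclose(d1, d2, rtol=1e-8)

    def test_population_calibration_mean_d2_is_dimension(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200_000, 3))
        feats = pd.DataFrame(X, columns=list(Z_COLS))
        d = me.fiber_hdi(feats, me.fit_reference_model(feats))["mahalanobis"]
        assert np.mean(d**2) == pytest.approx(3.0, rel=0.05)

    def test_squared_option_preserves_rank_order(self):
        rng = np.random.default_rng(12)
        feats = pd.DataFrame(rng.standard_normal((300, 3)), columns=list(Z_COLS))
        model = me.fit_reference_model(feats)
        h1 = me.fiber_hdi(feats, model)["hdi"]
        h2 = me.fiber_hdi(feats, model, squared=True)["hdi"]
        assert (h1.rank() == h2.rank()).all()
        assert np.allclose(h2, 2 * h1)

    def test_feature_subset_excludes_area(self):
        rng = np.random.default_rng(13)
        feats = pd.DataFrame(rng.standard_normal((300, 3)), columns=list(Z_COLS))
        model = me.fit_reference_model(feats)
        out = me.fiber_hdi(feats, model, feature_subset=("z_het", "z_apl"))
        manual = me.fiber_hdi(
            feats[["z_het", "z_apl"]],
            me.ReferenceModel(model.subset(("z_het", "z_apl")).covariance, ("z_het", "z_apl")),
        )
        assert np.allclose(out["mahalanobis"], manual["mahalanobis"])


class TestParticipantHDI:
    def test_mean_of_two_fibers(self):
        h = pd.Series([0.5, 1.5], index=[0, 1])
        pid = pd.Series(["P1", "P1"], index=[0, 1])
        out = me.participant_hdi(h, pid)
        assert out.loc["P1", "hdi"] == 1.0
        assert out.loc["P1", "n_fibers"] == 2

    def test_single_fiber_participant(self):
        out = me.participant_hdi(
            pd.Series([0.7], index=[0]), pd.Series(["P9"], index=[0])
        )
        assert out.loc["P9", "hdi"] == 0.7

    def test_matches_groupby_oracle(self, zscored_cohort):
        _, fibers = zscored_cohort
        model = me.fit_reference_model(fibers)
        res = me.fiber_hdi(fibers, model, on_zero_distance="drop")
        out = me.participant_hdi(res["hdi"], fibers["participant_id"])
        oracle = {}
        for pid in fibers["participant_id"].unique():
            vals = res["hdi"][fibers.loc[res.index, "participant_id"] == pid]
            oracle[pid] = vals.mean()
        for pid, v in oracle.items():
            assert out.loc[pid, "hdi"] == pytest.approx(v, abs=1e-12)
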