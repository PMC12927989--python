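"""Generator contracts: determinism, planted structure, degenerate cases."""

import numpy as np
import pandas as pd
import pytest

import myoentropy as me
from myoentropy.extraction import compute_type_heterogeneity
from myoentropy.synthetic import SizingError, rook_adjacency_pairs


class TestTessellation:
    def test_single_fiber_fills_field(self):
        t = me.generate_tessellation(1, (12, 12), jitter=0.0, seed=0)
        assert t.n_fibers == 1
        assert (t.label_image[1:-1, 1:-1] == 1).all()
        assert t.truth.loc[0, "neighbors"] == frozenset()

    def test_regular_grid_interior_has_four_neighbors(self):
        t = me.generate_tessellation(16, (42, 42), jitter=0.0, seed=0)
        degree = t.truth.set_index("fiber_id")["neighbors"].map(len)
        # corner regions 2, edge regions 3, the four interior regions 4
        assert sorted(degree) == [2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3, 4, 4, 4, 4]

    def test_deterministic_given_seed(self):
        a = me.generate_tessellation(50, (100, 100), 0.4, seed=5)
        b = me.generate_tessellation(50, (100, 100), 0.4, seed=5)
        assert (a.label_image == b.label_image).all()
        assert a.truth.equals(b.truth)

    def test_field_too_small_raises(self):
        with pytest.raises(SizingError):
            me.generate_tessellation(200, (10, 10), seed=0)

    def test_labels_contiguous_and_border_background(self, tess100):
        lab = tess100.label_image
        assert set(np.unique(lab)) == set(range(0, 101))
        assert (lab[0] == 0).all() and (lab[:, 0] == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_neighbor_relation_symmetric_irreflexive(self, seed):
        t = me.generate_tessellation(60, (100, 100), 0.35, seed=seed)
        nb = dict(zip(t.truth.fiber_id, t.truth.neighbors))
        for fid, ns in nb.items():
            assert fid not in ns
            for n in ns:
                assert fid in nb[n]

    def test_regions_four_connected(self, tess100):
        from scipy import ndimage

        for fid in (1, 25, 50, 100):
            region = tess100.label_image == fid
            _, n = ndimage.label(region)  # default structure = 4-connectivity
            assert n == 1


class TestFiberTypes:
    def test_single_type_proportions(self, tess100):
        types = me.assign_fiber_types(tess100, (1.0, 0.0, 0.0), clustering=0.8, seed=1)
        assert (types == "I").all()

    def test_negative_proportion_rejected(self, tess100):
        with pytest.raises(ValueError):
            me.assign_fiber_types(tess100, (-0.1, 0.6, 0.5))

    def test_iid_fractions_match_proportions(self):
        t = me.generate_tessellation(10_000, (1022, 1022), 0.3, seed=3)
        types = me.assign_fiber_types(t, (0.41, 0.35, 0.24), clustering=0.0, seed=4)
        frac = types.value_counts(normalize=True)
        for ty, p in zip(("I", "IIA", "IIX"), (0.41, 0.35, 0.24)):
            assert abs(frac[ty] - p) < 0.02

    def test_clustering_lowers_heterogeneity(self):
        """Neighbor-copying must reduce mean fiber-type heterogeneity."""
        diffs = []
        for seed in range(50):
            t = me.generate_tessellation(100, (122, 122), 0.35, seed=seed)
            edges = rook_adjacency_pairs(t.label_image)
            het = {}
            for c in (0.0, 0.9):
                ty = me.assign_fiber_types(t, clustering=c, seed=seed + 1000)
                h = compute_type_heterogeneity(ty, edges)
                het[c] = np.nanmean(list(h.values()))
            diffs.append(het[0.0] - het[0.9])
        assert np.mean(diffs) > 0
        assert np.sum(np.array(diffs) > 0) >= 45  # overwhelmingly consistent


class TestFiberAreas:
    def test_zero_sigma_gives_exact_type_means(self, tess100):
        types = me.assign_fiber_types(tess100, seed=0)
        areas = me.sample_fiber_areas(types, {"I": 4500, "IIA": 3100, "IIX": 2200}, 0.0, 1)
        assert (areas[types == "I"] == 4500).all()
        assert (areas[types == "IIX"] == 2200).all()

    def test_lognormal_cv_closed_form(self):
        sigma = 0.5
        types = pd.Series(["I"] * 50_000, index=range(50_000))
        areas = me.sample_fiber_areas(types, {"I": 4500.0}, sigma, seed=2)
        cv = areas.std(ddof=1) / areas.mean()
        assert abs(cv - np.sqrt(np.exp(sigma**2) - 1)) < 0.02

    def test_same_seed_identical_draws(self, tess100):
        types = me.assign_fiber_types(tess100, seed=0)
        a = me.sample_fiber_areas(types, sigma=0.4, seed=9)
        b = me.sample_fiber_areas(types, sigma=0.4, seed=9)
        assert (a == b).all()

    def test_nonpositive_mean_rejected(self, tess100):
        types = me.assign_fiber_types(tess100, seed=0)
        with pytest.raises(ValueError):
            me.sample_fiber_areas(types, {"I": 0.0, "IIA": 1.0, "IIX": 1.0}, 0.2, 0)


class TestRender:
    def test_mask_equals_label_image(self, rendered_sample):
        tess, _, _, mask = rendered_sample
        assert (mask == tess.label_image).all()

    def test_intensities_nonnegative_with_noise(self, tess100):
        types = me.assign_fiber_types(tess100, seed=0)
        img, _ = me.render_histology_image(tess100, types, noise_sd=80.0, seed=1)
        assert (img >= 0).all()

    def test_noiseless_types_fully_recoverable(self, rendered_sample):
        tess, types, img, mask = rendered_sample
        got = me.classify_fiber_types(me.LabelImage(mask, 1.0), img)
        assert all(got[int(i)] == types[int(i)] for i in types.index)


class TestCohort:
    def test_two_participants_fiber_count(self):
        c = me.generate_cohort(2, (10, 10), seed=0)
        assert len(c.fibers) == 20
        assert c.fibers.participant_id.nunique() == 2

    def test_noise_free_outcome_linear_in_theta(self):
        c = me.generate_cohort(
            30,
            (10, 10),
            outcome_betas={"walk_speed": -0.16},
            covariate_effects={},
            noise_sd=0.0,
            seed=3,
        )
        r = np.corrcoef(c.participants.theta, c.participants.walk_speed)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_degenerate_covariate_model_rejected(self):
        bad = dict(me.synthetic.DEFAULT_COVARIATE_MODEL)
        bad["age"] = (76.4, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            me.generate_cohort(5, (10, 10), covariate_model=bad, seed=0)

    def test_identical_seed_identical_tables(self):
        a = me.generate_cohort(3, (15, 15), seed=7)
        b = me.generate_cohort(3, (15, 15), seed=7)
        assert a.participants.equals(b.participants)
        assert a.fibers.equals(b.fibers)

    def test_theta_spread_drives_participant_hdi_spread(self):
        """Wider theta range must widen the participant-level HDI spread."""
        from myoentropy import hdi, pipeline

        def hdi_var(theta_range, seed):
            c = me.generate_cohort(
                20, (40, 40), theta_distribution=theta_range, seed=seed
            )
            fib = pipeline.compute_fiber_metrics(c.fibers)
            fib = me.stratified_zscore(fib, min_stratum_n=2, on_small_stratum="pool")
            model = me.fit_reference_model(fib)
            res = me.fiber_hdi(fib, model, on_zero_distance="drop")
            return me.participant_hdi(res["hdi"], fib.participant_id)["hdi"].var()

        diffs = [hdi_var((0.0, 1.0), s) - hdi_var((0.35, 0.65), s) for s in range(10)]
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 8
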