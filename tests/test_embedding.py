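import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from tactsurf.embedding import (
    BootstrapReport,
    PerceptualSpace,
    bootstrap_reliability,
    crossvalidate_dims,
    decision_loglik,
    fit_embedding,
    pairwise_distances,
    procrustes_align,
    select_dims_one_se,
    topo_distance_ratio,
)
from tactsurf.metric import pair_vector
from tactsurf.observer import (
    DecisionSet,
    TripletDecision,
    planted_dissimilarity,
    preset_config,
    simulate_experiment,
    simulate_sliding_with_friction,
)


def make_space(coords: dict[str, list[float]]) -> PerceptualSpace:
    df = pd.DataFrame.from_dict(coords, orient="index")
    df.columns = [f"dim{i+1}" for i in range(df.shape[1])]
    return PerceptualSpace(coordinates=df, n_dims=df.shape[1], log_likelihood=0.0)


def decision(ref, left, right, choice, participant=0):
    return TripletDecision(ref_id=ref, left_id=left, right_id=right,
                           choice=choice, participant=participant, modality="sliding")


class TestDecisionLoglik:
    def test_equidistant_alternatives_give_half(self):
        sp = make_space({"r": [0.0, 0.0], "a": [1.0, 0.0], "b": [-1.0, 0.0]})
        ll = decision_loglik(sp, decision("r", "a", "b", "left"), link_scale=1.0)
        assert ll == pytest.approx(np.log(0.5))

    def test_hand_computed_logistic_value(self):
        # d(left,ref)=1, d(right,ref)=2 -> P(left) = logistic(1)
        sp = make_space({"r": [0.0], "a": [1.0], "b": [-2.0]})
        ll = decision_loglik(sp, decision("r", "a", "b", "left"), link_scale=1.0)
        assert ll == pytest.approx(np.log(expit(1.0)), rel=1e-12)

    def test_swapping_sides_complements_probability(self):
        sp = make_space({"r": [0.0], "a": [1.0], "b": [-2.0]})
        p = np.exp(decision_loglik(sp, decision("r", "a", "b", "left"), link_scale=1.0))
        q = np.exp(decision_loglik(sp, decision("r", "b", "a", "left"), link_scale=1.0))
        assert p + q == pytest.approx(1.0, rel=1e-12)

    def test_unknown_sample_rejected(self):
        sp = make_space({"r": [0.0], "a": [1.0], "b": [-2.0]})
        with pytest.raises(KeyError):
            decision_loglik(sp, decision("r", "a", "zzz", "left"))


class TestFitEmbedding:
    def test_one_dimensional_order_recovery(self):
        # planted line a < b < c < d; noise-free decisions from all triplets
        pos = {"a": 0.0, "b": 1.0, "c": 2.5, "d": 4.0}
        ids = list(pos)
        decs = []
        from tactsurf.observer import enumerate_triplets

        for ref, pair in enumerate_triplets(ids):
            x, y = sorted(pair)
            choice = "left" if abs(pos[x] - pos[ref]) < abs(pos[y] - pos[ref]) else "right"
            decs.append(decision(ref, x, y, choice))
        space = fit_embedding(DecisionSet(tuple(decs)), n_dims=1, n_starts=8, seed=0)
        coord = space.coordinates["dim1"]
        order = list(coord.sort_values().index)
        assert order in (["a", "b", "c", "d"], ["d", "c", "b", "a"])

    def test_likelihood_invariant_under_rotation(self, summary_small):
        cfg = preset_config("tapping", seed=2)
        dec = simulate_experiment(cfg, summary_small)
        space = fit_embedding(dec, n_dims=3, n_starts=4, seed=0)
        total = sum(decision_loglik(space, d) for d in dec)
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = PerceptualSpace(
            coordinates=pd.DataFrame(
                space.coordinates.to_numpy() @ Q,
                index=space.coordinates.index, columns=space.coordinates.columns,
            ),
            n_dims=3, log_likelihood=space.log_likelihood,
            link=space.link, link_scale=space.link_scale,
        )
        total_rot = sum(decision_loglik(rotated, d) for d in dec)
        assert total_rot == pytest.approx(total, rel=1e-9)

    def test_low_noise_distance_recovery(self, summary_small):
        cfg = preset_config("sliding", seed=0, noise_scale=0.2)
        dec, _ = simulate_sliding_with_friction(cfg, summary_small)
        space = fit_embedding(dec, n_dims=3, n_starts=16, seed=100)
        _, ed = pair_vector(space.distances())
        _, pv = pair_vector(planted_dissimilarity(cfg, summary_small))
        assert stats.pearsonr(ed, pv)[0] >= 0.9

    def test_recovery_degrades_with_noise(self, summary_small):
        rs = []
        for noise in (0.2, 1.0, 3.0):
            cfg = preset_config("sliding", seed=0, noise_scale=noise)
            dec, _ = simulate_sliding_with_friction(cfg, summary_small)
            space = fit_embedding(dec, n_dims=3, n_starts=16, seed=100)
            _, ed = pair_vector(space.distances())
            _, pv = pair_vector(planted_dissimilarity(cfg, summary_small))
            rs.append(stats.pearsonr(ed, pv)[0])
        assert rs[0] > rs[1] > rs[2]

    def test_normalization_convention(self, summary_small):
        cfg = preset_config("tapping", seed=4)
        dec = simulate_experiment(cfg, summary_small)
        space = fit_embedding(dec, n_dims=2, n_starts=4, seed=0)
        X = space.coordinates.to_numpy()
        np.testing.assert_allclose(X.mean(0), 0.0, atol=1e-9)
        assert np.sqrt(np.mean((X**2).sum(1))) == pytest.approx(1.0, rel=1e-9)

    def test_too_few_samples_rejected(self):
        decs = (decision("a", "b", "c", "left"),)
        with pytest.raises(ValueError):
            fit_embedding(DecisionSet(decs), n_dims=3)


class TestCrossValidation:
    def test_three_dimensional_structure_selected(self, summary_small):
        cfg = preset_config("visual", seed=0, noise_scale=0.2)
        dec = simulate_experiment(cfg, summary_small)
        report = crossvalidate_dims(dec, dims_list=(1, 2, 3, 4), k=10, seed=0, n_starts=2)
        assert select_dims_one_se(report) == 3
        t = report.table.set_index("n_dims")["mean_loglik"]
        assert t[3] > t[1]  # clear improvement up to the planted dimensionality

    def test_seeded_folds_are_reproducible(self, summary_small):
        cfg = preset_config("tapping", seed=1)
        dec = simulate_experiment(cfg, summary_small)
        a = crossvalidate_dims(dec, dims_list=(2,), k=5, seed=3, n_starts=1)
        b = crossvalidate_dims(dec, dims_list=(2,), k=5, seed=3, n_starts=1)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_leave_one_out_folds(self):
        # k = |decisions| behaves as leave-one-out with folds of size 1
        pos = {"a": 0.0, "b": 1.0, "c": 3.0, "d": 6.0}
        from tactsurf.observer import enumerate_triplets

        decs = []
        for ref, pair in enumerate_triplets(list(pos)):
            x, y = sorted(pair)
            choice = "left" if abs(pos[x] - pos[ref]) < abs(pos[y] - pos[ref]) else "right"
            decs.append(decision(ref, x, y, choice))
        dset = DecisionSet(tuple(decs))
        report = crossvalidate_dims(dset, dims_list=(1,), k=len(dset), seed=0, n_starts=1)
        assert report.k == len(dset)


class TestBootstrap:
    def test_zero_noise_low_dispersion(self, summary_small):
        cfg = preset_config("visual", seed=0, noise_scale=1e-6)
        dec = simulate_experiment(cfg, summary_small)
        rep = bootstrap_reliability(dec, B=15, n_dims=3, seed=1, n_starts=2)
        assert isinstance(rep, BootstrapReport)
        assert rep.average_cov < 0.1

    def test_dispersion_monotone_in_observer_noise(self, summary_small):
        covs = []
        for noise in (0.3, 0.8, 2.0):
            cfg = preset_config("sliding", seed=4, noise_scale=noise)
            dec = simulate_experiment(cfg, summary_small)
            covs.append(
                bootstrap_reliability(dec, B=20, n_dims=3, seed=1, n_starts=2).average_cov
            )
        assert covs[0] < covs[1] < covs[2]

    def test_minimum_resamples_enforced(self, summary_small):
        cfg = preset_config("tapping", seed=0)
        dec = simulate_experiment(cfg, summary_small)
        with pytest.raises(ValueError):
            bootstrap_reliability(dec, B=1)


class TestProcrustes:
    @pytest.fixture()
    def fitted_space(self, summary_small):
        cfg = preset_config("visual", seed=0, noise_scale=0.3)
        dec = simulate_experiment(cfg, summary_small)
        return fit_embedding(dec, n_dims=3, n_starts=8, seed=0)

    def test_distances_unchanged(self, fitted_space, summary_small):
        aligned = procrustes_align(fitted_space, summary_small["hurst"])
        np.testing.assert_allclose(
            aligned.distances().to_numpy(), fitted_space.distances().to_numpy(), atol=1e-9
        )

    def test_rotation_round_trip(self, fitted_space, summary_small):
        h = summary_small["hurst"]
        aligned = procrustes_align(fitted_space, h)
        r0 = stats.pearsonr(aligned.coordinates["dim1"], h.loc[aligned.sample_ids])[0]
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        scrambled = PerceptualSpace(
            coordinates=pd.DataFrame(
                aligned.coordinates.to_numpy() @ Q,
                index=aligned.coordinates.index, columns=aligned.coordinates.columns,
            ),
            n_dims=3, log_likelihood=0.0,
        )
        restored = procrustes_align(scrambled, h)
        r1 = stats.pearsonr(restored.coordinates["dim1"], h.loc[restored.sample_ids])[0]
        assert r1 == pytest.approx(r0, abs=1e-6)
        assert r0 > 0  # H increases along +dim1

    def test_already_aligned_space_unchanged(self, fitted_space, summary_small):
        once = procrustes_align(fitted_space, summary_small["hurst"])
        twice = procrustes_align(once, summary_small["hurst"])
        np.testing.assert_allclose(
            np.abs(twice.coordinates["dim1"]), np.abs(once.coordinates["dim1"]), atol=1e-8
        )

    def test_degenerate_hurst_warns(self, fitted_space):
        h = pd.Series(0.5, index=fitted_space.sample_ids)
        with pytest.warns(UserWarning):
            out = procrustes_align(fitted_space, h)
        pd.testing.assert_frame_equal(out.coordinates, fitted_space.coordinates)


class TestTopoDistanceRatio:
    def make_clusters(self, side=10.0, spread=1.0):
        # three clusters of three points on an equilateral triangle of the centres
        centres = np.array(
            [[0.0, 0.0], [side, 0.0], [side / 2, side * np.sqrt(3) / 2]]
        )
        coords, labels = {}, {}
        for ci, c in enumerate(centres):
            for pi, ang in enumerate([0.0, 2 * np.pi / 3, 4 * np.pi / 3]):
                off = spread / np.sqrt(3) * np.array([np.cos(ang), np.sin(ang)])
                sid = f"c{ci}p{pi}"
                coords[sid] = [0.0, *(c + off)]  # dim1 unused; ratio over dims (2,3)
                labels[sid] = f"topo{ci}"
        return make_space(coords), labels

    def test_constructed_ratio_matches_geometry(self):
        space, labels = self.make_clusters(side=10.0, spread=1.0)
        ratio = topo_distance_ratio(space, labels, dims=(2, 3))
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_label_permutation_invariance(self):
        space, labels = self.make_clusters()
        renamed = {k: {"topo0": "x", "topo1": "y", "topo2": "z"}[v] for k, v in labels.items()}
        assert topo_distance_ratio(space, renamed) == pytest.approx(
            topo_distance_ratio(space, labels)
        )

    def test_collapsed_clusters_give_infinity(self):
        space, labels = self.make_clusters(spread=0.0)
        assert topo_distance_ratio(space, labels) == np.inf

    def test_singleton_label_rejected(self):
        space, labels = self.make_clusters()
        labels["c0p0"] = "lonely"
        with pytest.raises(ValueError):
            topo_distance_ratio(space, labels)
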