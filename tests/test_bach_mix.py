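import numpy as np
import pytest

from bach3d.bach_mix import (Arrangement, ArrangementMixture,
                             arrangement_transform, compare_models_aic,
                             effective_structures, enumerate_arrangements,
                             mixture_rates, place_region_b, prune_mixture,
                             run_bach_mix, select_separated_arrangements)
from bach3d.bach_sampler import SamplerConfig
from bach3d.contact_data import LocusFeatures
from bach3d.poisson_model import ModelParams, Structure3D, poisson_rates
from bach3d.simulate import (SimScenario, make_backbone, simulate_features,
                             simulate_mixture_population)


class TestArrangementTransform:
    def test_identity(self):
        arr = arrangement_transform((0.0, 0.0, 0.0), 1)
        np.testing.assert_allclose(arr.transform, np.eye(3), atol=1e-12)

    def test_mirror_has_negative_determinant(self):
        arr = arrangement_transform((0.7, 1.1, 2.9), -1)
        assert np.linalg.det(arr.transform) == pytest.approx(-1.0)
        arr2 = arrangement_transform((0.7, 1.1, 2.9), 1)
        assert np.linalg.det(arr2.transform) == pytest.approx(1.0)

    def test_alpha_only_is_rotation_about_z(self):
        # axis-angle oracle: rotation by alpha about the z axis
        alpha = 0.83
        arr = arrangement_transform((alpha, 0.0, 0.0), 1)
        c, s = np.cos(alpha), np.sin(alpha)
        oracle = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        np.testing.assert_allclose(arr.transform, oracle, atol=1e-12)


class TestEnumerateArrangements:
    def test_single_bin_gives_two_mirror_states(self):
        arrs = enumerate_arrangements(bins_per_angle=1)
        assert len(arrs) == 2
        assert {a.mirror for a in arrs} == {1, -1}

    def test_default_grid_bounded_and_orthogonal(self):
        arrs = enumerate_arrangements(bins_per_angle=4)
        assert len(arrs) <= 128
        for a in arrs:
            np.testing.assert_allclose(a.transform @ a.transform.T,
                                       np.eye(3), atol=1e-10)

    def test_deduplication_by_exhaustive_comparison(self):
        tol = 1e-6
        arrs = enumerate_arrangements(bins_per_angle=3, dedup_tol=tol)
        mats = np.stack([a.transform for a in arrs])
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                assert np.max(np.abs(mats[i] - mats[j])) > tol


class TestPlaceRegionB:
    @pytest.fixture
    def regions(self):
        rng = np.random.default_rng(0)
        return (make_backbone("random_walk", 8, rng),
                make_backbone("random_walk", 6, rng))

    def test_identity_preserves_b_up_to_translation(self, regions):
        a, b = regions
        placed = place_region_b(a, b, arrangement_transform((0, 0, 0), 1))
        shift = placed.coords[0] - b.coords[0]
        np.testing.assert_allclose(placed.coords, b.coords + shift,
                                   atol=1e-10)

    def test_rigidity_of_intra_b_distances(self, regions):
        a, b = regions
        from scipy.spatial.distance import pdist
        for arr in enumerate_arrangements(2)[:6]:
            placed = place_region_b(a, b, arr)
            np.testing.assert_allclose(pdist(placed.coords),
                                       pdist(b.coords), atol=1e-10)

    def test_mirror_flips_chirality(self, regions):
        a, b = regions
        arr = arrangement_transform((0.4, 1.2, 2.2), -1)
        placed = place_region_b(a, b, arr)

        def signed_volume(x):
            return np.linalg.det(x[1:4] - x[0])

        v0 = signed_volume(b.coords[:4])
        v1 = signed_volume(placed.coords[:4])
        assert v0 * v1 < 0
        assert abs(v1) == pytest.approx(abs(v0), abs=1e-10)

    def test_chain_adjacency_at_junction(self, regions):
        a, b = regions
        bond = np.mean(np.linalg.norm(np.diff(a.coords, axis=0), axis=1))
        for arr in enumerate_arrangements(2)[:4]:
            placed = place_region_b(a, b, arr)
            gap = np.linalg.norm(placed.coords[0] - a.coords[-1])
            assert gap == pytest.approx(bond, abs=1e-10)

    def test_degenerate_region_a_rejected(self, regions):
        _, b = regions
        bad = Structure3D([[0, 0, 0], [1, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            place_region_b(bad, b, arrangement_transform((0, 0, 0), 1))


class TestMixtureRates:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(1)
        a = make_backbone("random_walk", 6, rng)
        b = make_backbone("random_walk", 5, rng)
        lf = simulate_features(11, 2)
        lf_a, lf_b = lf.subset(np.arange(6)), lf.subset(np.arange(6, 11))
        p = ModelParams(2.0, -1.0, 0.2, 0.4, 0.6)
        return a, b, lf_a, lf_b, p

    def test_single_component_reduces_to_poisson_rates(self, setup):
        a, b, lf_a, lf_b, p = setup
        arr = arrangement_transform((0.9, 0.8, 0.7), 1)
        mix = ArrangementMixture([arr], np.array([1.0]))
        lam = mixture_rates(a, b, mix, lf_a, lf_b, p)
        placed = place_region_b(a, b, arr)
        composed = Structure3D(np.vstack([a.coords, placed.coords]))
        lf_all = LocusFeatures(
            np.concatenate([lf_a.frag_ends, lf_b.frag_ends]),
            np.concatenate([lf_a.gc, lf_b.gc]),
            np.concatenate([lf_a.mappability, lf_b.mappability]))
        full = poisson_rates(composed, lf_all, p)
        np.testing.assert_allclose(lam, full[:6, 6:], atol=1e-10)

    def test_duplicate_arrangements_match_single(self, setup):
        a, b, lf_a, lf_b, p = setup
        arr = arrangement_transform((0.3, 0.5, 0.1), -1)
        one = mixture_rates(a, b, ArrangementMixture([arr], [1.0]),
                            lf_a, lf_b, p)
        two = mixture_rates(a, b,
                            ArrangementMixture([arr, arr], [0.4, 0.6]),
                            lf_a, lf_b, p)
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_linear_in_proportions(self, setup):
        a, b, lf_a, lf_b, p = setup
        arrs = [arrangement_transform((0.3, 0.5, 0.1), 1),
                arrangement_transform((2.3, 1.5, 3.1), -1)]
        r1 = mixture_rates(a, b, ArrangementMixture(arrs, [1.0, 0.0]),
                           lf_a, lf_b, p)
        r2 = mixture_rates(a, b, ArrangementMixture(arrs, [0.0, 1.0]),
                           lf_a, lf_b, p)
        for w in (0.25, 0.6):
            rw = mixture_rates(a, b,
                               ArrangementMixture(arrs, [w, 1 - w]),
                               lf_a, lf_b, p)
            np.testing.assert_allclose(rw, w * r1 + (1 - w) * r2,
                                       atol=1e-10)


class TestPruningAndEffective:
    def test_component_below_one_percent_removed(self):
        arrs = enumerate_arrangements(1)
        mix = ArrangementMixture(arrs, np.array([0.995, 0.005]))
        out = prune_mixture(mix, 0.01)
        assert out.k == 1
        np.testing.assert_allclose(out.proportions, [1.0])

    def test_proportions_renormalized(self):
        arrs = enumerate_arrangements(2)[:3]
        mix = ArrangementMixture(arrs, np.array([0.5, 0.495, 0.005]))
        out = prune_mixture(mix, 0.01)
        assert out.proportions.sum() == pytest.approx(1.0)
        assert out.k == 2

    def test_effective_structure_count(self):
        arrs = enumerate_arrangements(2)[:3]
        mix = ArrangementMixture(arrs, np.array([0.90, 0.06, 0.04]))
        assert effective_structures(mix, 0.05) == 2
        single = ArrangementMixture(arrs[:1], np.array([1.0]))
        assert effective_structures(single, 0.49) == 1

    def test_monotone_in_threshold(self):
        arrs = enumerate_arrangements(2)[:4]
        mix = ArrangementMixture(arrs, np.array([0.55, 0.25, 0.12, 0.08]))
        counts = [effective_structures(mix, t) for t in (0.01, 0.05, 0.10)]
        assert counts == sorted(counts, reverse=True)


class TestRunBachMix:
    """End-to-end mixture inference on small synthetic cross matrices."""

    @pytest.fixture(scope="class")
    def design(self):
        rng = np.random.default_rng(5)
        a = make_backbone("random_walk", 10, rng)
        b = make_backbone("random_walk", 10, rng)
        cands = select_separated_arrangements(a, b, k=8)
        return a, b, cands

    def test_two_component_recovery(self, design):
        a, b, cands = design
        props = np.zeros(8)
        props[1], props[5] = 0.7, 0.3
        sc = SimScenario(n_loci=20, split_at=10, seed=5, mean_count=300,
                         mixture_arrangements=cands,
                         mixture_proportions=props)
        cross, truth = simulate_mixture_population(sc)
        cfg = SamplerConfig(n_chains=2, n_iter=800, burn_in=300, thin=10,
                            seed=7)
        fit = run_bach_mix(cross, truth.extra["struct_a"],
                           truth.extra["struct_b"], truth.extra["lf_a"],
                           truth.extra["lf_b"], cfg, arrangements=cands)
        by_id = {id(c): p for c, p in zip(fit.mixture.arrangements,
                                          fit.mixture.proportions)}
        assert abs(by_id.get(id(cands[1]), 0.0) - 0.7) < 0.1
        assert abs(by_id.get(id(cands[5]), 0.0) - 0.3) < 0.1
        assert fit.mixture.proportions.sum() == pytest.approx(1.0)

    def test_single_arrangement_collapses_to_k1(self, design):
        a, b, cands = design
        props = np.zeros(8)
        props[3] = 1.0
        sc = SimScenario(n_loci=20, split_at=10, seed=9, mean_count=300,
                         mixture_arrangements=cands,
                         mixture_proportions=props)
        cross, truth = simulate_mixture_population(sc)
        cfg = SamplerConfig(n_chains=2, n_iter=800, burn_in=300, thin=10,
                            seed=11)
        fit = run_bach_mix(cross, truth.extra["struct_a"],
                           truth.extra["struct_b"], truth.extra["lf_a"],
                           truth.extra["lf_b"], cfg, arrangements=cands)
        assert fit.mixture.k == 1
        assert fit.mixture.arrangements[0] is cands[3]


class TestCompareModels:
    def test_equal_loglik_prefers_fewer_parameters(self):
        from bach3d.bach_sampler import BachFit
        from bach3d.bach_mix import MixFit
        from bach3d.poisson_model import aic

        class _Stub:
            pass

        bach = _Stub()
        bach.aic = aic(-100.0, 20)
        mixf = _Stub()
        mixf.aic = aic(-100.0, 25)
        sel = compare_models_aic(bach, mixf)
        assert sel.selected == "single"
        assert sel.aic_single < sel.aic_mixture
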