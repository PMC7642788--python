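"""EM clustering over classes and in-plane rotations."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from spivolve.emclass import (EMConfig, em_cluster, em_cluster_polar,
                              frames_for_classes, hard_assignments,
                              select_classes, stable_intersection)
from spivolve.io import PatternStack
from spivolve.simulate import (PhantomSpec, SimConfig, make_phantom,
                               render_intensity, sample_patterns)


@pytest.fixture(scope="module")
def two_population_stack(square_geometry):
    """100 sphere-60 + 100 sphere-80 frames at random in-plane angles."""
    iva = render_intensity(make_phantom(PhantomSpec("sphere", 60.0, 8.0, 1.0),
                                        72, 2.0), 4)
    ivb = render_intensity(make_phantom(PhantomSpec("sphere", 80.0, 8.0, 1.0),
                                        84, 2.0), 4)
    kw = dict(fluence_scale=200.0, size_jitter_sd=0.0, single_fraction=1.0,
              multi_fraction=0.0, blank_fraction=0.0)
    sa = sample_patterns(iva, square_geometry,
                         SimConfig(n_frames=100, seed=11, **kw))
    sb = sample_patterns(ivb, square_geometry,
                         SimConfig(n_frames=100, seed=12, **kw))
    counts = np.concatenate([sa.counts, sb.counts])
    labels = np.array([0] * 100 + [1] * 100)
    return PatternStack(counts=counts, geometry=square_geometry), labels


class TestEMCluster:
    def test_single_class_single_rotation_is_mean(self, rng):
        # one angular bin means the rotation group is trivial: the M-step
        # closed form is the pixel-wise mean of the frames
        data = rng.poisson(3.0, (30, 1, 96)).astype(float)
        pmask = np.ones((1, 96), bool)
        cfg = EMConfig(n_classes=1, n_rotations=1, max_iter=5, seed=0)
        w, occ, trace, resp = em_cluster_polar(data, pmask, cfg)
        assert np.allclose(w[0], data.mean(axis=0), rtol=1e-9)
        assert occ[0] == pytest.approx(1.0)
        assert np.allclose(resp.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_two_population_separation(self, two_population_stack):
        stack, labels = two_population_stack
        cfg = EMConfig(n_classes=2, n_rotations=36, max_iter=40, seed=1)
        model, resp = em_cluster(stack, cfg)
        ari = adjusted_rand_score(labels, hard_assignments(resp))
        assert ari >= 0.95

    def test_loglik_monotone(self, two_population_stack):
        stack, _ = two_population_stack
        cfg = EMConfig(n_classes=3, n_rotations=24, max_iter=15, seed=2)
        model, _ = em_cluster(stack, cfg)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_rotation_equivariance(self, rng):
        """Cyclically rotating every frame by one grid angle leaves the
        partition unchanged (models rotate correspondingly)."""
        base = rng.poisson(2.0, (40, 12, 10)).astype(float)
        base[:20, 2:5] *= 3.0        # two crude populations
        pmask = np.ones((12, 10), bool)
        cfg = EMConfig(n_classes=2, n_rotations=12, max_iter=12, seed=3)
        _, _, _, resp_a = em_cluster_polar(base, pmask, cfg)
        rolled = np.roll(base, 1, axis=1)
        _, _, _, resp_b = em_cluster_polar(rolled, pmask, cfg)
        assert np.array_equal(hard_assignments(resp_a),
                              hard_assignments(resp_b))

    def test_photon_conservation(self, rng):
        data = rng.poisson(2.5, (60, 16, 14)).astype(float)
        pmask = np.ones((16, 14), bool)
        cfg = EMConfig(n_classes=3, n_rotations=16, max_iter=25, seed=4)
        w, occ, _, _ = em_cluster_polar(data, pmask, cfg)
        class_totals = w.reshape(3, -1).sum(axis=1)
        mean_total = data.reshape(60, -1).sum(axis=1).mean()
        assert (occ * class_totals).sum() == pytest.approx(mean_total,
                                                           rel=1e-6)

    def test_more_classes_than_frames_rejected(self, rng):
        data = rng.poisson(1.0, (3, 6, 6)).astype(float)
        with pytest.raises(ValueError):
            em_cluster_polar(data, np.ones((6, 6), bool),
                            EMConfig(n_classes=5, n_rotations=4))


class TestSelection:
    def test_explicit_ids_pass_through(self, two_population_stack):
        stack, labels = two_population_stack
        cfg = EMConfig(n_classes=2, n_rotations=24, max_iter=25, seed=5)
        model, resp = em_cluster(stack, cfg)
        ids = select_classes(model, rule=[0])
        assert ids == {0}
        frames = frames_for_classes(stack, resp, ids)
        # the selected class is one of the two populations
        hard = hard_assignments(resp)
        expected = set(int(i) for i in stack.frame_id[hard == 0])
        assert frames == expected

    def test_empty_rule_warns(self, two_population_stack):
        stack, _ = two_population_stack
        cfg = EMConfig(n_classes=2, n_rotations=8, max_iter=5, seed=6)
        model, _ = em_cluster(stack, cfg)
        with pytest.warns(UserWarning):
            ids = select_classes(model, rule=[])
        assert ids == set()

    def test_auto_rule_prefers_fringed_classes(self, square_geometry, rng):
        """Fringed single-particle frames vs structureless noise frames:
        the heuristic proposes only classes dominated by the former."""
        iv = render_intensity(make_phantom(PhantomSpec("sphere", 70.0, 8.0,
                                                       1.0), 72, 2.0), 4)
        cfg_s = SimConfig(n_frames=60, fluence_scale=400.0,
                          size_jitter_sd=0.0, single_fraction=1.0,
                          multi_fraction=0.0, blank_fraction=0.0, seed=21)
        singles = sample_patterns(iv, square_geometry, cfg_s).counts
        noise = rng.poisson(singles.mean(),
                            (60,) + square_geometry.panel_shape).astype(float)
        stack = PatternStack(counts=np.concatenate([singles, noise]),
                             geometry=square_geometry)
        emc = EMConfig(n_classes=2, n_rotations=24, max_iter=30, seed=7)
        model, resp = em_cluster(stack, emc)
        ids = select_classes(model, rule="auto", min_fringes=3, min_gamma=0.2)
        hard = hard_assignments(resp)
        single_class = np.bincount(hard[:60], minlength=2).argmax()
        assert ids == {int(single_class)}


class TestStableIntersection:
    def test_deterministic_runs_intersect_to_selection(self, rng):
        counts = rng.poisson(2.0, (30, 10, 10)).astype(float)
        geom_kwargs = dict(distance_m=0.075, pixel_size_um=75.0,
                           panel_shape=(10, 10), beam_center=(4.5, 4.5),
                           photon_energy_kev=1.7)
        from spivolve.geometry import DetectorGeometry
        stack = PatternStack(counts=counts,
                             geometry=DetectorGeometry(**geom_kwargs))
        cfg = EMConfig(n_classes=1, n_rotations=4, max_iter=3, seed=0)
        stable, report = stable_intersection(
            stack, cfg, n_runs=3, per_run_selection=[0], return_report=True)
        assert stable == set(int(i) for i in stack.frame_id)
        assert report["per_run_sizes"] == [30, 30, 30]

    def test_disjoint_selections_empty(self, two_population_stack):
        """Runs that select complementary populations intersect to the
        empty set."""
        stack, _ = two_population_stack
        cfg = EMConfig(n_classes=2, n_rotations=24, max_iter=25, seed=1)
        toggle = iter([True, False])

        def complementary(model, resp):
            hard = hard_assignments(resp)
            anchor = hard[0]          # class containing frame 0 this run
            return {int(anchor)} if next(toggle) else {int(1 - anchor)}

        stable = stable_intersection(stack, cfg, n_runs=2,
                                     per_run_selection=complementary)
        assert stable == set()

    def test_intersection_precision_not_worse(self, two_population_stack):
        """On labeled data, intersecting runs can only remove frames, so
        precision is at least the best single run's precision."""
        stack, labels = two_population_stack
        cfg = EMConfig(n_classes=2, n_rotations=24, max_iter=25, seed=3)
        true_small = set(int(i) for i in stack.frame_id[labels == 0])

        def pick_small_class(model, resp):
            hard = hard_assignments(resp)
            small = np.bincount(hard, minlength=2).argmin()
            return {int(small)}

        precisions = []
        selections = []
        for run in range(3):
            run_cfg = EMConfig(n_classes=2, n_rotations=24, max_iter=25,
                               seed=cfg.seed + 1000 * run)
            model, resp = em_cluster(stack, run_cfg)
            sel = frames_for_classes(stack, resp, pick_small_class(model, resp))
            selections.append(sel)
            if sel:
                precisions.append(len(sel & true_small) / len(sel))
        stable = set.intersection(*selections)
        if stable:
            stable_precision = len(stable & true_small) / len(stable)
            assert stable_precision >= max(precisions) - 1e-12
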