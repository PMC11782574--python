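"""Metrics: GI, gyral/sulcal classification, densities, stiffness maps."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from foldax.metrics import (
    angular_distribution,
    classify_gyri_sulci,
    count_reached,
    equivalent_stiffness,
    fiber_density,
    gyrification_index,
    local_stiffness_map,
    upper_hull_length,
    volume_fractions,
)


def sinusoid(A=1.0, lam=10.0, L=60.0, n=2001):
    x = np.linspace(0.0, L, n)
    return np.column_stack([x, A * np.sin(2 * np.pi * x / lam)])


class TestGyrificationIndex:
    def test_straight_line_is_one(self):
        x = np.linspace(0, 10, 50)
        pial = np.column_stack([x, np.full_like(x, 2.0)])
        assert gyrification_index(pial) == pytest.approx(1.0)

    def test_convex_arc_is_one(self):
        t = np.linspace(0.25 * np.pi, 0.75 * np.pi, 200)
        pial = np.column_stack([np.cos(t)[::-1], np.sin(t)[::-1]])
        assert gyrification_index(pial) == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_matches_quadrature_oracle(self):
        A, lam, L = 1.0, 10.0, 60.0
        pial = sinusoid(A, lam, L, n=240001)
        k = 2 * np.pi / lam

        def ds(x):
            return math.hypot(1.0, A * k * math.cos(k * x))

        arc, _ = quad(ds, 0, L, limit=400)

        # independent upper-hull oracle: Andrew monotone chain over the
        # sampled points (the implementation walks a scipy ConvexHull)
        def cross2(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

        chain = []
        for p in pial[np.lexsort((pial[:, 1], pial[:, 0]))]:
            while len(chain) >= 2 and cross2(chain[-2], chain[-1], p) >= 0:
                chain.pop()
            chain.append(p)
        chain = np.asarray(chain)
        hull = np.hypot(*np.diff(chain, axis=0).T).sum()
        assert gyrification_index(pial) == pytest.approx(arc / hull, abs=1e-6)

    def test_upper_hull_ignores_lower_excursions(self):
        # a dip below the chord must not lengthen the upper hull
        pts = np.array([[0.0, 0.0], [1.0, -5.0], [2.0, 0.0]])
        assert upper_hull_length(pts) == pytest.approx(2.0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            gyrification_index(np.array([[0.0, 0.0]]))


class TestClassification:
    def test_flat_geometry_ties_to_gyral(self):
        x = np.linspace(0, 10, 21)
        iface = np.column_stack([x, np.full_like(x, 4.5)])
        pial = np.column_stack([x, np.full_like(x, 6.0)])
        labels = classify_gyri_sulci(iface, pial)
        assert labels.all()

    def test_sinusoid_crests_gyral_troughs_sulcal(self):
        x = np.linspace(0, 60, 601)
        y = np.sin(2 * np.pi * x / 10.0)
        iface = np.column_stack([x, 4.5 + y])
        pial = np.column_stack([x, 6.0 + y])  # parallel fold, flat baseline
        labels = classify_gyri_sulci(iface, pial)
        crests = y > 0.5
        troughs = y < -0.5
        assert labels[crests].all()
        assert not labels[troughs].any()

    def test_labels_partition_interface(self):
        x = np.linspace(0, 60, 601)
        y = np.sin(2 * np.pi * x / 10.0)
        iface = np.column_stack([x, 4.5 + y])
        pial = np.column_stack([x, 6.0 + y])
        labels = classify_gyri_sulci(iface, pial)
        assert labels.dtype == bool and len(labels) == len(iface)

    def test_requires_matched_samples(self):
        with pytest.raises(ValueError):
            classify_gyri_sulci(np.zeros((5, 2)), np.zeros((4, 2)))


class TestFiberDensity:
    def _straight_interface(self, L=10.0, n=101):
        x = np.linspace(0, L, n)
        return np.column_stack([x, np.zeros_like(x)])

    def test_equal_lengths_follow_counts(self):
        # arc length is attributed half to each endpoint of a segment, so
        # with 101 points and labels x <= 5 the gyral side owns 50.5 of the
        # 100 half-segments (len_g = 5.05, len_s = 4.95)
        iface = self._straight_interface()
        labels = iface[:, 0] <= 5.0
        tips = np.array([[1.0, 0.0]] * 8 + [[9.0, 0.0]] * 2)
        dg, ds = fiber_density(tips, labels, iface)
        rho_g, rho_s = 8.0 / 5.05, 2.0 / 4.95
        assert dg == pytest.approx(100 * rho_g / (rho_g + rho_s))
        assert ds == pytest.approx(100 * rho_s / (rho_g + rho_s))

    def test_all_gyral(self):
        iface = self._straight_interface()
        labels = iface[:, 0] <= 5.0
        tips = np.array([[2.0, 0.0], [3.0, 0.0]])
        dg, ds = fiber_density(tips, labels, iface)
        assert dg == pytest.approx(100.0) and ds == pytest.approx(0.0)

    def test_length_normalization_arithmetic(self):
        # shorter sulcal region -> its raw density is inflated accordingly;
        # half-segment attribution puts the boundary half-segment (point at
        # x = 6.6 owns [6.55, 6.65]) on the gyral side: len_g = 6.65
        iface = self._straight_interface()
        labels = iface[:, 0] <= 20.0 / 3.0
        tips = np.array([[1.0, 0.0], [9.0, 0.0]])  # one tip each
        dg, ds = fiber_density(tips, labels, iface)
        rho_g, rho_s = 1.0 / 6.65, 1.0 / 3.35
        assert dg == pytest.approx(100 * rho_g / (rho_g + rho_s))
        assert ds == pytest.approx(100 * rho_s / (rho_g + rho_s))

    def test_sum_is_100(self, rng):
        iface = self._straight_interface()
        labels = rng.random(101) > 0.4
        tips = np.column_stack([rng.uniform(0, 10, 17), np.zeros(17)])
        dg, ds = fiber_density(tips, labels, iface)
        assert dg + ds == pytest.approx(100.0, abs=1e-9)

    def test_no_settled_tips_undefined(self):
        iface = self._straight_interface()
        labels = iface[:, 0] < 5.0
        assert fiber_density(np.empty((0, 2)), labels, iface) == (None, None)


class TestVolumeFractions:
    def test_no_fibers(self):
        from foldax.mesh import build_bilayer_mesh

        mesh = build_bilayer_mesh(6.0, 4.5, 1.5, 0.75)
        vf, vecm = volume_fractions(mesh)
        assert vf == 0.0 and vecm == 1.0

    def test_quarter_fiber(self):
        from foldax.kinematics import Region
        from foldax.mesh import build_bilayer_mesh

        mesh = build_bilayer_mesh(6.0, 4.5, 1.5, 0.75)
        region = mesh.elem_region.copy()
        wm = np.flatnonzero(region != int(Region.CORTEX))
        region[wm[: len(wm) // 4]] = int(Region.FIBER)
        vf, vecm = volume_fractions(mesh, region)
        assert vf == pytest.approx(0.25)
        assert vf + vecm == pytest.approx(1.0, abs=1e-12)


class TestStiffness:
    def test_fiber_free_neighbourhood_is_one(self):
        from foldax.mesh import build_bilayer_mesh

        mesh = build_bilayer_mesh(6.0, 4.5, 1.5, 0.75)
        vals = local_stiffness_map(mesh, np.array([[3.0, 2.0]]), mu_ratio=2.0)
        assert vals[0] == pytest.approx(1.0)

    def test_fully_fiber_disc_reaches_ratio(self):
        from foldax.kinematics import Region
        from foldax.mesh import build_bilayer_mesh

        mesh = build_bilayer_mesh(6.0, 4.5, 1.5, 0.75)
        region = mesh.elem_region.copy()
        region[region != int(Region.CORTEX)] = int(Region.FIBER)
        vals = local_stiffness_map(mesh, np.array([[3.0, 2.0]]), 2.0,
                                   region=region)
        assert vals[0] == pytest.approx(2.0)

    def test_map_bounded_by_ratio(self, rng):
        from foldax.kinematics import Region
        from foldax.mesh import build_bilayer_mesh

        mesh = build_bilayer_mesh(6.0, 4.5, 1.5, 0.75)
        region = mesh.elem_region.copy()
        wm = np.flatnonzero(region != int(Region.CORTEX))
        region[rng.choice(wm, size=len(wm) // 3, replace=False)] = int(Region.FIBER)
        pts = np.column_stack([rng.uniform(0, 6, 10), rng.uniform(0, 4.5, 10)])
        vals = local_stiffness_map(mesh, pts, 2.0, region=region)
        assert ((vals >= 1.0 - 1e-12) & (vals <= 2.0 + 1e-12)).all()

    def test_equivalent_stiffness_formula(self):
        from foldax.kinematics import Region
        from foldax.mesh import build_bilayer_mesh

        mesh = build_bilayer_mesh(6.0, 4.5, 1.5, 0.75)
        region = mesh.elem_region.copy()
        wm = np.flatnonzero(region != int(Region.CORTEX))
        region[wm[: len(wm) // 2]] = int(Region.FIBER)
        assert equivalent_stiffness(mesh, 2.0, region) == pytest.approx(1.5)
        assert equivalent_stiffness(mesh, 2.0, mesh.elem_region) == pytest.approx(1.0)


class TestAngularDistributionAndCounts:
    def _bundles(self, thetas):
        from foldax.agents import AxonBundle

        return [
            AxonBundle(id=i, tip=np.zeros(2), theta=t,
                       rng=np.random.default_rng(i))
            for i, t in enumerate(thetas)
        ]

    def test_single_direction_single_bin(self):
        hist, edges = angular_distribution(self._bundles([np.pi / 2] * 7), n_bins=18)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1

    def test_uniform_angles_flat_histogram(self, rng):
        thetas = rng.uniform(0, np.pi, 30000)
        hist, _ = angular_distribution(self._bundles(thetas), n_bins=10)
        assert hist.sum() == pytest.approx(1.0)
        assert np.allclose(hist, 0.1, atol=0.01)

    def test_folding_into_0_pi(self):
        hist, edges = angular_distribution(self._bundles([-np.pi / 4]), n_bins=4)
        # -pi/4 folds to 3pi/4
        assert hist[3] == pytest.approx(1.0)

    def test_count_reached_partition(self):
        from foldax.agents import BundleStatus

        bundles = self._bundles([0.1] * 6)
        bundles[0].status = BundleStatus.SETTLED
        bundles[1].status = BundleStatus.SETTLED
        bundles[2].status = BundleStatus.STALLED
        n_settled = count_reached(bundles)
        n_growing = sum(1 for b in bundles if b.status is BundleStatus.GROWING)
        n_stalled = sum(1 for b in bundles if b.status is BundleStatus.STALLED)
        assert n_settled == 2
        assert n_settled + n_growing + n_stalled == 6
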