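"""Gaussian capsule fitting and the T, O, H, R profiles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oildrop import (
    EffectivePointSet,
    build_profiles,
    default_scale,
    distance_kernel,
    fit_gaussian_capsule,
    intrinsic_profile,
    observed_profile,
    profiles_from_points,
    select_residues,
    theoretical_profile,
    uniform_profile,
)
from oildrop.errors import DegenerateGeometryError, ProfileError
from tests.conftest import random_point_set


def pset(points, intrinsic=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    h = np.ones(n) if intrinsic is None else np.asarray(intrinsic, dtype=float)
    labels = tuple(("A", str(i + 1), "ALA") for i in range(n))
    return EffectivePointSet(points=points, intrinsic=h, labels=labels)


class TestCapsule:
    def test_three_sigma_rule_on_known_extent(self):
        """Points spanning [-9, +9] along the long axis give sigma 3."""
        pts = pset([[-9, 0, 0], [9, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 1]])
        cap = fit_gaussian_capsule(pts)
        assert cap.sigmas[0] == pytest.approx(3.0)
        # flat third dimension hits the 1 A sigma floor
        assert cap.sigmas[2] >= 1.0

    def test_rigid_motion_leaves_sigmas_unchanged(self):
        rng = np.random.default_rng(11)
        pts = random_point_set(rng, 40)
        rot = Rotation.random(random_state=5).as_matrix()
        moved = EffectivePointSet(
            points=pts.points @ rot.T + np.array([10.0, -3.0, 7.0]),
            intrinsic=pts.intrinsic,
            labels=pts.labels,
        )
        np.testing.assert_allclose(
            fit_gaussian_capsule(pts).sigmas,
            fit_gaussian_capsule(moved).sigmas,
            atol=1e-9,
        )

    def test_sigmas_match_independent_eigendecomposition(self):
        """Oracle: recompute principal extents with raw numpy linalg."""
        rng = np.random.default_rng(3)
        xyz = rng.normal(scale=[8.0, 4.0, 2.0], size=(50, 3))
        pts = pset(xyz)
        cap = fit_gaussian_capsule(pts)

        centered = xyz - xyz.mean(0)
        evals, evecs = np.linalg.eigh(centered.T @ centered / len(xyz))
        order = np.argsort(evals)[::-1]
        expected = []
        for k in order:
            proj = centered @ evecs[:, k]
            expected.append(max(abs(proj).max() / 3.0, 1.0))
        np.testing.assert_allclose(cap.sigmas, expected, rtol=1e-10)

    def test_axes_are_proper_rotation(self):
        rng = np.random.default_rng(9)
        cap = fit_gaussian_capsule(random_point_set(rng, 30))
        np.testing.assert_allclose(cap.axes @ cap.axes.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(cap.axes) == pytest.approx(1.0)

    def test_degenerate_cloud_raises(self):
        with pytest.raises(DegenerateGeometryError):
            fit_gaussian_capsule(pset([[1, 1, 1], [1, 1, 1], [1, 1, 1]]))


class TestTheoreticalProfile:
    def test_center_residue_has_maximal_value(self):
        pts = pset([[0, 0, 0], [6, 0, 0], [-6, 0, 0], [0, 5, 0], [0, -5, 0]])
        cap = fit_gaussian_capsule(pts)
        t = theoretical_profile(cap, pts)
        assert np.argmax(t) == 0

    def test_symmetric_residues_get_equal_values(self):
        pts = pset([[7, 0, 0], [-7, 0, 0], [0, 3, 0], [0, -3, 0]])
        cap = fit_gaussian_capsule(pts)
        t = theoretical_profile(cap, pts)
        assert t[0] == pytest.approx(t[1], rel=1e-12)
        assert t[2] == pytest.approx(t[3], rel=1e-12)

    def test_five_residue_hand_computation(self):
        """Oracle: explicit per-residue Gaussian evaluation and normalization."""
        coords = np.array(
            [[-9.0, 0, 0], [-4.5, 0.5, 0.3], [0.0, -1.0, 0.2],
             [4.5, 1.0, -0.3], [9.0, 0, 0]]
        )
        pts = pset(coords)
        cap = fit_gaussian_capsule(pts)
        t = theoretical_profile(cap, pts)

        local = (coords - cap.center) @ cap.axes.T
        raw = [
            math.exp(-sum(local[i, k] ** 2 / (2 * cap.sigmas[k] ** 2)
                          for k in range(3)))
            for i in range(5)
        ]
        expected = np.array(raw) / sum(raw)
        np.testing.assert_allclose(t, expected, rtol=1e-12)


class TestObservedProfile:
    def test_kernel_endpoints(self):
        assert distance_kernel(0.0, 9.0) == pytest.approx(1.0)
        assert distance_kernel(9.0, 9.0) == pytest.approx(0.0, abs=1e-15)
        assert distance_kernel(10.0, 9.0) == 0.0

    def test_far_apart_residues_reduce_to_self_terms(self):
        pts = pset([[0, 0, 0], [100, 0, 0]], intrinsic=[0.3, 0.9])
        o = observed_profile(pts, cutoff=9.0)
        # raw values are (2*0.3, 2*0.9); normalized
        np.testing.assert_allclose(o, [0.25, 0.75])

    def test_four_residue_double_loop_oracle(self):
        """Oracle: brute-force pairwise summation, written independently."""
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0], [8, 8, 0]], float)
        h = np.array([0.2, 0.9, 0.5, 0.7])
        pts = pset(coords, intrinsic=h)
        c = 9.0

        def g(r):
            if r > c:
                return 0.0
            s = (r / c) ** 2
            return 1 - 0.5 * (7 * s - 9 * s**2 + 5 * s**3 - s**4)

        raw = np.zeros(4)
        for i in range(4):
            for j in range(4):
                raw[i] += (h[i] + h[j]) * g(np.linalg.norm(coords[i] - coords[j]))
        np.testing.assert_allclose(
            observed_profile(pts, cutoff=c), raw / raw.sum(), rtol=1e-12
        )

    @pytest.mark.parametrize("n", [5, 23, 50])
    def test_tree_method_equals_dense(self, n):
        rng = np.random.default_rng(n)
        pts = random_point_set(rng, n, spread=6.0)
        np.testing.assert_allclose(
            observed_profile(pts, method="tree"),
            observed_profile(pts, method="dense"),
            rtol=1e-10,
        )

    def test_self_term_toggle(self):
        pts = pset([[0, 0, 0], [3, 0, 0]], intrinsic=[0.1, 0.5])
        with_self = observed_profile(pts, include_self=True)
        without = observed_profile(pts, include_self=False)
        assert not np.allclose(with_self, without)
        # without self-term both residues share the same pair sum
        np.testing.assert_allclose(without, [0.5, 0.5])


class TestIntrinsicAndUniform:
    def test_homopolymer_is_uniform(self):
        pts = pset(np.random.default_rng(1).normal(size=(6, 3)),
                   intrinsic=[0.7] * 6)
        np.testing.assert_allclose(intrinsic_profile(pts), [1 / 6] * 6)

    def test_two_residue_closed_form(self):
        pts = pset([[0, 0, 0], [5, 0, 0]], intrinsic=[0.4, 1.2])
        np.testing.assert_allclose(intrinsic_profile(pts), [0.25, 0.75])

    def test_vqivyk_hand_normalization(self, scale):
        """H profile of the tau hexapeptide from the packaged scale table."""
        vals = np.array([scale[a] for a in
                         ("VAL", "GLN", "ILE", "VAL", "TYR", "LYS")])
        pts = pset(np.arange(18).reshape(6, 3), intrinsic=vals)
        np.testing.assert_allclose(intrinsic_profile(pts), vals / vals.sum())

    def test_all_zero_intrinsic_raises(self):
        pts = pset([[0, 0, 0], [5, 0, 0]], intrinsic=[0.0, 0.0])
        with pytest.raises(ProfileError):
            intrinsic_profile(pts)

    @pytest.mark.parametrize("n,expected", [(4, [0.25] * 4), (1, [1.0])])
    def test_uniform_values(self, n, expected):
        np.testing.assert_allclose(uniform_profile(n), expected)

    def test_uniform_rejects_zero(self):
        with pytest.raises(ProfileError):
            uniform_profile(0)


class TestBuildProfiles:
    def test_profiles_are_distributions(self, vqivyk_fibril, scale):
        ps = build_profiles(
            select_residues(vqivyk_fibril, "all"),
            select_residues(vqivyk_fibril, "chain:C"),
            scale=scale,
        )
        for v in (ps.T, ps.O, ps.H, ps.R):
            assert abs(v.sum() - 1.0) < 1e-9
            assert np.all(v >= 0)
        assert len(ps) == 6

    def test_identity_restriction(self, sorted_globule, scale):
        whole = select_residues(sorted_globule, "all")
        a = build_profiles(whole, whole, scale=scale)
        b = build_profiles(whole, None, scale=scale)
        np.testing.assert_array_equal(a.T, b.T)
        np.testing.assert_array_equal(a.O, b.O)

    def test_rigid_motion_invariance_of_all_profiles(self, scale):
        """T, O, H, R identical after random rotation + translation."""
        rng = np.random.default_rng(21)
        pts = random_point_set(rng, 35, spread=8.0)
        rot = Rotation.random(random_state=17).as_matrix()
        moved = EffectivePointSet(
            points=pts.points @ rot.T + np.array([-4.0, 12.0, 3.0]),
            intrinsic=pts.intrinsic,
            labels=pts.labels,
        )
        a = profiles_from_points(pts)
        b = profiles_from_points(moved)
        for name in ("T", "O", "H", "R"):
            np.testing.assert_allclose(
                getattr(a, name), getattr(b, name), atol=1e-9
            )

    def test_centrally_sorted_hydrophobicity_correlates_t_with_o(self):
        """Monotone hydrophobicity-vs-centrality gives rank corr(T, O) > 0.7."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(5)
        xyz = rng.normal(scale=6.0, size=(80, 3))
        dist = np.linalg.norm(xyz - xyz.mean(0), axis=1)
        h = 1.0 / (1.0 + dist)  # decreasing with distance from center
        pts = pset(xyz, intrinsic=h)
        ps = profiles_from_points(pts)
        assert spearmanr(ps.T, ps.O).statistic > 0.7
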