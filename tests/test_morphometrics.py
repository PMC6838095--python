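"""Procrustes superimposition, centroid size, and between-group PCA."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapeshift.morphometrics import (DegenerateConfigurationError,
                                      LandmarkSet, bgpca, centroid_size, gpa,
                                      opa_to_consensus, procrustes_distance,
                                      project, read_landmarks_csv, read_tps)


def rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_config(rng, k=8):
    return rng.normal(size=(k, 3))


def make_set(configs, species=None):
    n = len(configs)
    species = species or [f"sp{i}" for i in range(n)]
    return LandmarkSet(specimen_ids=[f"s{i}" for i in range(n)],
                       species=species, coordinates=np.stack(configs))


class TestCentroidSize:
    def test_hand_value(self):
        cfg = np.array([[0.0, 0, 0], [3.0, 4, 0]])
        assert centroid_size(cfg) == pytest.approx(np.sqrt(12.5))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), scale=st.floats(0.1, 10))
    def test_rigid_invariance_and_homogeneity(self, seed, scale):
        rng = np.random.default_rng(seed)
        cfg = random_config(rng)
        R = rotation(rng)
        shift = rng.normal(size=3)
        assert centroid_size(cfg @ R + shift) == pytest.approx(centroid_size(cfg))
        assert centroid_size(cfg * scale) == pytest.approx(scale * centroid_size(cfg))

    def test_coincident_landmarks_error(self):
        cfg = np.zeros((5, 3))
        lms = make_set([cfg, cfg + 1])
        with pytest.raises(DegenerateConfigurationError):
            gpa(lms)


class TestGPA:
    def test_rigid_motion_gives_zero_procrustes_distance(self, rng):
        cfg = random_config(rng)
        Rz90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        moved = cfg @ Rz90 + np.array([5.0, -3.0, 2.0])
        aligned = gpa(make_set([cfg, moved]))
        d = np.sqrt(((aligned.coordinates[0] - aligned.coordinates[1]) ** 2).sum())
        assert d < 1e-9

    def test_alignment_invariant_to_rigid_motion_and_scale(self, rng):
        configs = [random_config(rng) for _ in range(6)]
        base = gpa(make_set(configs))
        moved = [c * rng.uniform(0.5, 2) @ rotation(rng) + rng.normal(size=3)
                 for c in configs]
        redo = gpa(make_set(moved))
        assert np.allclose(base.coordinates, redo.coordinates, atol=1e-9)

    def test_idempotence(self, rng):
        """Re-running GPA on aligned output is a fixed point up to the
        second-order curvature of the tangent projection."""
        template = random_config(rng)
        configs = [template + 1e-3 * rng.normal(size=(8, 3)) for _ in range(5)]
        a1 = gpa(make_set(configs))
        a2 = gpa(make_set(list(a1.coordinates)))
        assert np.abs(a1.coordinates - a2.coordinates).max() < 1e-4
        assert np.abs(a1.consensus - a2.consensus).max() < 1e-6

    def test_centroid_sizes_recorded(self, rng):
        cfg = random_config(rng)
        aligned = gpa(make_set([cfg, 2 * cfg]))
        assert aligned.centroid_sizes[1] == pytest.approx(2 * aligned.centroid_sizes[0])
        assert np.allclose(aligned.ln_centroid_sizes, np.log(aligned.centroid_sizes))

    def test_mean_distance_to_consensus_matches_monte_carlo(self):
        """Specimens = template + isotropic noise: mean Procrustes distance to
        the consensus approaches its Monte-Carlo expectation."""
        rng = np.random.default_rng(42)
        template = random_config(rng, k=10)
        template = (template - template.mean(0))
        template /= np.sqrt((template ** 2).sum())
        sigma = 0.01
        dists = []
        for _ in range(4):
            configs = [template + rng.normal(0, sigma, size=(10, 3)) for _ in range(20)]
            a = gpa(make_set(configs))
            cons = a.consensus.reshape(-1)
            flat = a.flat
            dists.append(np.mean(np.sqrt(((flat - cons) ** 2).sum(1))))
        # oracle: independent Monte-Carlo replicates agree with each other
        # and with the analytic small-noise scale sigma * sqrt(3k - 7)
        expected = sigma * np.sqrt(3 * 10 - 7)
        assert np.mean(dists) == pytest.approx(expected, rel=0.25)

    def test_degenerate_configuration_error(self):
        flat_cfg = np.zeros((6, 3))
        flat_cfg[:, 0] = np.arange(6)
        flat_cfg[:, 1] = np.arange(6) ** 2
        lms = make_set([flat_cfg, flat_cfg])
        with pytest.raises(DegenerateConfigurationError):
            gpa(lms)


class TestBgPCA:
    def test_two_groups_single_axis_symmetric(self, rng):
        base = random_config(rng)
        shift = 0.01 * rng.normal(size=(8, 3))
        configs = [base + (shift if i < 3 else -shift)
                   + 0.0001 * rng.normal(size=(8, 3)) for i in range(6)]
        species = ["g1"] * 3 + ["g2"] * 3
        space = bgpca(gpa(make_set(configs, species)))
        assert space.eigenvectors.shape[1] == 1
        s = space.group_mean_scores[:, 0]
        assert s[0] == pytest.approx(-s[1], rel=1e-6)

    def test_axis_count_at_most_g_minus_1(self, rng):
        configs = [random_config(rng) for _ in range(8)]
        species = [f"g{i % 4}" for i in range(8)]
        space = bgpca(gpa(make_set(configs, species)))
        assert space.eigenvectors.shape[1] <= 3

    def test_eigenvalues_conserve_group_mean_variance(self, rng):
        configs = [random_config(rng) for _ in range(9)]
        species = [f"g{i % 3}" for i in range(9)]
        aligned = gpa(make_set(configs, species))
        space = bgpca(aligned)
        flat = aligned.flat
        sp = np.asarray(aligned.species, dtype=object)
        means = np.stack([flat[sp == g].mean(0) for g in space.group_names])
        total = ((means - means.mean(0)) ** 2).sum() / (len(space.group_names) - 1)
        assert space.eigenvalues.sum() == pytest.approx(total)

    def test_group_scores_zero_mean(self, rng):
        configs = [random_config(rng) for _ in range(10)]
        species = [f"g{i % 5}" for i in range(10)]
        space = bgpca(gpa(make_set(configs, species)))
        assert np.allclose(space.group_mean_scores.mean(axis=0), 0, atol=1e-12)

    def test_projection_consistency(self, rng):
        configs = [random_config(rng) for _ in range(9)]
        species = [f"g{i % 3}" for i in range(9)]
        aligned = gpa(make_set(configs, species))
        space = bgpca(aligned)
        flat = aligned.flat
        sp = np.asarray(aligned.species, dtype=object)
        for j, g in enumerate(space.group_names):
            got = project(space, flat[sp == g].mean(0))
            assert np.allclose(got[0], space.group_mean_scores[j], atol=1e-10)

    def test_grand_mean_projects_to_zero(self, rng):
        configs = [random_config(rng) for _ in range(6)]
        species = [f"g{i % 2}" for i in range(6)]
        space = bgpca(gpa(make_set(configs, species)))
        assert np.allclose(project(space, space.grand_mean), 0, atol=1e-12)

    def test_eigenvector_projection_is_unit_score(self, rng):
        configs = [random_config(rng) for _ in range(9)]
        species = [f"g{i % 3}" for i in range(9)]
        space = bgpca(gpa(make_set(configs, species)))
        c = 0.37
        probe = space.grand_mean + c * space.eigenvectors[:, 0]
        got = project(space, probe)[0]
        assert got[0] == pytest.approx(c)
        assert np.allclose(got[1:], 0, atol=1e-12)

    def test_equal_groups_zero_within_variance_matches_plain_pca(self, rng):
        """With one specimen per group, bgPCA equals ordinary PCA of the
        specimen matrix (oracle: numpy SVD of centred specimens)."""
        configs = [random_config(rng) for _ in range(5)]
        species = [f"g{i}" for i in range(5)]
        aligned = gpa(make_set(configs, species))
        space = bgpca(aligned)
        X = aligned.flat - aligned.flat.mean(0)
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        vals = s[:4] ** 2 / 4
        assert np.allclose(space.eigenvalues, vals, atol=1e-12)
        for j in range(4):
            dot = abs(space.eigenvectors[:, j] @ vt[j])
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_unknown_group_and_too_few_groups(self, rng):
        configs = [random_config(rng) for _ in range(4)]
        aligned = gpa(make_set(configs, ["a", "a", "b", "b"]))
        with pytest.raises(ValueError):
            bgpca(aligned, include_in_eigenanalysis=["a", "zz"])
        with pytest.raises(ValueError):
            bgpca(aligned, include_in_eigenanalysis=["a"])

    def test_excluded_group_projected_post_hoc(self, rng):
        """Fossils kept out of the eigenanalysis still receive scores, and
        the eigenbasis ignores them."""
        configs = [random_config(rng) for _ in range(9)]
        species = [f"g{i % 3}" for i in range(9)]
        aligned = gpa(make_set(configs, species))
        full = bgpca(aligned, include_in_eigenanalysis=["g0", "g1"])
        reduced_set = make_set([c for c, s in zip(configs, species) if s != "g2"],
                               [s for s in species if s != "g2"])
        # same eigenbasis dimension as a 2-group analysis
        assert full.eigenvectors.shape[1] == 1
        assert full.specimen_scores.shape[0] == 9


class TestOPA:
    def test_opa_matches_joint_alignment_for_identical_shape(self, rng):
        cfg = random_config(rng)
        aligned = gpa(make_set([cfg, cfg @ rotation(rng) * 2.0]))
        fossil = cfg @ rotation(rng) + rng.normal(size=3)
        placed = opa_to_consensus(fossil, aligned.consensus)
        d = np.sqrt(((placed - aligned.coordinates[0]) ** 2).sum())
        assert d < 1e-8

    def test_procrustes_distance_zero_for_rigid_copies(self, rng):
        cfg = random_config(rng)
        assert procrustes_distance(cfg, cfg @ rotation(rng) * 3 + 1) < 1e-12


class TestReaders:
    def test_long_csv_round_trip(self, rng):
        csv = io.StringIO(
            "specimen,species,landmark_index,x,y,z,is_fossil\n" + "\n".join(
                f"s{i},sp{i % 2},{j},{rng.normal()},{rng.normal()},{rng.normal()},"
                f"{i == 3}"
                for i in range(4) for j in range(5)))
        lms = read_landmarks_csv(csv)
        assert lms.n_specimens == 4 and lms.n_landmarks == 5
        assert lms.species == ["sp0", "sp1", "sp0", "sp1"]
        assert list(lms.is_fossil) == [False, False, False, True]

    def test_tps_reader(self):
        text = """LM3=4
0 0 0
1 0 0
0 1 0
0 0 1
ID=spec_a
LM3=4
0 0 0
2 0 0
0 2 0
0 0 2
ID=spec_b
"""
        lms = read_tps(text)
        assert lms.specimen_ids == ["spec_a", "spec_b"]
        assert lms.coordinates.shape == (2, 4, 3)
        assert lms.coordinates[1, 1, 0] == 2.0
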