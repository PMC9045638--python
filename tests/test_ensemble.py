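"""Bound selection, symmetric RMSD clustering, and interface descriptors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from spcdimer.constants import kt
from spcdimer.ensemble import (choose_n_clusters, cluster_bound,
                               cluster_centroid, cluster_free_energies,
                               contact_probability_map, motif_report,
                               select_bound, symmetric_rmsd,
                               symmetric_rmsd_matrix, topology_descriptors)
from spcdimer.reweight import WeightedEnsemble
from spcdimer.synthetic import default_planted_fes, synthetic_bound_ensemble
from spcdimer.toyhelix import DEFAULT_TEMPLATES, frames_from_cvs

from conftest import random_rotation


def make_ensemble(weights):
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    return WeightedEnsemble(np.zeros(len(weights), dtype=int),
                            np.arange(len(weights)), weights)


@pytest.fixture(scope="module")
def bound_set(topo):
    """Seeded thermal bound ensemble from the three planted topologies."""
    fes, _ = default_planted_fes(topo)
    coords, labels, cvs = synthetic_bound_ensemble(fes, 150, seed=9)
    return coords, labels


class TestSelectBound:
    def test_all_unbound_raises(self):
        ens = make_ensemble(np.ones(5))
        with pytest.raises(ValueError):
            select_bound(ens, np.full(5, 2.0))

    def test_cutoff_boundary_inclusive(self):
        ens = make_ensemble(np.ones(3))
        sub, mask = select_bound(ens, np.array([0.60, 0.61, 0.3]))
        assert list(mask) == [True, False, True]

    def test_weight_share_bookkeeping(self):
        ens = make_ensemble([1, 2, 3, 4])
        sub, mask = select_bound(ens, np.array([0.5, 0.7, 0.5, 0.7]))
        assert sub.total_weight == pytest.approx(0.4)
        assert sub.weights.sum() == pytest.approx(1.0)


class TestSymmetricRMSD:
    def test_self_is_zero(self, bound_set, topo):
        coords, _ = bound_set
        assert symmetric_rmsd(coords[0], coords[0], topo) == pytest.approx(0.0, abs=1e-12)

    def test_monomer_swap_is_zero(self, bound_set, topo):
        coords, _ = bound_set
        swapped = coords[0][::-1].copy()
        assert symmetric_rmsd(coords[0], swapped, topo) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_zero(self, bound_set, topo, rng):
        coords, _ = bound_set
        rot = random_rotation(rng)
        moved = coords[0] @ rot.T + rng.standard_normal(3)
        assert symmetric_rmsd(coords[0], moved, topo) == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_superposition(self, bound_set, topo):
        # cross-check the hand-batched Kabsch against scipy's align_vectors
        coords, _ = bound_set
        a, b = coords[0], coords[3]
        idx = topo.bead_indices(topo.groups["helical_segment"])
        pa = np.concatenate([a[0][idx], a[1][idx]])
        pb = np.concatenate([b[0][idx], b[1][idx]])
        pa = pa - pa.mean(axis=0)
        pb = pb - pb.mean(axis=0)
        rot, rssd = Rotation.align_vectors(pa, pb)
        direct = rssd / np.sqrt(len(pa))
        assert symmetric_rmsd(a, b, topo) <= direct + 1e-9
        # the direct (unswapped) term agrees with scipy exactly
        from spcdimer.ensemble import _kabsch_rmsd_one_to_many
        assert _kabsch_rmsd_one_to_many(pa, pb[None])[0] == pytest.approx(
            direct, abs=1e-9)

    def test_pseudometric_triangle_inequality(self, bound_set, topo):
        coords, _ = bound_set
        sub = coords[:12]
        mat = symmetric_rmsd_matrix(sub, topo)
        assert np.allclose(mat, mat.T, atol=1e-12)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-9

    def test_matrix_matches_pairwise(self, bound_set, topo):
        coords, _ = bound_set
        sub = coords[:6]
        mat = symmetric_rmsd_matrix(sub, topo)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mat[i, j] == pytest.approx(
                    symmetric_rmsd(sub[i], sub[j], topo), abs=1e-9)

    def test_mismatched_beads_raise(self, bound_set, topo):
        coords, _ = bound_set
        with pytest.raises(ValueError):
            symmetric_rmsd(coords[0], coords[1][:, :10], topo)


class TestClustering:
    def test_planted_topologies_recovered(self, bound_set, topo):
        coords, labels_true = bound_set
        mat = symmetric_rmsd_matrix(coords, topo)
        labels, heights, _ = cluster_bound(mat, 3)
        assert adjusted_rand_score(labels_true, labels) >= 0.95

    def test_duplication_invariance(self, bound_set, topo):
        coords, _ = bound_set
        sub = coords[:30]
        mat = symmetric_rmsd_matrix(sub, topo)
        labels, _, _ = cluster_bound(mat, 3)
        dup = np.concatenate([sub, sub])
        mat2 = symmetric_rmsd_matrix(dup, topo)
        labels2, _, _ = cluster_bound(mat2, 3)
        assert np.array_equal(labels2[:30], labels)
        assert np.array_equal(labels2[30:], labels)

    def test_single_cluster_degenerate(self, bound_set, topo):
        coords, _ = bound_set
        mat = symmetric_rmsd_matrix(coords[:10], topo)
        labels, _, _ = cluster_bound(mat, 1)
        assert set(labels) == {0}

    def test_too_few_frames_raise(self, bound_set, topo):
        coords, _ = bound_set
        mat = symmetric_rmsd_matrix(coords[:2], topo)
        with pytest.raises(ValueError):
            cluster_bound(mat, 3)

    def test_sklearn_and_scipy_cuts_agree(self, bound_set, topo):
        # dual route: the scikit-learn partition equals cutting the scipy
        # dendrogram at the same cluster count
        from scipy.cluster.hierarchy import fcluster
        coords, _ = bound_set
        mat = symmetric_rmsd_matrix(coords[:60], topo)
        labels, _, z = cluster_bound(mat, 3)
        scipy_labels = fcluster(z, t=3, criterion="maxclust")
        assert adjusted_rand_score(labels, scipy_labels) == 1.0

    def test_gap_selection_prefers_three(self, bound_set, topo):
        coords, _ = bound_set
        mat = symmetric_rmsd_matrix(coords, topo)
        _, heights, _ = cluster_bound(mat, 3)
        assert choose_n_clusters(heights) == 3


class TestClusterEstimates:
    def test_equal_weights_equal_free_energy(self):
        ens = make_ensemble(np.ones(10))
        ens.total_weight = 0.5
        labels = np.repeat([0, 1], 5)
        out = cluster_free_energies(labels, ens, unbound_weight=0.5)
        assert out[0] == pytest.approx(out[1])

    def test_closed_form_two_kt(self):
        kT = kt(310.0)
        w = np.concatenate([np.full(5, np.e ** 2), np.ones(5)])
        ens = make_ensemble(w)
        ens.total_weight = 0.5
        labels = np.repeat([0, 1], 5)
        out = cluster_free_energies(labels, ens, unbound_weight=0.5)
        assert out[0] - out[1] == pytest.approx(-2 * kT, rel=1e-9)

    def test_centroid_tie_breaks_to_lowest_index(self):
        mat = np.zeros((4, 4))
        cents = cluster_centroid(np.zeros(4, dtype=int), mat, np.ones(4))
        assert cents[0] == 0

    def test_centroid_matches_brute_force(self, bound_set, topo, rng):
        coords, _ = bound_set
        sub = coords[:9]
        mat = symmetric_rmsd_matrix(sub, topo)
        w = rng.uniform(0.1, 1.0, 9)
        labels = np.zeros(9, dtype=int)
        cents = cluster_centroid(labels, mat, w)
        costs = [(mat[i] * w).sum() for i in range(9)]
        assert cents[0] == int(np.argmin(costs))

    def test_centroid_is_member(self, bound_set, topo):
        coords, labels_true = bound_set
        mat = symmetric_rmsd_matrix(coords, topo)
        cents = cluster_centroid(labels_true, mat, np.ones(len(mat)))
        for lab, idx in cents.items():
            assert labels_true[idx] == lab


class TestDescriptors:
    def test_identical_frames_degenerate_distribution(self, bound_set, topo):
        coords, _ = bound_set
        same = np.repeat(coords[:1], 5, axis=0)
        out = topology_descriptors(np.zeros(5, dtype=int), same,
                                   np.ones(5), topo)
        entry = out[0]
        for key in ("nterm", "mid", "cterm"):
            vals = entry[key]["values"]
            assert np.ptp(vals) == 0.0
            assert abs(entry[key]["mode"] - vals[0]) <= 0.025 + 1e-12
            assert entry[key]["mean"] == pytest.approx(vals[0])

    def test_planted_modes_recovered(self, bound_set, topo):
        coords, labels = bound_set
        out = topology_descriptors(labels, coords, np.ones(len(labels)), topo)
        by_name = {t.name: t for t in DEFAULT_TEMPLATES}
        for k, t in enumerate(DEFAULT_TEMPLATES):
            entry = out[k]
            got = (entry["nterm"]["mode"], entry["mid"]["mode"],
                   entry["cterm"]["mode"])
            # the planted value must lie in the mode bin or one adjacent bin
            for g, want in zip(got, t.region_targets):
                assert abs(g - want) < 1.5 * 0.05
            assert entry["crossing_angle"]["mean"] == pytest.approx(
                t.crossing_angle_target, abs=3.0)


class TestContactMaps:
    def test_identical_frames_probabilities_binary(self, bound_set, topo):
        coords, _ = bound_set
        same = np.repeat(coords[:1], 4, axis=0)
        maps = contact_probability_map(np.zeros(4, dtype=int), same,
                                       np.ones(4), topo, symmetrize=False)
        probs = maps[0].probabilities
        assert set(np.unique(probs)) <= {0.0, 1.0}

    def test_symmetrized_map_transpose_invariant(self, bound_set, topo):
        coords, labels = bound_set
        maps = contact_probability_map(labels, coords,
                                       np.ones(len(labels)), topo)
        for cmap in maps.values():
            assert np.allclose(cmap.probabilities, cmap.probabilities.T,
                               atol=1e-12)
            assert np.all(cmap.probabilities >= 0)
            assert np.all(cmap.probabilities <= 1)

    def test_parallel_interface_residues(self, bound_set, topo):
        coords, labels = bound_set
        maps = contact_probability_map(labels, coords, np.ones(len(labels)), topo)
        marg = maps[0].marginal  # cluster 0 = parallel topology
        high = {r + 1 for r in np.flatnonzero(marg > 0.5)}
        assert high & {21, 22}
        assert high & {25, 26}
        assert high & {29, 30}
        assert high & {32, 33}
        # the interface lives on the C-terminal half, not the terminal tails
        assert not high & {1, 2, 3, 4, 5, 6, 7}

    def test_display_threshold_masks_only_rendering(self, bound_set, topo):
        coords, labels = bound_set
        maps = contact_probability_map(labels, coords, np.ones(len(labels)), topo)
        cmap = maps[0]
        shown = cmap.displayed()
        assert np.all(shown[cmap.probabilities <= 0.2] == 0.0)
        assert (cmap.probabilities[(cmap.probabilities > 0)
                                   & (cmap.probabilities <= 0.2)] > 0).all()


class TestMotifReport:
    def test_interface_motif_string(self, topo):
        marginal = np.zeros(35)
        for r in (21, 25, 29, 33):
            marginal[r - 1] = 0.9
        rep = motif_report(marginal, topo, threshold=0.5)
        assert rep["motif"] == "V21xxxVxxxGxxxM33"
        assert rep["residues"] == [21, 25, 29, 33]

    def test_empty_profile(self, topo):
        rep = motif_report(np.zeros(35), topo, threshold=0.5)
        assert rep["motif"] == "" and rep["residues"] == []

    def test_unattainable_threshold(self, topo):
        rep = motif_report(np.ones(35), topo, threshold=1.01)
        assert rep["residues"] == []
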