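"""Ensemble combination, alignment, coordinate PCA, clustering, occupancy."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from epishift.ensemble import (
    EnsembleCollection,
    align_ensemble,
    ca_mask,
    cluster_midpoints,
    cluster_profile,
    combine_trajectories,
    coordinate_pca,
    hierarchical_clusters,
    occupancy_timecourse,
    select_k_elbow,
)
from epishift.structure_io import AtomRecord, Frame, Trajectory
from epishift.synthetic import ConformerScenario, simulate_model_set


def _traj(coords_list, model="WT", repeat=0):
    topo = [
        AtomRecord(i + 1, "CA", "C", i + 1, "GLY", "A", 1.7)
        for i in range(coords_list[0].shape[0])
    ]
    frames = [Frame(c, time_label=float(i)) for i, c in enumerate(coords_list)]
    return Trajectory(topo, frames, model_label=model, repeat_id=repeat)


class TestCombine:
    def test_concatenation_preserves_provenance(self, rng):
        a = _traj([rng.normal(size=(4, 3)) for _ in range(10)], model="WT")
        b = _traj([rng.normal(size=(4, 3)) for _ in range(10)], model="VARIANT")
        ens = combine_trajectories([a, b])
        assert ens.n_frames == 20
        counts = ens.provenance["model_label"].value_counts()
        assert counts["WT"] == 10 and counts["VARIANT"] == 10

    def test_mismatched_atom_name_cites_index(self, rng):
        a = _traj([rng.normal(size=(8, 3))])
        b = _traj([rng.normal(size=(8, 3))])
        bad = AtomRecord(8, "CB", "C", 8, "GLY", "A", 1.7)
        b.topology[7] = bad
        with pytest.raises(ValueError, match="atom 7"):
            combine_trajectories([a, b])

    def test_single_trajectory_rejected(self, rng):
        a = _traj([rng.normal(size=(4, 3))])
        with pytest.raises(ValueError):
            combine_trajectories([a])


class TestAlign:
    def test_rigid_copies_collapse(self, rng):
        base = rng.normal(size=(6, 3)) * 5
        frames = []
        for _ in range(8):
            rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            frames.append(base @ rot.T + rng.normal(size=3) * 10)
        a = _traj(frames[:4])
        b = _traj(frames[4:], model="VARIANT")
        ens = align_ensemble(combine_trajectories([a, b]))
        for i in range(1, ens.n_frames):
            d = np.sqrt(np.mean(np.sum((ens.coordinates[i] - ens.coordinates[0]) ** 2, axis=1)))
            assert d <= 1e-6

    def test_idempotent(self, small_ensemble):
        ens, _, _, _ = small_ensemble
        again = align_ensemble(ens, ca_mask(ens.topology))
        assert np.max(np.abs(again.coordinates - ens.coordinates)) <= 1e-6

    def test_second_pass_tightens_fit_to_mean(self, rng):
        base = rng.normal(size=(5, 3)) * 4
        frames = [base + rng.normal(size=(5, 3)) for _ in range(12)]
        ens = combine_trajectories([_traj(frames[:6]), _traj(frames[6:], model="VARIANT")])

        def mean_rmsd_after_single_pass(reference):
            from epishift.geometry import kabsch_superpose

            fitted = np.array(
                [kabsch_superpose(c, reference).apply(c) for c in ens.coordinates]
            )
            mean = fitted.mean(axis=0)
            return np.mean(
                [np.sqrt(np.mean(np.sum((f - mean) ** 2, axis=1))) for f in fitted]
            )

        one_pass = mean_rmsd_after_single_pass(ens.coordinates[0])
        two_pass_ens = align_ensemble(ens)
        mean2 = two_pass_ens.coordinates.mean(axis=0)
        two_pass = np.mean(
            [
                np.sqrt(np.mean(np.sum((f - mean2) ** 2, axis=1)))
                for f in two_pass_ens.coordinates
            ]
        )
        assert two_pass <= one_pass + 1e-9


class TestPca:
    def test_identical_frames_zero_eigenvalues(self, rng):
        base = rng.normal(size=(5, 3))
        ens = combine_trajectories([_traj([base] * 3), _traj([base] * 3, model="VARIANT")])
        ens = align_ensemble(ens)
        model = coordinate_pca(ens)
        assert np.all(model.eigenvalues <= 1e-12)

    def test_unaligned_ensemble_rejected(self, rng):
        ens = combine_trajectories(
            [_traj([rng.normal(size=(4, 3))]), _traj([rng.normal(size=(4, 3))])]
        )
        with pytest.raises(ValueError, match="align"):
            coordinate_pca(ens)

    def test_eigenvalue_sum_equals_total_variance(self, small_ensemble):
        ens, pca, _, _ = small_ensemble
        X = ens.coordinates[:, pca.atom_mask, :].reshape(ens.n_frames, -1)
        total = np.var(X, axis=0, ddof=1).sum()
        assert pca.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_full_reconstruction(self, small_ensemble):
        ens, pca, _, _ = small_ensemble
        X = ens.coordinates[:, pca.atom_mask, :].reshape(ens.n_frames, -1)
        recon = pca.projections @ pca.components + pca.mean_coordinates
        assert np.max(np.abs(recon - X)) <= 1e-8

    def test_components_orthonormal(self, small_ensemble):
        _, pca, _, _ = small_ensemble
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_pc1_separates_planted_states(self, small_ensemble):
        ens, pca, states, _ = small_ensemble
        p1 = pca.projections[:, 0]
        o = p1[np.array(states) == "O"]
        j = p1[np.array(states) == "J"]
        # linearly separable: no overlap between the O and J supports
        assert max(o.min(), j.min()) > min(o.max(), j.max()) or (
            o.max() < j.min() or j.max() < o.min()
        )


class TestClustering:
    def test_two_planted_states_exact_recovery(self, rng):
        # two tight blobs in 4-D score space
        a = rng.normal(size=(30, 4)) + np.array([50, 0, 0, 0])
        b = rng.normal(size=(25, 4)) - np.array([50, 0, 0, 0])
        X = np.vstack([a, b])
        truth = [0] * 30 + [1] * 25
        cl = hierarchical_clusters(X, n_pcs=4, n_clusters=2)
        assert adjusted_rand_score(truth, cl.assignment) == 1.0

    def test_singletons_when_k_equals_n(self, rng):
        X = rng.normal(size=(7, 4))
        cl = hierarchical_clusters(X, n_pcs=4, n_clusters=7)
        assert sorted(cl.assignment) == list(range(1, 8))

    def test_partition_invariant_to_frame_order(self, rng):
        X = np.vstack(
            [rng.normal(size=(20, 4)) + off for off in ([8, 0, 0, 0], [-8, 0, 0, 0], [0, 8, 0, 0])]
        )
        cl1 = hierarchical_clusters(X, n_clusters=3)
        perm = rng.permutation(X.shape[0])
        cl2 = hierarchical_clusters(X[perm], n_clusters=3)
        # same partition up to label names
        assert adjusted_rand_score(cl1.assignment[perm], cl2.assignment) == 1.0

    def test_k_larger_than_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_clusters(rng.normal(size=(5, 4)), n_clusters=6)

    def test_labels_relabelled_by_first_occurrence(self, rng):
        X = np.vstack([rng.normal(size=(10, 4)) + [9, 0, 0, 0], rng.normal(size=(10, 4))])
        cl = hierarchical_clusters(X, n_clusters=2)
        assert cl.assignment[0] == 1


class TestElbow:
    def test_three_separated_states(self, rng):
        X = np.vstack(
            [rng.normal(size=(60, 4)) + off for off in ([30, 0, 0, 0], [-30, 0, 0, 0], [0, 30, 0, 0])]
        )
        assert select_k_elbow(X, n_pcs=4, k_range=range(1, 9), seed=1) == 3

    def test_single_blob_low_confidence(self, rng, caplog):
        X = rng.normal(size=(100, 4))
        with caplog.at_level("WARNING"):
            k = select_k_elbow(X, n_pcs=4, k_range=range(1, 9), seed=1)
        assert k in (1, 2) or "low-confidence" in caplog.text

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(80, 4)) * 3
        runs = {select_k_elbow(X, n_pcs=4, k_range=range(1, 7), seed=9) for _ in range(2)}
        assert len(runs) == 1


class TestMidpointsProfileOccupancy:
    def test_midpoint_of_singleton_cluster(self, rng):
        X = rng.normal(size=(5, 4))
        cl = hierarchical_clusters(X, n_clusters=5)
        for cid, frame in cl.midpoint_frame.items():
            assert cl.assignment[frame] == cid

    def test_exact_centroid_frame_wins(self):
        X = np.array([[0.0, 0, 0, 0], [1.0, 0, 0, 0], [-1.0, 0, 0, 0]])
        cl = hierarchical_clusters(X, n_clusters=1)
        assert cl.midpoint_frame[1] == 0

    def test_midpoints_match_exhaustive_scan(self, rng):
        X = rng.normal(size=(40, 4)) * 5
        cl = hierarchical_clusters(X, n_clusters=4)
        for cid in range(1, 5):
            members = np.flatnonzero(cl.assignment == cid)
            centroid = X[members, : cl.n_pcs_used].mean(axis=0)
            d = np.linalg.norm(X[members, : cl.n_pcs_used] - centroid, axis=1)
            assert cl.midpoint_frame[cid] == members[np.argmin(d)]

    def test_profile_identical_frames(self, rng):
        base = rng.normal(size=(4, 3))
        ens = combine_trajectories(
            [_traj([base] * 3), _traj([base] * 3, model="VARIANT")]
        )
        ens = align_ensemble(ens)
        cl = hierarchical_clusters(np.zeros((6, 4)) + rng.normal(size=(6, 4)) * 1e-9, n_clusters=1)
        prof = cluster_profile(ens, cl)
        assert prof["rmsd_to_midpoint_mean"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert prof["rmsd_to_midpoint_sd"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_occupancy_counts_conserved(self, small_ensemble):
        ens, pca, _, _ = small_ensemble
        cl = hierarchical_clusters(pca.projections, n_clusters=3)
        prof = cluster_profile(ens, cl)
        assert prof["n_frames"].sum() == ens.n_frames
        assert (prof["n_WT"] + prof["n_VARIANT"]).sum() == ens.n_frames

    def test_extended_cluster_has_larger_rg(self, small_ensemble):
        ens, pca, states, _ = small_ensemble
        cl = hierarchical_clusters(pca.projections, n_clusters=3)
        prof = cluster_profile(ens, cl).set_index("cluster")
        states = np.array(states)
        rg_by_state = {}
        for cid in range(1, 4):
            members = states[cl.assignment == cid]
            top = pd.Series(members).mode()[0]
            rg_by_state[top] = prof.loc[cid, "rg_mean"]
        assert rg_by_state["J"] > rg_by_state["O"]

    def test_all_frames_in_reference_cluster(self, rng):
        base = rng.normal(size=(4, 3))
        ens = combine_trajectories(
            [_traj([base] * 5), _traj([base] * 5, model="VARIANT")]
        )
        ens = align_ensemble(ens)
        cl = hierarchical_clusters(rng.normal(size=(10, 4)) * 1e-9, n_clusters=1)
        occ, half = occupancy_timecourse(ens, cl, reference_cluster=1, n_bins=5)
        assert np.nanmax(occ["fraction_departed"]) == 0.0
        assert all(v is None for v in half.values())

    def test_departed_fraction_complements_reference(self, small_ensemble):
        ens, pca, _, _ = small_ensemble
        cl = hierarchical_clusters(pca.projections, n_clusters=3)
        ref = int(cl.assignment[0])
        occ, _ = occupancy_timecourse(ens, cl, ref, n_bins=6)
        # for each (model, bin): departed + stayed = 1
        times = ens.provenance["time_label"].to_numpy()
        edges = np.linspace(times.min(), times.max(), 7)
        edges[-1] = np.nextafter(edges[-1], np.inf)
        for _, row in occ.dropna().iterrows():
            sel = (
                (ens.provenance["model_label"] == row["model_label"]).to_numpy()
                & (times >= edges[int(row["bin"]) - 1])
                & (times < edges[int(row["bin"])])
            )
            stayed = np.mean(cl.assignment[sel] == ref)
            assert stayed + row["fraction_departed"] == pytest.approx(1.0)
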