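"""Combined-ensemble analysis: alignment, coordinate PCA, conformational clustering.

All labelled trajectories (wild type and variant, both starting shapes,
every repeat) are concatenated into one collection so that a single PCA
basis describes every simulation; frames are then clustered in the leading
principal-component space with average-linkage agglomeration, and each
cluster is characterised by its midpoint frame, within-cluster RMSD,
radius of gyration and per-model occupancy over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .geometry import kabsch_superpose, radius_of_gyration, rmsd
from .structure_io import AtomRecord, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleCollection",
    "PcaModel",
    "EnsembleClustering",
    "combine_trajectories",
    "align_ensemble",
    "coordinate_pca",
    "select_k_elbow",
    "hierarchical_clusters",
    "cluster_midpoints",
    "cluster_profile",
    "occupancy_timecourse",
    "ca_mask",
]


@dataclass
class EnsembleCollection:
    """Frames from several trajectories sharing one topology.

    ``provenance`` has one row per frame with columns
    (model_label, start_shape, repeat_id, time_label).
    """

    topology: list[AtomRecord]
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    provenance: pd.DataFrame
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.provenance):
            raise ValueError("provenance length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class PcaModel:
    """Coordinate PCA of the aligned ensemble over a masked atom set."""

    mean_coordinates: np.ndarray  # (n_masked * 3,)
    components: np.ndarray  # (n_components, n_masked * 3), orthonormal rows
    eigenvalues: np.ndarray  # variances (A^2), non-increasing
    projections: np.ndarray  # (n_frames, n_components)
    atom_mask: np.ndarray


@dataclass
class EnsembleClustering:
    """Hard partition of frames into conformational clusters (ids 1..k)."""

    n_clusters: int
    assignment: np.ndarray  # per-frame id in 1..n_clusters
    midpoint_frame: dict[int, int]
    linkage_method: str
    n_pcs_used: int


def ca_mask(topology: list[AtomRecord]) -> np.ndarray:
    """0-based indices of backbone "CA" beads/atoms (default PCA mask)."""
    idx = np.array([i for i, a in enumerate(topology) if a.atom_name == "CA"], dtype=int)
    if idx.size == 0:
        raise ValueError("topology has no CA atoms")
    return idx


def combine_trajectories(trajs: list[Trajectory]) -> EnsembleCollection:
    """Concatenate labelled trajectories over a shared topology."""
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories to combine")
    ref = trajs[0].topology
    for t in trajs[1:]:
        if len(t.topology) != len(ref):
            raise ValueError(
                f"topology size mismatch: {len(t.topology)} vs {len(ref)}"
            )
        for i, (a, b) in enumerate(zip(ref, t.topology)):
            if (a.atom_name, a.residue_index) != (b.atom_name, b.residue_index):
                raise ValueError(
                    f"topology mismatch at atom {i}: "
                    f"{a.atom_name}/res{a.residue_index} vs "
                    f"{b.atom_name}/res{b.residue_index}"
                )
    coords = np.concatenate([t.coordinate_array() for t in trajs], axis=0)
    rows = []
    for t in trajs:
        for fr in t.frames:
            rows.append(
                {
                    "model_label": t.model_label,
                    "start_shape": t.start_shape,
                    "repeat_id": t.repeat_id,
                    "time_label": fr.time_label,
                }
            )
    return EnsembleCollection(
        topology=list(ref),
        coordinates=coords,
        provenance=pd.DataFrame(rows),
        aligned=False,
    )


def align_ensemble(
    ens: EnsembleCollection, atom_mask: np.ndarray | None = None
) -> EnsembleCollection:
    """Two-pass mean-structure fit.

    Pass 1 superposes every frame onto frame 1; pass 2 recomputes the mean
    structure and superposes every frame onto it.  Deterministic, and
    idempotent to numerical precision.
    """
    coords = ens.coordinates.copy()
    n = coords.shape[0]

    def fit_all(reference: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for i in range(n):
            sup = kabsch_superpose(coords[i], reference, atom_mask)
            out[i] = sup.apply(coords[i])
        return out

    coords = fit_all(coords[0])
    mean_structure = coords.mean(axis=0)
    coords = fit_all(mean_structure)
    return EnsembleCollection(
        topology=ens.topology,
        coordinates=coords,
        provenance=ens.provenance.copy(),
        aligned=True,
    )


def coordinate_pca(
    ens: EnsembleCollection, atom_mask: np.ndarray | None = None
) -> PcaModel:
    """PCA of flattened masked coordinates of an aligned ensemble.

    Components are the eigenvectors of the coordinate covariance matrix,
    sorted by decreasing eigenvalue; projections are per-frame scores.
    """
    if not ens.aligned:
        raise ValueError("ensemble must be aligned first (see align_ensemble)")
    if ens.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    if atom_mask is None:
        atom_mask = np.arange(ens.n_atoms)
    atom_mask = np.asarray(sorted(atom_mask), dtype=int)
    X = ens.coordinates[:, atom_mask, :].reshape(ens.n_frames, -1)
    n_components = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    projections = pca.fit_transform(X)
    return PcaModel(
        mean_coordinates=pca.mean_,
        components=pca.components_,
        eigenvalues=pca.explained_variance_,
        projections=projections,
        atom_mask=atom_mask,
    )


def select_k_elbow(
    projections: np.ndarray,
    n_pcs: int = 4,
    k_range: range | None = None,
    seed: int = 1,
) -> int:
    """Pick the cluster count at the elbow of the k-means inertia curve.

    Runs k-means (10 restarts, fixed seed) for each k and returns the k
    maximising the second difference of log within-cluster sum of squares
    (log curvature is scale-invariant, so a huge first drop does not mask
    a later elbow).  A flat curve (no pronounced elbow) is logged as
    low-confidence.
    """
    if k_range is None:
        k_range = range(1, min(9, projections.shape[0] + 1))
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    X = np.asarray(projections)[:, :n_pcs]
    wcss = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X)
        wcss.append(max(km.inertia_, 1e-12))
    if len(ks) < 3:
        return ks[int(np.argmin(wcss))]
    log_wcss = np.log(wcss)
    second_diff = [
        log_wcss[i - 1] - 2 * log_wcss[i] + log_wcss[i + 1]
        for i in range(1, len(ks) - 1)
    ]
    best = int(np.argmax(second_diff))
    if second_diff[best] < 0.25:
        logger.warning(
            "elbow selection is low-confidence: inertia curve has no pronounced bend"
        )
    return ks[best + 1]


def hierarchical_clusters(
    projections: np.ndarray, n_pcs: int = 4, n_clusters: int = 6
) -> EnsembleClustering:
    """Average-linkage agglomeration in the leading principal components.

    Euclidean distances over the first ``n_pcs`` scores; the tree is cut
    to exactly ``n_clusters`` groups and ids are relabelled so cluster 1
    is the one containing the first frame, cluster 2 the next new cluster
    encountered in frame order, and so on.
    """
    X = np.asarray(projections)
    if n_pcs > X.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds available components {X.shape[1]}")
    if n_clusters > X.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds frame count {X.shape[0]}")
    X = X[:, :n_pcs]
    Z = linkage(X, method="average", metric="euclidean")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel by first occurrence
    mapping: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    clustering = EnsembleClustering(
        n_clusters=int(labels.max()),
        assignment=labels,
        midpoint_frame={},
        linkage_method="average",
        n_pcs_used=n_pcs,
    )
    clustering.midpoint_frame = cluster_midpoints(clustering, X)
    return clustering


def cluster_midpoints(
    clustering: EnsembleClustering, projections: np.ndarray
) -> dict[int, int]:
    """Representative frame per cluster: member closest to the PC centroid.

    Ties are broken by the lowest frame index.
    """
    X = np.asarray(projections)[:, : clustering.n_pcs_used]
    midpoints: dict[int, int] = {}
    for cid in range(1, clustering.n_clusters + 1):
        members = np.flatnonzero(clustering.assignment == cid)
        centroid = X[members].mean(axis=0)
        d = np.linalg.norm(X[members] - centroid, axis=1)
        midpoints[cid] = int(members[int(np.argmin(d))])
    return midpoints


def cluster_profile(
    ens: EnsembleCollection, clustering: EnsembleClustering
) -> pd.DataFrame:
    """Per-cluster structural summary.

    Columns: cluster, n_frames, mean/sd RMSD to the cluster midpoint
    (after superposition), mean/sd radius of gyration, and one occupancy
    column per model label.
    """
    rows = []
    model_labels = sorted(ens.provenance["model_label"].unique())
    for cid in range(1, clustering.n_clusters + 1):
        members = np.flatnonzero(clustering.assignment == cid)
        mid = clustering.midpoint_frame[cid]
        rmsds = np.array(
            [rmsd(ens.coordinates[i], ens.coordinates[mid], align=True) for i in members]
        )
        rgs = np.array([radius_of_gyration(ens.coordinates[i]) for i in members])
        row = {
            "cluster": cid,
            "n_frames": len(members),
            "rmsd_to_midpoint_mean": float(rmsds.mean()),
            "rmsd_to_midpoint_sd": float(rmsds.std(ddof=0)),
            "rg_mean": float(rgs.mean()),
            "rg_sd": float(rgs.std(ddof=0)),
        }
        for m in model_labels:
            row[f"n_{m}"] = int(
                np.sum(ens.provenance["model_label"].to_numpy()[members] == m)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def occupancy_timecourse(
    ens: EnsembleCollection,
    clustering: EnsembleClustering,
    reference_cluster: int,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Departure from a reference cluster over simulation time, per model.

    Returns a table with one row per (model, time bin) giving the fraction
    of that model's frames outside ``reference_cluster``, plus the
    half-departure time per model: the midpoint of the first bin where the
    departed fraction reaches 0.5 (``None`` when never reached).
    """
    prov = ens.provenance
    times = prov["time_label"].to_numpy(dtype=float)
    edges = np.linspace(times.min(), times.max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    rows = []
    half_departure: dict[str, float | None] = {}
    for model in sorted(prov["model_label"].unique()):
        sel = prov["model_label"].to_numpy() == model
        if not np.any(clustering.assignment[sel] == reference_cluster):
            logger.warning(
                "reference cluster %d is empty for model %s", reference_cluster, model
            )
        half_departure[model] = None
        for b in range(n_bins):
            in_bin = sel & (times >= edges[b]) & (times < edges[b + 1])
            n_in = int(in_bin.sum())
            if n_in == 0:
                frac = np.nan
            else:
                frac = float(
                    np.mean(clustering.assignment[in_bin] != reference_cluster)
                )
            midpoint = 0.5 * (edges[b] + min(edges[b + 1], times.max()))
            rows.append(
                {
                    "model_label": model,
                    "bin": b + 1,
                    "time_mid": midpoint,
                    "n_frames": n_in,
                    "fraction_departed": frac,
                }
            )
            if half_departure[model] is None and n_in > 0 and frac >= 0.5:
                half_departure[model] = midpoint
    return pd.DataFrame(rows), half_departure
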