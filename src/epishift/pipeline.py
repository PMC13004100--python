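"""End-to-end orchestration: read -> align -> PCA -> cluster -> profile ->
exposure -> antigenicity -> report.

Every run is deterministic given the config and seed; the manifest records
all parameters that affect outputs plus input checksums, so two runs with
the same manifest produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .antigenicity import (
    SURROGATE_TAG,
    average_antigenicity,
    sample_cluster_frames,
    surrogate_antigenicity,
)
from .ensemble import (
    align_ensemble,
    ca_mask,
    cluster_profile,
    combine_trajectories,
    coordinate_pca,
    hierarchical_clusters,
    occupancy_timecourse,
)
from .exposure import build_exposure_table, exposure_delta
from .structure_io import (
    default_region_config_path,
    load_region_config,
    read_multi_model_pdb,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_ensemble_pipeline"]


class PipelineStageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """All knobs of one ensemble-analysis run."""

    trajectory_paths: list[Path]
    output_dir: Path
    region_config: Path | None = None  # None -> packaged defaults
    n_pcs: int = 4
    n_clusters: int = 6
    reference_model: str = "WT"
    reference_cluster: int | None = None  # None -> cluster of the first frame
    probe_radius: float = 1.4
    sasa_points: int = 960
    sampling_n: int = 100
    occupancy_bins: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        self.trajectory_paths = [Path(p) for p in self.trajectory_paths]
        self.output_dir = Path(self.output_dir)
        if self.region_config is not None:
            self.region_config = Path(self.region_config)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as handle:
        handle.write(f"# epishift {__version__} seed={seed}\n")
        df.to_csv(handle, sep="\t", index=False, float_format="%.6g")


def run_ensemble_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full conformational-ensemble analysis and write TSV outputs.

    Returns a mapping from output name to file path.  Any stage failure is
    re-raised as :class:`PipelineStageError` naming the stage, and no
    partial outputs are left behind.
    """
    region_path = (
        config.region_config
        if config.region_config is not None
        else default_region_config_path()
    )
    missing = [
        str(p) for p in [*config.trajectory_paths, region_path] if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    outputs: dict[str, pd.DataFrame] = {}
    t0 = time.time()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        stage("read")
        trajs = [read_multi_model_pdb(p) for p in config.trajectory_paths]
        motifs = load_region_config(region_path)
    except Exception as exc:
        raise PipelineStageError("read", exc) from exc

    try:
        stage("combine+align")
        ens = combine_trajectories(trajs)
        mask = ca_mask(ens.topology)
        ens = align_ensemble(ens, mask)
    except Exception as exc:
        raise PipelineStageError("align", exc) from exc

    try:
        stage("pca+cluster")
        pca = coordinate_pca(ens, mask)
        clustering = hierarchical_clusters(
            pca.projections, n_pcs=config.n_pcs, n_clusters=config.n_clusters
        )
        proj_df = ens.provenance.copy()
        for j in range(config.n_pcs):
            proj_df[f"PC{j+1}"] = pca.projections[:, j]
        proj_df["cluster"] = clustering.assignment
        outputs["projections"] = proj_df
    except Exception as exc:
        raise PipelineStageError("pca+cluster", exc) from exc

    try:
        stage("profile")
        outputs["cluster_profile"] = cluster_profile(ens, clustering)
        reference_cluster = (
            config.reference_cluster
            if config.reference_cluster is not None
            else int(clustering.assignment[0])
        )
        occ_df, half_dep = occupancy_timecourse(
            ens, clustering, reference_cluster, n_bins=config.occupancy_bins
        )
        occ_df["reference_cluster"] = reference_cluster
        outputs["occupancy"] = occ_df
        outputs["half_departure"] = pd.DataFrame(
            [
                {"model_label": m, "half_departure_time": t}
                for m, t in half_dep.items()
            ]
        )
    except Exception as exc:
        raise PipelineStageError("profile", exc) from exc

    try:
        stage("exposure")
        table = build_exposure_table(
            ens, clustering, config.probe_radius, config.sasa_points
        )
        outputs["exposure"] = table.data
        outputs["exposure_deltas"] = _all_motif_deltas(
            table, motifs, clustering, reference_cluster, config.reference_model
        )
    except Exception as exc:
        raise PipelineStageError("exposure", exc) from exc

    try:
        stage("antigenicity")
        scores: dict[int, dict[int, float]] = {}
        models = sorted(ens.provenance["model_label"].unique())
        for model in models:
            for cid in range(1, clustering.n_clusters + 1):
                members = np.flatnonzero(
                    (ens.provenance["model_label"].to_numpy() == model)
                    & (clustering.assignment == cid)
                )
                if members.size == 0:
                    continue
                sampled = sample_cluster_frames(
                    ens, clustering, cid, model, n=config.sampling_n, seed=config.seed
                )
                for i in sampled:
                    if i not in scores:
                        scores[int(i)] = surrogate_antigenicity(
                            ens.coordinates[i],
                            ens.topology,
                            config.probe_radius,
                            config.sasa_points,
                        )
        anti_table = average_antigenicity(scores, ens, clustering, SURROGATE_TAG)
        outputs["antigenicity"] = anti_table.data
        outputs["antigenicity_deltas"] = _all_motif_deltas(
            anti_table, motifs, clustering, reference_cluster, config.reference_model
        )
    except Exception as exc:
        raise PipelineStageError("antigenicity", exc) from exc

    stage("write")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in outputs.items():
        path = config.output_dir / f"{name}.tsv"
        _write_tsv(df, path, config.seed)
        written[name] = path

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "parameters": {
            "n_pcs": config.n_pcs,
            "n_clusters": config.n_clusters,
            "reference_model": config.reference_model,
            "reference_cluster": reference_cluster,
            "probe_radius": config.probe_radius,
            "sasa_points": config.sasa_points,
            "sampling_n": config.sampling_n,
            "occupancy_bins": config.occupancy_bins,
            "seed": config.seed,
            "scorer_tag": SURROGATE_TAG,
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [*config.trajectory_paths, region_path]
        },
        "outputs": {name: str(path) for name, path in written.items()},
    }
    manifest_path = config.output_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path
    return written


def _all_motif_deltas(table, motifs, clustering, reference_cluster, reference_model):
    """Delta table: every motif vs the reference cluster and reference model."""
    models = sorted(table.data["model_label"].unique())
    clusters = sorted(table.data["cluster"].unique())
    rows = []
    for motif in motifs:
        present = set(table.data["residue"])
        if not set(motif.residue_indices) <= present:
            logger.info("motif %s skipped: residues not in topology", motif.name)
            continue
        for model in models:
            for cid in clusters:
                if not (
                    (table.data["model_label"] == model) & (table.data["cluster"] == cid)
                ).any():
                    continue
                if cid != reference_cluster:
                    try:
                        d = exposure_delta(
                            table, motif, "vs_reference_cluster", model, cid,
                            reference_cluster=reference_cluster,
                        )
                        rows.append(_delta_row(d))
                    except KeyError:
                        pass
                if model != reference_model:
                    try:
                        d = exposure_delta(
                            table, motif, "vs_reference_model", model, cid,
                            reference_model=reference_model,
                        )
                        rows.append(_delta_row(d))
                    except KeyError:
                        pass
    return pd.DataFrame(
        rows,
        columns=[
            "motif",
            "comparison",
            "model_label",
            "cluster",
            "reference",
            "absolute_change",
            "percent_change",
        ],
    )


def _delta_row(d) -> dict:
    return {
        "motif": d.motif_name,
        "comparison": d.comparison,
        "model_label": d.model_label,
        "cluster": d.cluster_id,
        "reference": d.reference_label,
        "absolute_change": d.absolute_change,
        "percent_change": d.percent_change if d.percent_change is not None else float("nan"),
    }
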