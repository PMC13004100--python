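"""Per-residue SASA aggregation by (model, cluster) and motif exposure deltas.

The central quantity is the mean solvent-accessible surface area of each
residue within one conformational cluster of one model.  Motif-level
exposure is the sum of member-residue means (the loop is treated as a
unit), and deltas are reported both against a reference cluster of the
same model (e.g. extended shapes vs the circular O-Shape) and against the
same cluster of a reference model (variant vs wild type).  Negative
percent change means the motif became more buried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleClustering, EnsembleCollection
from .geometry import shrake_rupley_sasa
from .structure_io import MotifDefinition

__all__ = [
    "ExposureTable",
    "ExposureDelta",
    "build_exposure_table",
    "motif_exposure",
    "exposure_delta",
]


@dataclass
class ExposureTable:
    """Mean/sd per-residue SASA per (model_label, cluster_id) stratum."""

    data: pd.DataFrame  # columns: model_label, cluster, residue, mean, sd, n_frames
    probe_radius: float
    n_sphere_points: int
    value_name: str = "sasa"  # "sasa" or a score tag (antigenicity reuses this table)

    def stratum(self, model: str, cluster: int) -> pd.DataFrame:
        sel = (self.data["model_label"] == model) & (self.data["cluster"] == cluster)
        sub = self.data[sel]
        if sub.empty:
            raise KeyError(f"no entries for model={model!r}, cluster={cluster}")
        return sub

    def residue_mean(self, model: str, cluster: int, residue: int) -> float:
        sub = self.stratum(model, cluster)
        row = sub[sub["residue"] == residue]
        if row.empty:
            raise KeyError(f"residue {residue} absent from stratum ({model}, {cluster})")
        return float(row["mean"].iloc[0])


@dataclass(frozen=True)
class ExposureDelta:
    """Motif-level change against a reference stratum.

    ``percent_change`` is 100 * absolute_change / reference mean and is
    ``None`` when the reference mean is zero (flagged undefined).
    """

    motif_name: str
    comparison: str  # "vs_reference_cluster" | "vs_reference_model"
    model_label: str
    cluster_id: int
    reference_label: str
    absolute_change: float
    percent_change: float | None


def build_exposure_table(
    ens: EnsembleCollection,
    clustering: EnsembleClustering,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> ExposureTable:
    """Compute per-frame per-residue SASA and average within each stratum."""
    prov = ens.provenance
    residues = sorted({a.residue_index for a in ens.topology})
    per_frame = np.empty((ens.n_frames, len(residues)))
    res_pos = {r: j for j, r in enumerate(residues)}
    for i in range(ens.n_frames):
        sasa = shrake_rupley_sasa(
            ens.coordinates[i], ens.topology, probe_radius, n_sphere_points
        )
        for r, area in sasa.per_residue_area.items():
            per_frame[i, res_pos[r]] = area

    rows = []
    models = prov["model_label"].to_numpy()
    for model in sorted(set(models)):
        for cid in range(1, clustering.n_clusters + 1):
            sel = (models == model) & (clustering.assignment == cid)
            n = int(sel.sum())
            if n == 0:
                continue
            block = per_frame[sel]
            means = block.mean(axis=0)
            sds = block.std(axis=0, ddof=0)
            for j, r in enumerate(residues):
                rows.append(
                    {
                        "model_label": model,
                        "cluster": cid,
                        "residue": r,
                        "mean": float(means[j]),
                        "sd": float(sds[j]),
                        "n_frames": n,
                    }
                )
    return ExposureTable(
        data=pd.DataFrame(rows),
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


def motif_exposure(
    table: ExposureTable, motif: MotifDefinition, model: str, cluster: int
) -> float:
    """Motif-level mean SASA: sum of member-residue means within the stratum."""
    sub = table.stratum(model, cluster)
    present = set(sub["residue"])
    missing = sorted(set(motif.residue_indices) - present)
    if missing:
        raise KeyError(
            f"motif {motif.name!r}: residues {missing} missing from stratum "
            f"({model}, {cluster})"
        )
    sel = sub["residue"].isin(motif.residue_indices)
    return float(sub.loc[sel, "mean"].sum())


def exposure_delta(
    table: ExposureTable,
    motif: MotifDefinition,
    mode: str,
    model: str,
    cluster: int,
    reference_cluster: int | None = None,
    reference_model: str | None = None,
) -> ExposureDelta:
    """Motif exposure change against a reference cluster or reference model.

    mode="vs_reference_cluster": (model, cluster) vs (model, reference_cluster).
    mode="vs_reference_model": (model, cluster) vs (reference_model, cluster).
    """
    target = motif_exposure(table, motif, model, cluster)
    if mode == "vs_reference_cluster":
        if reference_cluster is None:
            raise ValueError("reference_cluster required for vs_reference_cluster")
        reference = motif_exposure(table, motif, model, reference_cluster)
        ref_label = f"cluster {reference_cluster}"
    elif mode == "vs_reference_model":
        if reference_model is None:
            raise ValueError("reference_model required for vs_reference_model")
        reference = motif_exposure(table, motif, reference_model, cluster)
        ref_label = f"model {reference_model}"
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")

    absolute = target - reference
    percent = 100.0 * absolute / reference if reference > 0 else None
    return ExposureDelta(
        motif_name=motif.name,
        comparison=mode,
        model_label=model,
        cluster_id=cluster,
        reference_label=ref_label,
        absolute_change=float(absolute),
        percent_change=percent,
    )
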