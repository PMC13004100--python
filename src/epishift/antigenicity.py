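"""Cluster-sampled residue antigenicity: external score import or SASA surrogate.

A structure-based epitope predictor scores each residue of a conformation;
averaging those scores over frames sampled from a conformational cluster
gives a cluster-level antigenicity profile, and motif deltas follow the
same arithmetic as SASA exposure deltas.

The external predictor itself (a trained neural model behind a web
service) is never called here.  Scores are either imported from CSV files
exported from such a service, or replaced by a transparent surrogate —
the residue's relative solvent exposure (SASA divided by its
isolated-sphere maximum), a number in [0, 1].  The surrogate is NOT the
external predictor; outputs carry a ``scorer_tag`` so the provenance of
every table is explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleClustering, EnsembleCollection
from .exposure import ExposureTable
from .geometry import max_residue_accessibility, shrake_rupley_sasa
from .structure_io import AtomRecord

logger = logging.getLogger(__name__)

__all__ = [
    "sample_cluster_frames",
    "surrogate_antigenicity",
    "import_external_scores",
    "average_antigenicity",
    "SURROGATE_TAG",
]

SURROGATE_TAG = "relative-exposure-surrogate"


def sample_cluster_frames(
    ens: EnsembleCollection,
    clustering: EnsembleClustering,
    cluster: int,
    model: str,
    n: int = 100,
    seed: int = 1,
) -> np.ndarray:
    """Uniformly sample frame indices (without replacement) from one stratum.

    If the stratum holds no more than ``n`` frames, all of them are
    returned (logged as a note).
    """
    models = ens.provenance["model_label"].to_numpy()
    members = np.flatnonzero((models == model) & (clustering.assignment == cluster))
    if members.size == 0:
        raise ValueError(f"stratum (model={model!r}, cluster={cluster}) is empty")
    if members.size <= n:
        if members.size < n:
            logger.info(
                "stratum (%s, %d) has only %d frames (< %d): using all",
                model,
                cluster,
                members.size,
                n,
            )
        return members.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(members, size=n, replace=False))


def surrogate_antigenicity(
    frame: np.ndarray,
    topology: Sequence[AtomRecord],
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[int, float]:
    """Relative-exposure score per residue: SASA / isolated-sphere maximum.

    Fully buried residues score 0; an isolated residue scores 1 (up to the
    lattice tolerance of the SASA estimate).  Monotone in residue SASA by
    construction.  A stand-in for an external epitope predictor, not a
    reimplementation of one.
    """
    sasa = shrake_rupley_sasa(frame, topology, probe_radius, n_sphere_points)
    max_acc = max_residue_accessibility(topology, probe_radius)
    return {
        r: area / max_acc[r] for r, area in sasa.per_residue_area.items()
    }


def import_external_scores(
    paths: Sequence[str | Path],
    topology: Sequence[AtomRecord],
    residue_column: str = "residue_index",
    score_column: str = "score",
) -> list[dict[int, float]]:
    """Load per-residue scores exported by an external predictor, one CSV per frame.

    Rows are validated against the topology residue range; residues absent
    from a file are simply absent from that frame's mapping (never imputed
    as zero).  Column names are configurable to absorb export dialects.
    """
    valid = {a.residue_index for a in topology}
    out: list[dict[int, float]] = []
    for path in paths:
        df = pd.read_csv(path)
        if residue_column not in df.columns or score_column not in df.columns:
            raise ValueError(
                f"{path}: expected columns {residue_column!r} and {score_column!r}, "
                f"got {list(df.columns)}"
            )
        residues = df[residue_column].astype(int)
        dup = residues[residues.duplicated()].tolist()
        if dup:
            raise ValueError(f"{path}: duplicate residue entries {sorted(set(dup))}")
        bad = sorted(set(residues) - valid)
        if bad:
            raise ValueError(f"{path}: residues {bad} are outside the topology")
        out.append(dict(zip(residues, df[score_column].astype(float))))
    return out


def average_antigenicity(
    scores: Mapping[int, Mapping[int, float]] | Sequence[tuple[int, Mapping[int, float]]],
    ens: EnsembleCollection,
    clustering: EnsembleClustering,
    scorer_tag: str,
) -> ExposureTable:
    """Average per-frame residue scores within each (model, cluster) stratum.

    ``scores`` maps frame index -> {residue -> score} for every scored
    frame.  Returns a table with the same layout as the SASA exposure
    table, so motif means and deltas reuse the exposure-delta arithmetic;
    ``value_name`` records the scorer tag.
    """
    if not scorer_tag:
        raise ValueError("scorer_tag must be non-empty")
    items = dict(scores)
    if not items:
        raise ValueError("no scored frames supplied")
    models = ens.provenance["model_label"].to_numpy()
    rows = []
    for model in sorted(set(models)):
        for cid in range(1, clustering.n_clusters + 1):
            members = np.flatnonzero((models == model) & (clustering.assignment == cid))
            frame_scores = [items[i] for i in members if i in items]
            if not frame_scores:
                continue
            residues = sorted(set().union(*[set(s) for s in frame_scores]))
            for r in residues:
                vals = np.array([s[r] for s in frame_scores if r in s])
                rows.append(
                    {
                        "model_label": model,
                        "cluster": cid,
                        "residue": r,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=0)),
                        "n_frames": int(vals.size),
                    }
                )
    if not rows:
        raise ValueError("no stratum had any scored frame")
    return ExposureTable(
        data=pd.DataFrame(rows),
        probe_radius=float("nan"),
        n_sphere_points=0,
        value_name=scorer_tag,
    )
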