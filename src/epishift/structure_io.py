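"""Multi-model structure I/O and region/motif definitions.

Containers for coarse or all-atom trajectories stored as multi-model PDB
files (one ``MODEL``/``ENDMDL`` block per frame), plus the TSV region
config that names the phospholipid-binding loops and epitope motifs.

Residue numbering convention
----------------------------
Residue indices are 1-based and *include* the signal peptide, so the
Domain V tryptophan of beta2-glycoprotein I is residue 335 (some studies
that exclude the signal peptide call the same residue W316).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "MotifDefinition",
    "PdbFormatError",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "load_region_config",
    "default_region_config_path",
]

#: Bondi-style van der Waals radii in Angstrom, keyed by element symbol.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS = 1.70


class PdbFormatError(ValueError):
    """Raised for malformed or internally inconsistent PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology.

    ``vdw_radius`` is carried explicitly so coarse-grained bead models can
    use radii that differ from the element table.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


@dataclass
class Frame:
    """Coordinates (Angstrom) for every topology atom at one time point."""

    coordinates: np.ndarray  # (n_atoms, 3)
    time_label: float = 0.0  # ns, or frame ordinal

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class Trajectory:
    """Ordered frames over one topology, with simulation provenance labels."""

    topology: list[AtomRecord]
    frames: list[Frame]
    model_label: str = "WT"
    start_shape: str = "circular"
    repeat_id: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory requires at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {fr.coordinates.shape[0]} atoms, topology has {n}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def residue_indices(self) -> list[int]:
        """Sorted unique residue indices present in the topology."""
        return sorted({a.residue_index for a in self.topology})

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class MotifDefinition:
    """A named residue set (phospholipid-binding loop or epitope motif)."""

    name: str
    residue_indices: frozenset[int]
    domain_tag: str = ""

    def __post_init__(self) -> None:
        if not self.residue_indices:
            raise ValueError(f"motif {self.name!r} has no residues")


def _infer_element(atom_name: str) -> str:
    """First alphabetic character of the atom name, uppercased.

    PDB convention left-justifies one-letter elements into column 14, so
    for cleaned/synthetic files (no metals) this is unambiguous: "CA" and
    "CB" are carbons, "OD1" oxygen, "1HB" hydrogen.
    """
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def vdw_radius_for_element(element: str) -> float:
    radius = VDW_RADII.get(element.upper())
    if radius is None:
        warnings.warn(
            f"unknown element {element!r}: using default vdW radius "
            f"{DEFAULT_VDW_RADIUS} A",
            stacklevel=2,
        )
        return DEFAULT_VDW_RADIUS
    return radius


def _parse_atom_line(line: str, line_no: int) -> tuple[AtomRecord, np.ndarray, float]:
    """Parse one fixed-width ATOM/HETATM record.

    Returns the atom record, its coordinates and the B-factor field (used
    by this package to persist per-atom vdW radii through round trips).
    """
    try:
        atom_index = int(line[6:11])
        atom_name = line[12:16].strip()
        altloc = line[16:17].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        residue_index = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        bfac_text = line[60:66].strip()
        bfactor = float(bfac_text) if bfac_text else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"unparseable ATOM record at line {line_no}: {exc}") from exc
    if icode:
        raise PdbFormatError(
            f"insertion code {icode!r} at line {line_no}: insertion codes are "
            "not supported (synthetic/cleaned structures only)"
        )
    if not element:
        element = _infer_element(atom_name)
    radius = bfactor if bfactor > 0 else vdw_radius_for_element(element)
    record = AtomRecord(
        atom_index=atom_index,
        atom_name=atom_name,
        element=element,
        residue_index=residue_index,
        residue_name=residue_name,
        chain_id=chain_id,
        vdw_radius=radius,
    )
    return record, np.array([x, y, z]), altloc


def read_multi_model_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Every ``MODEL``/``ENDMDL`` block becomes one frame; a file without
    MODEL records is read as a single frame.  Atom order must be identical
    across models.  Only the first altLoc of each atom is kept.  Custom
    ``REMARK 250`` lines written by :func:`write_multi_model_pdb` restore
    the model/start-shape/repeat provenance; B-factors > 0 restore per-atom
    vdW radii.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta = {"model_label": "WT", "start_shape": "circular", "repeat_id": 0}
    topology: list[AtomRecord] = []
    frames: list[Frame] = []
    current: list[np.ndarray] = []
    current_atoms: list[AtomRecord] = []
    seen_altloc: set[tuple[int, str]] = set()
    model_count = 0
    in_model = False
    model_time: float | None = None

    def close_model(label: int) -> None:
        nonlocal topology
        if not current_atoms:
            raise PdbFormatError(f"model {label} contains no atoms")
        if not topology:
            topology.extend(current_atoms)
        else:
            if len(current_atoms) != len(topology):
                raise PdbFormatError(
                    f"model {label} has {len(current_atoms)} atoms but model 1 "
                    f"has {len(topology)}"
                )
            for ref, got in zip(topology, current_atoms):
                if (ref.atom_name, ref.residue_index) != (
                    got.atom_name,
                    got.residue_index,
                ):
                    raise PdbFormatError(
                        f"model {label}: atom {got.atom_index} "
                        f"({got.atom_name}/res {got.residue_index}) does not match "
                        f"model 1 ({ref.atom_name}/res {ref.residue_index})"
                    )
        time_label = model_time if model_time is not None else float(len(frames))
        frames.append(Frame(np.array(current), time_label=time_label))

    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            rec = line[:6].strip()
            if rec == "REMARK" and line[7:10] == "250":
                payload = line[10:].strip()
                if payload.startswith("EPISHIFT"):
                    _, key, value = payload.split(None, 2)
                    if key == "MODEL_LABEL":
                        meta["model_label"] = value
                    elif key == "START_SHAPE":
                        meta["start_shape"] = value
                    elif key == "REPEAT_ID":
                        meta["repeat_id"] = int(value)
                    elif key == "TIME_NS":
                        model_time = float(value)
            elif rec == "MODEL":
                in_model = True
                model_count += 1
                current = []
                current_atoms = []
                seen_altloc = set()
            elif rec == "ENDMDL":
                close_model(model_count)
                in_model = False
                model_time = None
            elif rec in ("ATOM", "HETATM"):
                record, xyz, altloc = _parse_atom_line(line, line_no)
                if altloc:
                    key = (record.atom_index, record.atom_name)
                    if key in seen_altloc:
                        continue  # keep first altLoc only
                    seen_altloc.add(key)
                current_atoms.append(record)
                current.append(xyz)

    if in_model:
        raise PdbFormatError(f"model {model_count} not terminated by ENDMDL")
    if model_count == 0:
        # single implicit model
        if not current_atoms:
            raise PdbFormatError(f"{path} contains no ATOM records")
        close_model(1)

    traj = Trajectory(
        topology=topology,
        frames=frames,
        model_label=str(meta["model_label"]),
        start_shape=str(meta["start_shape"]),
        repeat_id=int(meta["repeat_id"]),
    )
    return traj


def write_multi_model_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a :class:`Trajectory` as a multi-model PDB file.

    Coordinates are fixed-width %8.3f, so round trips are exact to 0.001 A.
    Per-atom vdW radii are stored in the B-factor column; provenance labels
    go into ``REMARK 250 EPISHIFT`` lines so a read-back reconstructs the
    trajectory metadata.
    """
    if not isinstance(traj, Trajectory):
        raise TypeError("expected a Trajectory")
    path = Path(path)
    lines: list[str] = [
        f"REMARK 250 EPISHIFT MODEL_LABEL {traj.model_label}",
        f"REMARK 250 EPISHIFT START_SHAPE {traj.start_shape}",
        f"REMARK 250 EPISHIFT REPEAT_ID {traj.repeat_id}",
    ]
    for i_frame, frame in enumerate(traj.frames, start=1):
        lines.append(f"REMARK 250 EPISHIFT TIME_NS {frame.time_label:.6f}")
        lines.append(f"MODEL     {i_frame:4d}")
        for atom, xyz in zip(traj.topology, frame.coordinates):
            name = atom.atom_name
            # PDB atom-name justification: 1-letter elements start in col 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {atom.atom_index:5d} {name_field:<4s} "
                f"{atom.residue_name:<3s} {atom.chain_id:1s}"
                f"{atom.residue_index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{atom.vdw_radius:6.2f}          "
                f"{atom.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _parse_residue_field(text: str, row_no: int) -> frozenset[int]:
    """Parse "303,305,306" / "58-62" / mixtures of both into a residue set."""
    indices: set[int] = set()
    for token in text.replace(";", ",").split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            try:
                lo_s, hi_s = token.split("-")
                lo, hi = int(lo_s), int(hi_s)
            except ValueError as exc:
                raise ValueError(
                    f"row {row_no}: malformed range {token!r}"
                ) from exc
            if hi < lo:
                raise ValueError(f"row {row_no}: malformed range {token!r} (end < start)")
            indices.update(range(lo, hi + 1))
        else:
            try:
                indices.add(int(token))
            except ValueError as exc:
                raise ValueError(f"row {row_no}: bad residue index {token!r}") from exc
    if not indices:
        raise ValueError(f"row {row_no}: empty residue list")
    return frozenset(indices)


def load_region_config(path: str | Path) -> list[MotifDefinition]:
    """Load motif/loop definitions from a TSV with columns name, domain_tag, residues."""
    path = Path(path)
    motifs: list[MotifDefinition] = []
    seen: set[str] = set()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        required = {"name", "domain_tag", "residues"}
        if not required.issubset(header):
            raise ValueError(
                f"region config must have columns {sorted(required)}, got {header}"
            )
        cols = {c: header.index(c) for c in required}
        for row_no, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[cols["name"]].strip()
            if name in seen:
                raise ValueError(f"row {row_no}: duplicate motif name {name!r}")
            seen.add(name)
            motifs.append(
                MotifDefinition(
                    name=name,
                    domain_tag=parts[cols["domain_tag"]].strip(),
                    residue_indices=_parse_residue_field(parts[cols["residues"]], row_no),
                )
            )
    return motifs


def default_region_config_path() -> Path:
    """Path to the packaged default region config (Domain V loops + DI/DII motifs)."""
    return Path(str(resources.files("epishift").joinpath("data/regions_default.tsv")))


def check_motifs_against_topology(
    motifs: Iterable[MotifDefinition], topology: Sequence[AtomRecord]
) -> None:
    """Raise if any motif references a residue absent from the topology."""
    present = {a.residue_index for a in topology}
    for motif in motifs:
        missing = sorted(set(motif.residue_indices) - present)
        if missing:
            raise ValueError(
                f"motif {motif.name!r} references residues missing from "
                f"topology: {missing}"
            )
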