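"""Structural kernels: optimal superposition, RMSD, radius of gyration, SASA.

The solvent-accessible surface area follows Shrake & Rupley: each atom is
probed with a deterministic golden-spiral point lattice on its expanded
sphere (vdW radius + probe radius); a point counts as accessible when it
falls outside every neighbour's expanded sphere.  The lattice is fixed (no
RNG), so areas are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomRecord, Frame

__all__ = [
    "SuperpositionResult",
    "SasaResult",
    "kabsch_superpose",
    "rmsd",
    "radius_of_gyration",
    "shrake_rupley_sasa",
    "golden_spiral_points",
]

#: Standard atomic masses (Da) for mass-weighted radius of gyration.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "SE": 78.971,
}
DEFAULT_MASS = 12.011


class DegenerateGeometryError(ValueError):
    """Raised when a superposition mask is too small or collinear."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation of mobile onto reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd_after: float

    def apply(self, coordinates: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array."""
        return coordinates @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""

    per_atom_area: np.ndarray
    per_residue_area: dict[int, float]
    probe_radius: float
    n_sphere_points: int


def _as_coords(frame: Frame | np.ndarray) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.coordinates
    return np.asarray(frame, dtype=float)


def _masked(coords: np.ndarray, atom_mask: Sequence[int] | None) -> np.ndarray:
    if atom_mask is None:
        return coords
    idx = np.asarray(sorted(atom_mask), dtype=int)
    if idx.size == 0:
        raise ValueError("atom mask is empty")
    return coords[idx]


def kabsch_superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    atom_mask: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation is obtained from the Kabsch/SVD solution
    (via :meth:`scipy.spatial.transform.Rotation.align_vectors`, which
    enforces det = +1).  ``rmsd_after`` is the RMSD over the masked atoms
    after applying the returned transform.
    """
    mob = _masked(_as_coords(mobile), atom_mask)
    ref = _masked(_as_coords(reference), atom_mask)
    if mob.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: mobile {mob.shape[0]} vs reference {ref.shape[0]}"
        )
    if mob.shape[0] < 3:
        raise DegenerateGeometryError(
            f"superposition needs >= 3 atoms, got {mob.shape[0]}"
        )
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    mob_c = mob - mob_center
    ref_c = ref - ref_center
    # collinearity check: rank of centered coordinates < 2 leaves a free rotation
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("masked atoms are collinear or coincident")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    translation = ref_center - matrix @ mob_center
    moved = mob @ matrix.T + translation
    rmsd_after = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd_after=rmsd_after)


def rmsd(
    a: Frame | np.ndarray,
    b: Frame | np.ndarray,
    atom_mask: Sequence[int] | None = None,
    align: bool = False,
) -> float:
    """Root-mean-square coordinate deviation between two frames (A).

    With ``align=True`` the optimal superposition is applied first, so the
    value cannot exceed the unaligned RMSD.
    """
    ca = _masked(_as_coords(a), atom_mask)
    cb = _masked(_as_coords(b), atom_mask)
    if ca.shape != cb.shape:
        raise ValueError("frames have different masked atom counts")
    if ca.shape[0] == 0:
        raise ValueError("atom mask is empty")
    if align:
        return kabsch_superpose(a, b, atom_mask).rmsd_after
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def radius_of_gyration(
    frame: Frame | np.ndarray,
    topology: Sequence[AtomRecord] | None = None,
    atom_mask: Sequence[int] | None = None,
    mass_weighted: bool = False,
) -> float:
    """Radius of gyration sqrt(sum w_i |r_i - rbar|^2 / sum w_i) in Angstrom."""
    coords = _as_coords(frame)
    if mass_weighted:
        if topology is None:
            raise ValueError("mass_weighted=True requires a topology")
        weights = np.array(
            [ATOMIC_MASSES.get(a.element.upper(), DEFAULT_MASS) for a in topology]
        )
    else:
        weights = np.ones(coords.shape[0])
    if atom_mask is not None:
        idx = np.asarray(sorted(atom_mask), dtype=int)
        if idx.size == 0:
            raise ValueError("atom mask is empty")
        coords = coords[idx]
        weights = weights[idx]
    center = np.average(coords, axis=0, weights=weights)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=weights)))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform point lattice on the unit sphere.

    Golden-section spiral: z descends uniformly while the azimuth advances
    by the golden angle.  No randomness, so repeated calls are identical.
    """
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(
    frame: Frame | np.ndarray,
    topology: Sequence[AtomRecord],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Per-atom area = (accessible lattice points / n_points) * 4 pi (r + probe)^2,
    with the neighbour search restricted to atoms whose centres lie within
    r_i + r_j + 2 * probe of atom i.  Per-residue areas are the sums over
    member atoms.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable lattice")
    coords = _as_coords(frame)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n_atoms = coords.shape[0]
    if n_atoms != len(topology):
        raise ValueError("frame and topology atom counts differ")

    radii = np.array([a.vdw_radius for a in topology])
    expanded = radii + probe_radius
    unit = golden_spiral_points(n_points)

    # pairwise neighbour cutoffs: centres closer than r_i + r_j + 2*probe overlap
    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.sum(diff * diff, axis=-1)
    cutoff = radii[:, None] + radii[None, :] + 2.0 * probe_radius
    neighbor = (dist2 < cutoff**2) & ~np.eye(n_atoms, dtype=bool)
    sphere_area = 4.0 * np.pi * expanded**2

    counts = neighbor.sum(axis=1)
    k_max = int(counts.max()) if n_atoms > 1 else 0
    if k_max == 0:
        areas = sphere_area.copy()
    else:
        # padded neighbour lists (self-padded: an atom never blocks its own
        # lattice points, which sit exactly on its expanded sphere)
        nb_idx = np.full((n_atoms, k_max), 0, dtype=int)
        for i in range(n_atoms):
            nb = np.flatnonzero(neighbor[i])
            nb_idx[i, : nb.size] = nb
            nb_idx[i, nb.size :] = i
        nb_coords = coords[nb_idx]  # (n, k, 3)
        nb_r2 = (expanded[nb_idx] ** 2) - 1e-7  # strict inequality at self-padding
        test = coords[:, None, :] + expanded[:, None, None] * unit[None, :, :]  # (n, p, 3)
        # |t - c|^2 = |t|^2 + |c|^2 - 2 t.c, batched over atoms
        cross = np.matmul(test, nb_coords.transpose(0, 2, 1))  # (n, p, k)
        t2 = np.sum(test * test, axis=-1)  # (n, p)
        c2 = np.sum(nb_coords * nb_coords, axis=-1)  # (n, k)
        d2 = t2[:, :, None] + c2[:, None, :] - 2.0 * cross
        blocked = np.any(d2 < nb_r2[:, None, :], axis=2)  # (n, p)
        areas = sphere_area * (1.0 - blocked.mean(axis=1))

    per_residue: dict[int, float] = {}
    for atom, area in zip(topology, areas):
        per_residue[atom.residue_index] = per_residue.get(atom.residue_index, 0.0) + float(area)

    return SasaResult(
        per_atom_area=areas,
        per_residue_area=per_residue,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


def max_residue_accessibility(
    topology: Sequence[AtomRecord], probe_radius: float = 1.4
) -> dict[int, float]:
    """Isolated-sphere maximum accessibility per residue (A^2).

    Sum over member atoms of 4 pi (r + probe)^2 — the area each atom would
    expose with no neighbours.  Used to normalise SASA into a relative
    exposure in [0, 1].
    """
    out: dict[int, float] = {}
    for atom in topology:
        area = 4.0 * np.pi * (atom.vdw_radius + probe_radius) ** 2
        out[atom.residue_index] = out.get(atom.residue_index, 0.0) + area
    return out
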