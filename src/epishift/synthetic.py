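"""Synthetic data with planted ground truth.

Two generators:

* **Conformer trajectories** — a two-bead-per-residue chain that starts
  circular (O), extends into a bent line (J) and then a doubly-bent line
  (S) under a logistic switching schedule.  The "variant" model switches
  later (a slower O-to-linear transition) and carries side beads that are
  rotated toward the chain axis over a chosen loop (planting a target
  solvent-burial fraction) and away from it over a chosen motif (planting
  a target exposure gain).  Burial/exposure targets are calibrated by
  bisection against actual SASA on the noiseless extended geometry, so
  the planted deltas are real properties of the generated structures.
* **Two-trait GWAS summary statistics** — dosages from a liability-
  threshold AR(1) latent field (correlation rho^|i-j|), one causal
  variant per trait (shared or distinct), marginal per-variant
  regressions giving beta/se/p.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genetics import SummaryStatRecord
from .geometry import shrake_rupley_sasa
from .structure_io import AtomRecord, Frame, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ConformerScenario",
    "SyntheticTruth",
    "make_toy_topology",
    "state_geometry",
    "simulate_conformer_trajectory",
    "simulate_model_set",
    "simulate_two_trait_summary_stats",
]

CA_RADIUS = 1.9  # backbone bead vdW radius, A
CB_RADIUS = 2.0  # side bead vdW radius, A
CB_OFFSET = 2.5  # side bead distance from its backbone bead, A
CA_SPACING = 3.8  # consecutive backbone bead spacing, A
NEUTRAL_LAMBDA = 0.35  # default side-bead tilt toward the chain axis


@dataclass(frozen=True)
class ConformerScenario:
    """The stated world for the conformer generator.

    ``transition_midpoint`` holds the O-to-J switch frame per model; the
    J-to-S switch follows ``state_gap`` frames later.  The variant's
    midpoint must not precede the wild type's (slower transition).
    """

    n_residues: int = 60
    states: tuple[str, ...] = ("O", "J", "S")
    n_frames: int = 200
    n_repeats: int = 4
    noise_sd: float = 0.5  # A, isotropic on backbone beads
    transition_midpoint: tuple[tuple[str, float], ...] = (("WT", 70.0), ("VARIANT", 90.0))
    state_gap: float = 60.0  # frames between the two switches
    transition_rate: float = 0.02  # logistic slope, frames; near-two-state per-repeat switch
    midpoint_jitter: float = 15.0  # per-repeat uniform jitter on the midpoints, frames
    buried_loop: frozenset[int] = frozenset({40, 41, 42})
    burial_fraction: float = 0.30
    exposed_motif: frozenset[int] = frozenset({10, 11, 12, 13, 14})
    exposure_fraction: float = 0.10
    time_per_frame: float = 0.1  # ns
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.burial_fraction < 1:
            raise ValueError("burial_fraction must be in (0, 1)")
        if not 0 < self.exposure_fraction < 1:
            raise ValueError("exposure_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        mid = dict(self.transition_midpoint)
        if "WT" in mid and "VARIANT" in mid and mid["VARIANT"] < mid["WT"]:
            raise ValueError(
                "VARIANT transition_midpoint must be >= WT's (slower variant switch)"
            )

    def midpoint(self, model: str) -> float:
        return dict(self.transition_midpoint)[model]


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    # conformer scenario
    state_labels: list[str] | None = None  # per frame
    residue_classes: dict[int, str] | None = None  # buried_in_variant / exposed_in_variant / neutral
    planted_burial_fraction: float | None = None
    planted_exposure_fraction: float | None = None
    achieved_burial_fraction: float | None = None
    achieved_exposure_fraction: float | None = None
    # GWAS scenario
    causal_variant: str | None = None
    causal_variant_trait2: str | None = None
    true_effects: dict[str, float] | None = None


def make_toy_topology(n_residues: int) -> list[AtomRecord]:
    """Two beads per residue: backbone "CA" (r=1.9 A) and side "CB" (r=2.0 A)."""
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    atoms: list[AtomRecord] = []
    idx = 1
    for res in range(1, n_residues + 1):
        for name, radius in (("CA", CA_RADIUS), ("CB", CB_RADIUS)):
            atoms.append(
                AtomRecord(
                    atom_index=idx,
                    atom_name=name,
                    element="C",
                    residue_index=res,
                    residue_name="ALA",
                    chain_id="A",
                    vdw_radius=radius,
                )
            )
            idx += 1
    return atoms


def state_geometry(state: str, n_residues: int) -> np.ndarray:
    """Backbone-bead coordinates for one idealized state, in the xy-plane.

    O: beads equally spaced on a circle whose circumference gives 3.8 A
    spacing.  J: straight line with the last ceil(n/6) residues bent 90
    degrees.  S: line with two opposite 90-degree bends at thirds.
    """
    n = n_residues
    if state == "O":
        radius = CA_SPACING / (2.0 * np.sin(np.pi / n))
        angles = 2.0 * np.pi * np.arange(n) / n
        return np.column_stack(
            [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
        )
    if state == "J":
        bend = int(np.ceil(n / 6))
        straight = n - bend
        coords = np.zeros((n, 3))
        coords[:straight, 0] = CA_SPACING * np.arange(straight)
        # 90-degree bend: continue along +y
        coords[straight:, 0] = CA_SPACING * (straight - 1)
        coords[straight:, 1] = CA_SPACING * np.arange(1, bend + 1)
        return coords
    if state == "S":
        # three straight segments with a left turn then a right turn (+x, +y, +x);
        # bend positions chosen so the S shape is well separated from both the
        # J shape and the circle under optimal superposition
        b1, b2 = int(round(0.43 * n)), int(round(0.83 * n))
        coords = np.zeros((n, 3))
        directions = [(1, 0), (0, 1), (1, 0)]
        pos = np.zeros(2)
        seg_ends = [b1, b2, n]
        start = 0
        for (dx, dy), end in zip(directions, seg_ends):
            for i in range(start, end):
                if i > 0:
                    pos = pos + CA_SPACING * np.array([dx, dy])
                coords[i, :2] = pos
            start = end
        return coords
    raise ValueError(f"unknown state {state!r}")


def _chain_frame_vectors(backbone: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue unit tangent and outward normal of a backbone curve.

    The tangent is the central difference along the chain; the normal is
    the in-plane perpendicular (z x t), sign-flipped to point away from
    the chain centroid.  All state geometries live in the xy-plane, so
    the construction is never degenerate there.
    """
    n = backbone.shape[0]
    tangent = np.empty_like(backbone)
    tangent[1:-1] = backbone[2:] - backbone[:-2]
    tangent[0] = backbone[1] - backbone[0]
    tangent[-1] = backbone[-1] - backbone[-2]
    norms = np.linalg.norm(tangent, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangent /= norms

    z = np.array([0.0, 0.0, 1.0])
    normal = np.cross(np.broadcast_to(z, tangent.shape), tangent)
    nn = np.linalg.norm(normal, axis=1, keepdims=True)
    degenerate = nn[:, 0] < 1e-8
    normal[degenerate] = [1.0, 0.0, 0.0]
    nn[nn == 0] = 1.0
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    centroid = backbone.mean(axis=0)
    outward = np.einsum("ij,ij->i", normal, backbone - centroid)
    normal[outward < 0] *= -1.0
    return tangent, normal


@dataclass(frozen=True)
class SideBeadPlacement:
    """Per-residue side-bead placement parameters.

    ``tilt`` interpolates the bead direction from the outward chain normal
    (0) to the chain tangent (1), where neighbouring backbone beads
    occlude it.  ``lift`` (signed, in [-1, 1]) further interpolates toward
    +/-z, out of the plane all state geometries live in — alternating the
    sign along consecutive residues removes mutual side-bead occlusion,
    the most exposed placement available.  ``scale`` shrinks the bead
    offset below CB_OFFSET so the bead sinks into its backbone bead (it
    never exceeds CB_OFFSET, so side beads stay within 2.5 A of their
    backbone bead in every frame).
    """

    tilt: np.ndarray
    lift: np.ndarray
    scale: np.ndarray

    @staticmethod
    def neutral(n_residues: int) -> "SideBeadPlacement":
        return SideBeadPlacement(
            tilt=np.full(n_residues, NEUTRAL_LAMBDA),
            lift=np.zeros(n_residues),
            scale=np.ones(n_residues),
        )

    def with_residues(
        self, residues: frozenset[int], tilt: float, lift: float, scale: float
    ) -> "SideBeadPlacement":
        """Override placement of a residue set; lift signs alternate along it."""
        new = SideBeadPlacement(self.tilt.copy(), self.lift.copy(), self.scale.copy())
        for rank, r in enumerate(sorted(residues)):
            i = r - 1
            new.tilt[i] = tilt
            new.lift[i] = lift if rank % 2 == 0 else -lift
            new.scale[i] = scale
        return new


def _side_bead_directions(backbone: np.ndarray, placement: SideBeadPlacement) -> np.ndarray:
    tangent, normal = _chain_frame_vectors(backbone)
    lam = placement.tilt[:, None]
    mix = (1.0 - lam) * normal + lam * tangent
    z = np.array([0.0, 0.0, 1.0])
    lift = placement.lift[:, None]
    mix = (1.0 - np.abs(lift)) * mix + lift * z
    norms = np.linalg.norm(mix, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mix / norms


def _assemble_frame(backbone: np.ndarray, placement: SideBeadPlacement) -> np.ndarray:
    """Interleave backbone beads with side beads at scale * CB_OFFSET."""
    directions = _side_bead_directions(backbone, placement)
    cb = backbone + (placement.scale[:, None] * CB_OFFSET) * directions
    coords = np.empty((2 * backbone.shape[0], 3))
    coords[0::2] = backbone
    coords[1::2] = cb
    return coords


def _motif_sasa(
    coords: np.ndarray,
    topology: list[AtomRecord],
    residues: frozenset[int],
    n_points: int = 960,
) -> float:
    sasa = shrake_rupley_sasa(coords, topology, n_points=n_points)
    return sum(sasa.per_residue_area[r] for r in residues)


def _burial_params(u: float) -> tuple[float, float, float]:
    """Map a burial coordinate u in [0, 3] to (tilt, lift, scale).

    The path starts at the exposed placement (lift 1): u <= 1 lowers the
    bead back into the chain plane, 1 < u <= 2 tilts it toward the chain
    tangent where backbone beads occlude it, u > 2 sinks it into its
    backbone bead.  SASA decreases monotonically along the path.
    """
    if u <= 1.0:
        return 0.0, 1.0 - u, 1.0
    if u <= 2.0:
        return u - 1.0, 0.0, 1.0
    return 1.0, 0.0, 3.0 - u


def _exposure_params(u: float) -> tuple[float, float, float]:
    """Map an exposure coordinate u in [0, 2] to (tilt, lift, scale).

    u <= 1 untilts the bead from neutral to the pure outward normal;
    u > 1 lifts it out of the chain plane (alternating +/-z along the
    motif), where nothing occludes it.
    """
    if u <= 1.0:
        return NEUTRAL_LAMBDA * (1.0 - u), 0.0, 1.0
    return 0.0, u - 1.0, 1.0


def _calibrate_placement(
    topology: list[AtomRecord],
    backbone: np.ndarray,
    reference_placement: SideBeadPlacement,
    residues: frozenset[int],
    target_ratio: float,
    param_fn,
    u_max: float,
    n_iter: int = 18,
) -> tuple[tuple[float, float, float], float]:
    """Bisection along a monotone placement path to hit a motif-SASA ratio.

    The reference is the wild-type structure; the placement of the target
    residues moves along ``param_fn(u)`` for u in [0, u_max] until motif
    SASA / reference matches ``target_ratio``.  Clamps to the path end
    with a warning when the target is unreachable.
    """
    reference = _motif_sasa(
        _assemble_frame(backbone, reference_placement), topology, residues
    )

    def ratio_at(u: float) -> float:
        placement = reference_placement.with_residues(residues, *param_fn(u))
        return _motif_sasa(_assemble_frame(backbone, placement), topology, residues) / reference

    lo, hi = 0.0, u_max
    r_lo, r_hi = ratio_at(lo), ratio_at(hi)
    if (r_lo - target_ratio) * (r_hi - target_ratio) > 0:
        u = lo if abs(r_lo - target_ratio) < abs(r_hi - target_ratio) else hi
        achieved = ratio_at(u)
        warnings.warn(
            f"target motif-SASA ratio {target_ratio:.3f} unreachable along the "
            f"placement path; clamped at u={u:.2f} (achieved ratio {achieved:.3f})"
        )
        return param_fn(u), achieved
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = ratio_at(mid)
        if (r_lo - target_ratio) * (r_mid - target_ratio) <= 0:
            hi, r_hi = mid, r_mid
        else:
            lo, r_lo = mid, r_mid
    u = 0.5 * (lo + hi)
    return param_fn(u), ratio_at(u)


_CALIBRATION_CACHE: dict[tuple, tuple[SideBeadPlacement, SideBeadPlacement, float, float]] = {}


def _planted_placements(
    scenario: ConformerScenario,
) -> tuple[SideBeadPlacement, SideBeadPlacement, float, float]:
    """Side-bead placements for WT and VARIANT, with achieved delta fractions.

    Calibrated once per scenario on the noiseless J (extended) geometry
    and cached.  The WT is neutral everywhere except the functional loop,
    whose side beads are fully solvent-exposed (they model an exposed
    membrane-insertion loop, exposed because that is its function in the
    wild type); the VARIANT buries that loop to the burial target and
    exposes the chosen epitope motif to the exposure target.
    """
    key = (
        scenario.n_residues,
        scenario.buried_loop,
        scenario.burial_fraction,
        scenario.exposed_motif,
        scenario.exposure_fraction,
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    topology = make_toy_topology(scenario.n_residues)
    backbone = state_geometry("J", scenario.n_residues)
    wt = SideBeadPlacement.neutral(scenario.n_residues).with_residues(
        scenario.buried_loop, tilt=0.0, lift=1.0, scale=1.0
    )
    buried_params, burial_ratio = _calibrate_placement(
        topology,
        backbone,
        wt,
        scenario.buried_loop,
        target_ratio=1.0 - scenario.burial_fraction,
        param_fn=_burial_params,
        u_max=3.0,
    )
    exposed_params, exposure_ratio = _calibrate_placement(
        topology,
        backbone,
        wt,
        scenario.exposed_motif,
        target_ratio=1.0 + scenario.exposure_fraction,
        param_fn=_exposure_params,
        u_max=2.0,
    )
    var = wt.with_residues(scenario.buried_loop, *buried_params).with_residues(
        scenario.exposed_motif, *exposed_params
    )
    result = (wt, var, 1.0 - burial_ratio, exposure_ratio - 1.0)
    _CALIBRATION_CACHE[key] = result
    return result


def _logistic(t: np.ndarray, midpoint: float, rate: float) -> np.ndarray:
    from scipy.special import expit

    return expit((t - midpoint) / rate)


def simulate_conformer_trajectory(
    scenario: ConformerScenario,
    model: str = "WT",
    start_shape: str = "circular",
    repeat_id: int = 0,
) -> tuple[Trajectory, SyntheticTruth]:
    """One repeat of the planted conformational transition.

    Circular starts interpolate O -> J -> S under two logistic switches
    (midpoints per model; the variant's is later).  Linear starts stay
    pinned at the J geometry throughout.  Isotropic Gaussian noise
    (``noise_sd``) perturbs backbone beads; side beads are then placed at
    exactly ``CB_OFFSET`` from their (noisy) backbone bead along the
    planted direction, so the bead-offset invariant holds in every frame.
    """
    if model not in dict(scenario.transition_midpoint):
        raise ValueError(f"unknown model {model!r}")
    if start_shape not in ("circular", "linear"):
        raise ValueError(f"unknown start_shape {start_shape!r}")

    topology = make_toy_topology(scenario.n_residues)
    wt_place, var_place, achieved_burial, achieved_exposure = _planted_placements(scenario)
    placement = var_place if model == "VARIANT" else wt_place

    geom = {s: state_geometry(s, scenario.n_residues) for s in ("O", "J", "S")}

    shape_code = 0 if start_shape == "circular" else 1
    model_code = 0 if model == "WT" else 1
    rng = np.random.default_rng(
        [scenario.seed % (2**31), model_code, shape_code, repeat_id]
    )

    # each repeat switches at its own jittered time; the ensemble-level
    # departure from the starting shape is therefore gradual even though
    # any single repeat switches sharply
    jitter = (
        rng.uniform(-scenario.midpoint_jitter, scenario.midpoint_jitter)
        if scenario.midpoint_jitter > 0
        else 0.0
    )
    t = np.arange(scenario.n_frames, dtype=float)
    m1 = scenario.midpoint(model) + jitter
    m2 = m1 + scenario.state_gap
    w1 = _logistic(t, m1, scenario.transition_rate)
    w2 = _logistic(t, m2, scenario.transition_rate)

    frames: list[Frame] = []
    labels: list[str] = []
    for i in range(scenario.n_frames):
        if start_shape == "linear":
            backbone = geom["J"].copy()
            labels.append("J")
        else:
            backbone = (
                geom["O"]
                + w1[i] * (geom["J"] - geom["O"])
                + w2[i] * (geom["S"] - geom["J"])
            )
            if w1[i] < 0.5:
                labels.append("O")
            elif w2[i] < 0.5:
                labels.append("J")
            else:
                labels.append("S")
        if scenario.noise_sd > 0:
            backbone = backbone + rng.normal(0.0, scenario.noise_sd, backbone.shape)
        coords = _assemble_frame(backbone, placement)
        frames.append(Frame(coords, time_label=i * scenario.time_per_frame))

    residue_classes = {}
    for r in range(1, scenario.n_residues + 1):
        if r in scenario.buried_loop:
            residue_classes[r] = "buried_in_variant"
        elif r in scenario.exposed_motif:
            residue_classes[r] = "exposed_in_variant"
        else:
            residue_classes[r] = "neutral"

    truth = SyntheticTruth(
        state_labels=labels,
        residue_classes=residue_classes,
        planted_burial_fraction=scenario.burial_fraction,
        planted_exposure_fraction=scenario.exposure_fraction,
        achieved_burial_fraction=achieved_burial,
        achieved_exposure_fraction=achieved_exposure,
    )
    traj = Trajectory(
        topology=topology,
        frames=frames,
        model_label=model,
        start_shape=start_shape,
        repeat_id=repeat_id,
    )
    return traj, truth


def simulate_model_set(
    scenario: ConformerScenario,
    models: tuple[str, ...] = ("WT", "VARIANT"),
    start_shapes: tuple[str, ...] = ("circular",),
    n_repeats: int | None = None,
) -> tuple[list[Trajectory], list[SyntheticTruth]]:
    """All repeats for the requested models and starting shapes."""
    n_rep = scenario.n_repeats if n_repeats is None else n_repeats
    trajs, truths = [], []
    for model in models:
        for shape in start_shapes:
            for rep in range(n_rep):
                traj, truth = simulate_conformer_trajectory(scenario, model, shape, rep)
                trajs.append(traj)
                truths.append(truth)
    return trajs, truths


def _indicator_corr(r: np.ndarray, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Correlation of 1{z1<t1}, 1{z2<t2} for bivariate normal z with corr r.

    The bivariate orthant probability is evaluated by Gauss-Legendre
    quadrature of P(z2<t2 | z1=x) over x < t1.  Vectorized over pairs.
    """
    from scipy.stats import norm

    r = np.clip(np.asarray(r, dtype=float), -0.9999, 0.9999)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    nodes, weights = np.polynomial.legendre.leggauss(48)
    lo = -8.5
    # map [-1, 1] -> [lo, t1] per pair
    half = (t1 - lo) / 2.0
    x = lo + half[..., None] * (nodes + 1.0)  # (..., 48)
    cond = norm.cdf((t2[..., None] - r[..., None] * x) / np.sqrt(1.0 - r[..., None] ** 2))
    p11 = half * np.sum(weights * norm.pdf(x) * cond, axis=-1)
    p1 = norm.cdf(t1)
    p2 = norm.cdf(t2)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


_LATENT_CORR_CACHE: dict[tuple, np.ndarray] = {}


def _latent_corr_matrix(rho: float, mafs: np.ndarray) -> np.ndarray:
    """Latent Gaussian correlations whose thresholded indicators have corr rho^|i-j|.

    Thresholding attenuates correlation (more strongly at rare MAFs), so
    each pair's latent correlation is solved by bisection to make the
    realized dosage LD match the stated AR(1) decay.  The assembled
    matrix is projected to the nearest PSD matrix by eigenvalue clipping.
    """
    from scipy.stats import norm

    key = (float(rho), mafs.tobytes())
    if key in _LATENT_CORR_CACHE:
        return _LATENT_CORR_CACHE[key]
    m = mafs.size
    thresholds = norm.ppf(mafs)
    ii, jj = np.triu_indices(m, 1)
    target = rho ** np.abs(ii - jj)
    # Frechet bound: indicators with unequal marginals cannot reach corr 1;
    # cap the target so the bisection stays solvable for user-supplied MAFs
    p_lo = np.minimum(mafs[ii], mafs[jj])
    p_hi = np.maximum(mafs[ii], mafs[jj])
    frechet = np.sqrt(p_lo * (1 - p_hi) / (p_hi * (1 - p_lo)))
    target = np.minimum(target, 0.98 * frechet)
    t1, t2 = thresholds[ii], thresholds[jj]
    lo = np.zeros_like(target)
    hi = np.full_like(target, 0.9999)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        achieved = _indicator_corr(mid, t1, t2)
        go_up = achieved < target
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    r = 0.5 * (lo + hi)
    R = np.eye(m)
    R[ii, jj] = r
    R[jj, ii] = r
    eigval, eigvec = np.linalg.eigh(R)
    if eigval.min() < 1e-10:
        eigval = np.clip(eigval, 1e-10, None)
        R = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    _LATENT_CORR_CACHE[key] = R
    return R


def _ar1_dosages(
    rng: np.random.Generator, n: int, m: int, rho: float, mafs: np.ndarray
) -> np.ndarray:
    """Hardy-Weinberg dosages from a thresholded latent Gaussian field.

    Each of the two haplotype copies is an independent draw from a latent
    Gaussian whose correlations are calibrated so the thresholded allele
    indicators — and hence the dosages — have correlation rho^|i-j|.
    """
    from scipy.stats import norm

    thresholds = norm.ppf(mafs)
    L = np.linalg.cholesky(_latent_corr_matrix(rho, mafs))
    dosage = np.zeros((n, m))
    for _hap in range(2):
        z = rng.standard_normal((n, m)) @ L.T
        dosage += (z < thresholds[None, :]).astype(float)
    return dosage


def _marginal_regression(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple linear regression slopes and standard errors."""
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc * xc, axis=0)
    beta = xc.T @ yc / sxx
    resid_var = (
        np.sum(yc * yc) - beta * (xc.T @ yc)
    ) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    return beta, se


def simulate_two_trait_summary_stats(
    m_variants: int = 50,
    n: int = 5000,
    ld_rho: float = 0.9,
    causal_index: int = 25,
    shared: bool = True,
    variance_explained: float = 0.01,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 1,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SyntheticTruth]:
    """Two independent-cohort GWAS of a region with known causal structure.

    ``causal_index`` is 1-based.  With ``shared=True`` both traits are
    driven by the same variant; otherwise trait 2's causal variant is
    drawn at least 20 positions away (low LD at rho^20).  Effect sizes are
    scaled so the causal variant explains ``variance_explained`` of each
    trait's variance.
    """
    from scipy.stats import norm as _norm

    if not 1 <= causal_index <= m_variants:
        raise ValueError("causal_index out of range")
    rng = np.random.default_rng([seed % (2**31), 777])
    # MAFs vary smoothly along the region: variants in strong LD share
    # haplotypes and hence similar allele frequencies (an iid draw would
    # make high LD between frequency-mismatched neighbours unattainable)
    u = np.empty(m_variants)
    u[0] = rng.standard_normal()
    innov = rng.standard_normal(m_variants - 1)
    for j in range(1, m_variants):
        u[j] = ld_rho * u[j - 1] + np.sqrt(1.0 - ld_rho**2) * innov[j - 1]
    mafs = maf_range[0] + (maf_range[1] - maf_range[0]) * _norm.cdf(u)

    causal2 = causal_index
    if not shared:
        candidates = [
            j
            for j in range(1, m_variants + 1)
            if abs(j - causal_index) >= 20
        ]
        if not candidates:
            raise ValueError("no position >= 20 variants away for the second causal")
        causal2 = int(rng.choice(candidates))

    ids = [f"rs{1000 + j}" for j in range(1, m_variants + 1)]
    records: list[list[SummaryStatRecord]] = []
    true_effects: dict[str, float] = {}
    for trait_idx, causal in ((0, causal_index), (1, causal2)):
        X = _ar1_dosages(rng, n, m_variants, ld_rho, mafs)
        g = X[:, causal - 1]
        var_g = g.var()
        if var_g == 0:
            raise RuntimeError("causal variant is monomorphic in the simulated cohort")
        beta_true = np.sqrt(variance_explained / var_g) if variance_explained > 0 else 0.0
        y = beta_true * g + rng.normal(0.0, np.sqrt(1.0 - variance_explained), n)
        beta, se = _marginal_regression(X, y)
        z = beta / se
        pvals = np.clip(2.0 * _norm.sf(np.abs(z)), 1e-300, 1.0)
        eafs = np.clip(X.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
        recs = [
            SummaryStatRecord(
                variant_id=ids[j],
                chromosome="17",
                position=66_100_000 + 1000 * (j + 1),
                effect_allele="A",
                other_allele="G",
                eaf=float(eafs[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                p=float(pvals[j]),
                n=n,
            )
            for j in range(m_variants)
        ]
        records.append(recs)
        true_effects[f"trait{trait_idx + 1}"] = float(beta_true)

    truth = SyntheticTruth(
        causal_variant=ids[causal_index - 1],
        causal_variant_trait2=ids[causal2 - 1],
        true_effects=true_effects,
    )
    return records[0], records[1], truth
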