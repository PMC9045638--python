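"""Toy bead-helix geometry: templates, poses, and CV inverse kinematics.

The synthetic sampler works in collective-variable space; this module turns
CV samples back into bead coordinates.  Each monomer is an ideal alpha-helix
of one backbone and one side bead per residue (axial rise 0.15 nm/residue,
100 degrees twist/residue) with a gentle quadratic axis bend, placed rigidly
in the membrane plane.

A :class:`TopologyTemplate` names one of the three planted dimer topologies
(parallel, inverted V-shape, V-shape) by its descriptor targets: the modes of
the N-terminal / middle / C-terminal region minimum distances, the crossing
angle, and the global minimum inter-monomer distance.  ``solve_template``
finds, once per template, a canonical relative placement (tilts, bends,
spins, separation) realizing those targets; ``pose_from_cvs`` then adjusts
only the two azimuthal spins and the separation so that the interface
dihedrals (phi1, phi2) and the COM distance d match requested values exactly.
Spins map almost one-to-one onto the dihedrals (each dihedral measures which
helix face points at the partner), so the 2x2 Newton solve is well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .topology import (DimerTopology, FrameGeometry, com_distance,
                       compute_phi1_phi2, crossing_angle, min_distance,
                       wrap_angle)

__all__ = [
    "HelixParams",
    "MonomerPlacement",
    "ToyPose",
    "TopologyTemplate",
    "TemplateSolution",
    "DEFAULT_TEMPLATES",
    "build_monomer",
    "pose_frame",
    "solve_template",
    "pose_from_cvs",
    "solve_spins_batch",
    "frames_from_cvs",
]


@dataclass(frozen=True)
class HelixParams:
    """Ideal helix geometry of one monomer."""

    rise: float = 0.15          # nm per residue along the axis
    twist_deg: float = 100.0    # degrees per residue
    r_backbone: float = 0.23    # nm, backbone bead radial offset
    r_side: float = 0.41        # nm, side bead radial offset
    center_residue: float = 18.0


DEFAULT_HELIX = HelixParams()


@dataclass(frozen=True)
class MonomerPlacement:
    """Rigid placement + internal shape of one monomer.

    ``spin`` rotates the helix about its own axis (which residue face points
    where); ``tilt_x``/``tilt_y`` tip the axis away from the membrane normal;
    the bend displaces beads along an in-plane direction ``bend_delta``
    quadratically in the axial coordinate about ``bend_zc`` (a gently curved
    helix axis).  Bead coordinates are a deterministic function of the pose;
    the monomer center of mass coincides with ``position``.
    """

    position: tuple = (0.0, 0.0, 0.0)
    tilt_x: float = 0.0
    tilt_y: float = 0.0
    spin: float = 0.0
    bend_kappa: float = 0.0     # nm^-1
    bend_delta: float = 0.0     # rad, bend direction in the xy plane
    bend_zc: float = 0.0        # nm, axial center of the bend


@dataclass(frozen=True)
class ToyPose:
    """Relative placement of the two monomers of a dimer."""

    monomer1: MonomerPlacement
    monomer2: MonomerPlacement
    template_name: str = ""


def _tilt_matrix(tilt_x: float, tilt_y: float) -> np.ndarray:
    cx, sx = np.cos(tilt_x), np.sin(tilt_x)
    cy, sy = np.cos(tilt_y), np.sin(tilt_y)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return ry @ rx


def _raw_helix(topo: DimerTopology, helix: HelixParams, spin):
    """Bead coordinates before tilt/translation; ``spin`` may be scalar or (N,).

    Returns an array of shape (..., n_beads, 3).
    """
    res = np.arange(1, topo.n_residues_per_monomer + 1, dtype=float)
    z = (res - helix.center_residue) * helix.rise
    theta0 = np.radians(helix.twist_deg) * res
    radii = np.stack([np.full_like(res, helix.r_backbone),
                      np.full_like(res, helix.r_side)], axis=1)  # (n_res, 2)
    theta = theta0[:, None] + np.zeros((1, topo.beads_per_residue))
    spin = np.asarray(spin, dtype=float)
    ang = theta[None] + spin.reshape(-1, 1, 1)  # (N, n_res, 2)
    x = radii[None] * np.cos(ang)
    y = radii[None] * np.sin(ang)
    zz = np.broadcast_to(z[None, :, None], x.shape)
    beads = np.stack([x, y, zz], axis=-1).reshape(spin.size, -1, 3)
    return beads if spin.ndim else beads[0]


def build_monomer(placement: MonomerPlacement, topo: DimerTopology,
                  helix: HelixParams = DEFAULT_HELIX) -> np.ndarray:
    """Bead coordinates (n_beads, 3) of one placed monomer, nm."""
    return _build_monomers_batch(
        placement, topo, helix,
        spins=np.array([placement.spin]),
        positions=np.asarray(placement.position, dtype=float).reshape(1, 3))[0]


def _build_monomers_batch(placement: MonomerPlacement, topo: DimerTopology,
                          helix: HelixParams, spins: np.ndarray,
                          positions: np.ndarray) -> np.ndarray:
    """Beads (N, n_beads, 3) for one monomer shape at many spins/positions."""
    beads = _raw_helix(topo, helix, spins)  # (N, nb, 3)
    if placement.bend_kappa != 0.0:
        # the bend is part of the rigid body: its direction co-rotates with
        # the spin so that spinning the helix rotates the bent rod as a whole
        ang = placement.bend_delta + np.atleast_1d(np.asarray(spins, dtype=float))
        u = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=-1)
        disp = placement.bend_kappa * (beads[..., 2] - placement.bend_zc) ** 2
        beads = beads + disp[..., None] * u[:, None, :]
    beads = beads - beads.mean(axis=1, keepdims=True)
    rot = _tilt_matrix(placement.tilt_x, placement.tilt_y)
    beads = beads @ rot.T
    return beads + positions[:, None, :]


def pose_frame(pose: ToyPose, topo: DimerTopology,
               helix: HelixParams = DEFAULT_HELIX, box=None) -> FrameGeometry:
    """Reconstruct the bead frame of a pose."""
    return FrameGeometry(build_monomer(pose.monomer1, topo, helix),
                         build_monomer(pose.monomer2, topo, helix), box=box)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyTemplate:
    """Descriptor targets of one planted dimer topology.

    ``region_targets`` are the modes of the minimum N-terminal, middle and
    C-terminal inter-monomer region distances (nm); ``crossing_angle_target``
    is the mean crossing angle (deg); ``dmin_target`` the typical global
    minimum distance of the bound dimer (nm); ``interface_residue`` the
    residue whose helix face points at the partner (sets the spin guess and
    hence the contact face).
    """

    name: str
    region_targets: tuple          # (N, mid, C) nm
    crossing_angle_target: float   # deg
    dmin_target: float             # nm
    interface_residue: int
    opening: float = 0.0           # initial in-plane half-tilt guess (rad)

    def __post_init__(self):
        if any(t <= 0 for t in self.region_targets) or self.dmin_target <= 0:
            raise ValueError("distance targets must be positive")
        if not 0.0 <= self.crossing_angle_target <= 90.0:
            raise ValueError("crossing angle target must lie in [0, 90] degrees")


# Region-distance modes and mean crossing angles of the three bound dimer
# topologies; the typical bound minimum distances are 0.46-0.50 nm.
DEFAULT_TEMPLATES = (
    TopologyTemplate("parallel", (0.63, 0.63, 0.62), 15.4, 0.462,
                     interface_residue=25, opening=0.0),
    TopologyTemplate("inverted-V", (1.37, 0.78, 0.62), 24.6, 0.469,
                     interface_residue=26, opening=0.10),
    TopologyTemplate("V", (1.25, 1.08, 0.64), 18.3, 0.495,
                     interface_residue=22, opening=0.08),
)


@dataclass(frozen=True)
class TemplateSolution:
    """A solved canonical placement for a template."""

    template: TopologyTemplate
    pose: ToyPose
    separation_dir: tuple            # unit vector monomer1 -> monomer2 COM
    canonical_cvs: tuple             # (phi1, phi2, d) of the canonical pose
    achieved: dict                   # hard-min descriptors actually realized


def _softmin(d: np.ndarray, beta: float = 1000.0) -> float:
    d = np.asarray(d, dtype=float).ravel()
    m = d.min()
    return float(m - np.log(np.exp(-(d - m) * beta).sum()) / beta)


def _pair_distances(frame: FrameGeometry, topo: DimerTopology, residues) -> np.ndarray:
    idx = topo.bead_indices(residues)
    pa, pb = frame.coords_a[idx], frame.coords_b[idx]
    return np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))


def _pose_from_params(x: np.ndarray, template: TopologyTemplate) -> ToyPose:
    tx1, ty1, tx2, ty2, s1, s2, k1, dl1, zc1, k2, dl2, zc2, sep, zoff = x
    m1 = MonomerPlacement((0.0, 0.0, 0.0), tx1, ty1, s1, k1, dl1, zc1)
    m2 = MonomerPlacement((sep, 0.0, zoff), tx2, ty2, s2, k2, dl2, zc2)
    return ToyPose(m1, m2, template.name)


def _descriptor_residuals(x, template, topo, helix, x0, hard=False, avoid_cvs=()):
    pose = _pose_from_params(np.asarray(x, dtype=float), template)
    frame = pose_frame(pose, topo, helix)
    # keep this topology's interface dihedrals away from other templates'
    # canonical CVs so the planted basins are well separated
    sep_res = []
    if avoid_cvs:
        p1, p2 = compute_phi1_phi2(frame, topo)
        for a1, a2 in avoid_cvs:
            dist = np.hypot(wrap_angle(p1 - a1), wrap_angle(p2 - a2))
            sep_res.append(max(0.0, 1.2 - dist) / 0.01)
    mind = np.min if hard else _softmin
    seg = topo.groups["helical_segment"]
    regions = [topo.groups["region_nterm"], topo.groups["region_mid"],
               topo.groups["region_cterm"]]
    res = []
    for region, target in zip(regions, template.region_targets):
        res.append((mind(_pair_distances(frame, topo, region)) - target) / 0.01)
    res.append((crossing_angle(frame, topo) - template.crossing_angle_target) / 0.5)
    res.append((mind(_pair_distances(frame, topo, seg)) - template.dmin_target) / 0.01)
    # steric guards: the closest contact must be the helical-segment
    # interface (no pair anywhere undercuts it), and the flexible terminal
    # tails stay out of the interface entirely
    all_res = range(1, topo.n_residues_per_monomer + 1)
    floor = template.dmin_target - 0.015
    clash = max(0.0, floor - mind(_pair_distances(frame, topo, all_res)))
    res.append(clash / 0.002)
    tails = (1, 2, 3, 4, 5, 6, 7, 34, 35)
    idx_t = topo.bead_indices(tails)
    idx_all = topo.bead_indices(all_res)
    for pa, pb in ((frame.coords_a[idx_t], frame.coords_b[idx_all]),
                   (frame.coords_a[idx_all], frame.coords_b[idx_t])):
        dist = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
        tail_gap = max(0.0, 0.70 - (dist.min() if hard else _softmin(dist)))
        res.append(tail_gap / 0.004)
    res.extend(sep_res)
    # soft regularization pins the unconstrained pose directions
    res.extend(0.05 * (np.asarray(x) - x0))
    return np.asarray(res, dtype=float)


_TEMPLATE_CACHE: dict = {}

# Placements solved by ``_solve_template_params`` for the default templates
# and helix geometry, frozen so that importing processes need not repeat the
# (deterministic, ~30 s) least-squares fit.  A test re-validates these
# against the descriptor targets.
_FROZEN_PARAMS = {
    "parallel": (
        0.11169112464217912, -0.014329260136687881, -0.15180835973154883,
        -0.02334310843788201, 0.7348330035928781, -2.331169700289675,
        -0.014023039468015766, 2.9707005087658573, 1.2117888011311693,
        0.02696604886891058, 2.617608022314105, 1.1862696565433724,
        1.2076601634219029, 0.24591719304446227),
    "inverted-V": (
        -0.396484261420182, 0.1818311377715961, 0.21025646290357547,
        0.023675717995845287, -1.0559158270006404, 1.3474252856653741,
        -0.1519249893857323, -3.5664289587168536, -0.40064649107280764,
        -0.09582312692993758, -4.150989083418004, 0.4029570859820676,
        1.4652535518025522, 0.2156310118517523),
    "V": (
        0.18924087183615337, 0.133146461648361, -0.19076055413824897,
        -0.13582133845560018, -1.0998316318139756, 2.0027429390353912,
        0.026225535345818896, 4.9088883130292595, 1.2602694042059737,
        0.08319183221123079, -0.1658392259598394, 1.361104186014346,
        1.583840640160995, -0.021508800140335804),
}


def solve_template(template: TopologyTemplate, topo: DimerTopology | None = None,
                   helix: HelixParams = DEFAULT_HELIX,
                   avoid_cvs=()) -> TemplateSolution:
    """Canonical placement of a template (frozen for the defaults, otherwise
    solved once, deterministically).

    ``avoid_cvs`` lists (phi1, phi2) pairs the solution's own interface
    dihedrals must stay clear of; the default templates are solved
    sequentially this way so their basins never overlap in CV space.
    """
    topo = topo or DimerTopology()
    key = (template, topo.n_residues_per_monomer, helix)
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    if (helix == DEFAULT_HELIX and topo.n_residues_per_monomer == 35
            and template in DEFAULT_TEMPLATES
            and template.name in _FROZEN_PARAMS):
        sol = _finish_solution(np.array(_FROZEN_PARAMS[template.name]),
                               template, topo, helix)
        _TEMPLATE_CACHE[key] = sol
        return sol
    if not avoid_cvs and template in DEFAULT_TEMPLATES:
        idx = DEFAULT_TEMPLATES.index(template)
        avoid_cvs = tuple(
            solve_template(t, topo, helix).canonical_cvs[:2]
            for t in DEFAULT_TEMPLATES[:idx])

    twist = np.radians(helix.twist_deg)
    # spin guesses put the interface residue's face on the partner-facing side
    s1 = wrap_angle(-twist * template.interface_residue)
    s2 = wrap_angle(np.pi - twist * template.interface_residue)
    psi = np.radians(template.crossing_angle_target)
    op = template.opening
    # split the crossing angle between an in-plane opening (tilt_y) and an
    # out-of-plane skew (tilt_x); both get refined
    skew = np.sqrt(max(psi ** 2 / 4 - op ** 2, 1e-4))
    zc = (26.0 - helix.center_residue) * helix.rise
    # bend deltas are body-relative; initial absolute directions point away
    # from the partner (pi for monomer 1 at the origin, 0 for monomer 2)
    x0 = np.array([skew, op, -skew, -op, s1, s2,
                   0.02, np.pi - s1, zc, 0.02, -s2, zc, 1.15, 0.0])
    sol = least_squares(
        _descriptor_residuals, x0,
        args=(template, topo, helix, x0, False, avoid_cvs),
        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=4000)
    # polish against the hard minimum (active pair is stable near the optimum)
    sol = least_squares(
        _descriptor_residuals, sol.x,
        args=(template, topo, helix, sol.x, True, avoid_cvs),
        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=2000)
    solution = _finish_solution(sol.x, template, topo, helix)
    _TEMPLATE_CACHE[key] = solution
    return solution


def _finish_solution(x: np.ndarray, template: TopologyTemplate,
                     topo: DimerTopology, helix: HelixParams) -> TemplateSolution:
    pose = _pose_from_params(x, template)
    frame = pose_frame(pose, topo, helix)
    sep_vec = np.asarray(pose.monomer2.position) - np.asarray(pose.monomer1.position)
    d0 = float(np.linalg.norm(sep_vec))
    phi1, phi2 = compute_phi1_phi2(frame, topo)
    achieved = {
        "region_nterm": min_distance(frame, topo, topo.groups["region_nterm"]),
        "region_mid": min_distance(frame, topo, topo.groups["region_mid"]),
        "region_cterm": min_distance(frame, topo, topo.groups["region_cterm"]),
        "crossing_angle_deg": crossing_angle(frame, topo),
        "d_min": min_distance(frame, topo),
        "d_com": com_distance(frame, topo),
    }
    return TemplateSolution(
        template=template, pose=pose,
        separation_dir=tuple(sep_vec / d0),
        canonical_cvs=(float(phi1), float(phi2), d0),
        achieved=achieved)


# ---------------------------------------------------------------------------
# CV inverse kinematics
# ---------------------------------------------------------------------------

_ANCHOR_MODEL_CACHE: dict = {}


def _anchor_model(placement: MonomerPlacement, topo: DimerTopology,
                  helix: HelixParams):
    """Closed-form anchor kinematics: each anchor-group COM (centered on the
    monomer COM, before tilt) is (Re(E e^{i s}), Im(E e^{i s}), dz) for a
    complex amplitude E and height dz independent of the spin s."""
    key = (placement.bend_kappa, placement.bend_delta, placement.bend_zc,
           placement.tilt_x, placement.tilt_y,
           topo.n_residues_per_monomer, helix)
    if key in _ANCHOR_MODEL_CACHE:
        return _ANCHOR_MODEL_CACHE[key]
    beads0 = _raw_helix(topo, helix, 0.0)  # spin 0, no bend
    xy = beads0[:, 0] + 1j * beads0[:, 1]
    z = beads0[:, 2]
    q = (z - placement.bend_zc) ** 2
    bend = placement.bend_kappa * np.exp(1j * placement.bend_delta)

    def group_model(idx):
        amp = xy[idx].mean() + bend * q[idx].mean()
        return amp, z[idx].mean()

    body_amp, body_z = group_model(np.arange(len(z)))
    amps, dzs = [], []
    for g in ("anchor_upper", "anchor_middle", "anchor_lower"):
        idx = topo.bead_indices(topo.groups[g])
        a, zz = group_model(idx)
        amps.append(a - body_amp)
        dzs.append(zz - body_z)
    model = (np.array(amps), np.array(dzs),
             _tilt_matrix(placement.tilt_x, placement.tilt_y))
    _ANCHOR_MODEL_CACHE[key] = model
    return model


def _anchor_points_batch(placement: MonomerPlacement, topo: DimerTopology,
                         helix: HelixParams, spins: np.ndarray,
                         positions: np.ndarray) -> np.ndarray:
    """Anchor-group COMs (N, 3 groups, 3) as a function of spin."""
    amps, dzs, rot = _anchor_model(placement, topo, helix)
    e = np.exp(1j * np.asarray(spins, dtype=float))[:, None]  # (N, 1)
    rotated = amps[None, :] * e                               # (N, 3)
    pts = np.empty((len(spins), 3, 3))
    pts[:, :, 0] = rotated.real
    pts[:, :, 1] = rotated.imag
    pts[:, :, 2] = dzs[None, :]
    return pts @ rot.T + positions[:, None, :]


def _dihedral_batch(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    y = (np.cross(n1, n2) * b2n).sum(-1)
    x = (n1 * n2).sum(-1)
    return wrap_angle(np.arctan2(y, x))


def _phis_batch(solution: TemplateSolution, topo, helix, s1, s2, positions2):
    n = len(s1)
    pos1 = np.zeros((n, 3))
    a1 = _anchor_points_batch(solution.pose.monomer1, topo, helix, s1, pos1)
    a2 = _anchor_points_batch(solution.pose.monomer2, topo, helix, s2, positions2)
    phi1 = _dihedral_batch(a1[:, 0], a1[:, 1], a1[:, 2], a2[:, 2])
    phi2 = _dihedral_batch(a2[:, 0], a2[:, 1], a2[:, 2], a1[:, 2])
    return phi1, phi2


def solve_spins_batch(solution: TemplateSolution, phi1, phi2, d,
                      topo: DimerTopology | None = None,
                      helix: HelixParams = DEFAULT_HELIX,
                      tol: float = 1e-9, max_iter: int = 60):
    """Solve the spins (s1, s2) realizing (phi1, phi2) at separations d.

    2x2 damped Newton with numerical Jacobian, vectorized over frames.
    Raises if any frame fails to converge.
    """
    topo = topo or DimerTopology()
    phi1 = np.atleast_1d(np.asarray(phi1, dtype=float))
    phi2 = np.atleast_1d(np.asarray(phi2, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(d <= 0):
        raise ValueError("infeasible pose: COM distance d must be positive")
    u = np.asarray(solution.separation_dir)
    pos2 = d[:, None] * u[None, :]
    # each dihedral is a winding-1 (possibly very non-uniform) circle map of
    # its own monomer's spin with weak cross-coupling: alternate robust
    # bracketed scalar solves, then polish the pair with Newton
    s1 = np.full_like(phi1, solution.pose.monomer1.spin)
    s2 = np.full_like(phi2, solution.pose.monomer2.spin)
    for _ in range(4):
        s1 = _circle_solve(
            lambda s: _phis_batch(solution, topo, helix, s, s2, pos2)[0], phi1)
        s2 = _circle_solve(
            lambda s: _phis_batch(solution, topo, helix, s1, s, pos2)[1], phi2)
    s1, s2 = _newton_spins(solution, topo, helix, phi1, phi2, pos2, s1, s2,
                           tol, max_iter)
    return s1, s2, pos2


def _circle_solve(func, target, n_scan: int = 48, n_bisect: int = 40):
    """Vectorized root solve of wrap(func(s) - target) = 0 over s in [-pi, pi).

    ``func`` maps a spin vector to an angle vector (a degree-1 circle map per
    frame). A coarse scan finds a genuine sign-change bracket (excluding the
    2*pi wrap jump), then bisection refines it.
    """
    target = np.asarray(target, dtype=float)
    n = len(target)
    scan = np.linspace(-np.pi, np.pi, n_scan + 1)
    h = np.empty((n_scan + 1, n))
    for k, s in enumerate(scan):
        h[k] = wrap_angle(func(np.full(n, s)) - target)
    hlo, hhi = h[:-1], h[1:]
    sign_change = (hlo <= 0) & (hhi > 0) | (hlo >= 0) & (hhi < 0)
    genuine = sign_change & (np.abs(hlo) < 2.6) & (np.abs(hhi) < 2.6)
    span = np.abs(hlo) + np.abs(hhi)
    score = np.where(genuine, span, np.inf)
    pick = np.argmin(score, axis=0)
    if np.any(~np.isfinite(score[pick, np.arange(n)])):
        # no clean bracket (target sits in an extremely fast segment):
        # fall back to the scan point with the smallest residual
        pick = np.argmin(np.abs(h[:-1]), axis=0)
    lo = scan[pick]
    hi = scan[pick + 1]
    flo = h[pick, np.arange(n)]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        fm = wrap_angle(func(mid) - target)
        left = (flo <= 0) == (fm <= 0)
        lo = np.where(left, mid, lo)
        flo = np.where(left, fm, flo)
        hi = np.where(left, hi, mid)
    return 0.5 * (lo + hi)


def _newton_spins(solution, topo, helix, phi1, phi2, pos2, s1, s2, tol, max_iter):
    eps = 1e-6
    err = np.full(len(phi1), np.inf)
    for _ in range(max_iter):
        f1, f2 = _phis_batch(solution, topo, helix, s1, s2, pos2)
        r1 = wrap_angle(f1 - phi1)
        r2 = wrap_angle(f2 - phi2)
        err = np.maximum(np.abs(r1), np.abs(r2))
        if err.max() < tol:
            break
        g1a, g2a = _phis_batch(solution, topo, helix, s1 + eps, s2, pos2)
        g1b, g2b = _phis_batch(solution, topo, helix, s1, s2 + eps, pos2)
        j11 = wrap_angle(g1a - f1) / eps
        j21 = wrap_angle(g2a - f2) / eps
        j12 = wrap_angle(g1b - f1) / eps
        j22 = wrap_angle(g2b - f2) / eps
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-12, np.where(det < 0, -1e-12, 1e-12), det)
        ds1 = (j22 * r1 - j12 * r2) / det
        ds2 = (j11 * r2 - j21 * r1) / det
        step = np.sqrt(ds1 ** 2 + ds2 ** 2)
        damp = np.minimum(1.0, 0.4 / np.maximum(step, 1e-12))
        s1 = s1 - damp * ds1
        s2 = s2 - damp * ds2
    if err.max() >= tol:
        bad = int(np.sum(err >= tol))
        raise RuntimeError(
            f"spin solve failed for {bad} frame(s); max residual {err.max():.2e} rad")
    return s1, s2


def pose_from_cvs(phi1: float, phi2: float, d: float,
                  template: TopologyTemplate,
                  topo: DimerTopology | None = None,
                  helix: HelixParams = DEFAULT_HELIX) -> ToyPose:
    """A pose whose computed (phi1, phi2, d) match the inputs to < 1e-6."""
    topo = topo or DimerTopology()
    solution = solve_template(template, topo, helix)
    s1, s2, pos2 = solve_spins_batch(solution, phi1, phi2, d, topo, helix)
    m1 = replace(solution.pose.monomer1, spin=float(s1[0]), position=(0.0, 0.0, 0.0))
    m2 = replace(solution.pose.monomer2, spin=float(s2[0]), position=tuple(pos2[0]))
    return ToyPose(m1, m2, template.name)


def frames_from_cvs(phi1, phi2, d, template: TopologyTemplate,
                    topo: DimerTopology | None = None,
                    helix: HelixParams = DEFAULT_HELIX):
    """Batched bead reconstruction: coords (N, 2, n_beads, 3) from CV arrays."""
    topo = topo or DimerTopology()
    solution = solve_template(template, topo, helix)
    s1, s2, pos2 = solve_spins_batch(solution, phi1, phi2, d, topo, helix)
    pos1 = np.zeros_like(pos2)
    c1 = _build_monomers_batch(solution.pose.monomer1, topo, helix, s1, pos1)
    c2 = _build_monomers_batch(solution.pose.monomer2, topo, helix, s2, pos2)
    return np.stack([c1, c2], axis=1)
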