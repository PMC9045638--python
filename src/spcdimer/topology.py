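"""Dimer bookkeeping and geometric collective variables.

The system is a homodimer of two 35-residue coarse-bead helices in a membrane
plane. Three reaction coordinates drive the biased sampling:

* ``phi1``: the dihedral angle A-B-C-C', where A, B, C are the centers of mass
  of the upper (residues 31-33), middle (17-19) and lower (8-10) anchor groups
  of monomer 1 and C' is the lower anchor of monomer 2;
* ``phi2``: the mirrored dihedral A'-B'-C'-C of monomer 2;
* ``d``: the distance between the whole-monomer centers of mass.

phi1/phi2 measure which helix face points at the partner (the interface
azimuth), d measures association.  Downstream descriptors (d_min, region
distances, crossing angle, contact maps) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DimerTopology",
    "FrameGeometry",
    "CVRecord",
    "center_of_mass",
    "dihedral_angle",
    "compute_phi1_phi2",
    "com_distance",
    "min_distance",
    "is_bound",
    "crossing_angle",
    "residue_contact_matrix",
    "wrap_angle",
]

#: Residue names the system defines (1-letter), by 1-based residue index.
#: Indices without an entry are carried as index-only labels.
KNOWN_RESIDUE_NAMES = {
    2: "R", 4: "P", 7: "P", 8: "V", 9: "N", 10: "L", 14: "L",
    17: "V", 18: "V", 19: "V", 21: "V", 22: "L", 25: "V", 26: "V",
    29: "G", 30: "A", 31: "L", 32: "L", 33: "M", 34: "G",
}

#: Bound-state criterion on the minimum inter-monomer bead distance (nm).
BOUND_CUTOFF_NM = 0.60

#: Residue-residue contact criterion, 6 Angstrom between any bead pair (nm).
CONTACT_CUTOFF_NM = 0.60


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class DimerTopology:
    """Residue/bead bookkeeping shared by the two (identical) monomers.

    The default layout has one backbone bead and one side bead per residue;
    ``bead_index_map`` maps a 1-based residue index to the bead indices within
    one monomer's coordinate array.
    """

    n_residues_per_monomer: int = 35
    beads_per_residue: int = 2
    groups: dict = field(default_factory=dict)
    residue_names: dict = field(default_factory=lambda: dict(KNOWN_RESIDUE_NAMES))

    def __post_init__(self):
        if not self.groups:
            object.__setattr__(self, "groups", {
                "anchor_upper": (31, 32, 33),    # A / A'
                "anchor_middle": (17, 18, 19),   # B / B'
                "anchor_lower": (8, 9, 10),      # C / C'
                "region_nterm": (8, 9, 10),
                "region_mid": (17, 18, 19),
                "region_cterm": (31, 32, 33),
                "helical_segment": tuple(range(9, 34)),
                "axis_head": (8, 9, 10, 11),
                "axis_tail": (30, 31, 32, 33),
            })
        n = self.n_residues_per_monomer
        for name, residues in self.groups.items():
            bad = [r for r in residues if not (1 <= r <= n)]
            if bad:
                raise ValueError(f"group {name!r} has residues {bad} outside [1, {n}]")

    @property
    def n_beads(self) -> int:
        return self.n_residues_per_monomer * self.beads_per_residue

    def bead_index_map(self, residue: int) -> np.ndarray:
        """Bead indices (within one monomer) of a 1-based residue index."""
        if not 1 <= residue <= self.n_residues_per_monomer:
            raise ValueError(f"residue {residue} outside [1, {self.n_residues_per_monomer}]")
        base = (residue - 1) * self.beads_per_residue
        return np.arange(base, base + self.beads_per_residue)

    def bead_indices(self, residues) -> np.ndarray:
        """Bead indices of a set of residues, sorted."""
        idx = np.concatenate([self.bead_index_map(r) for r in residues])
        return np.sort(idx)

    def bead_tag(self, bead_index: int) -> str:
        """'BB' for the backbone bead of a residue, 'SC' otherwise."""
        return "BB" if bead_index % self.beads_per_residue == 0 else "SC"

    def backbone_bead_indices(self, residues) -> np.ndarray:
        return np.array([(r - 1) * self.beads_per_residue for r in residues])

    def residue_label(self, residue: int) -> str:
        """Name+index for residues with a known name, index-only otherwise."""
        name = self.residue_names.get(residue)
        return f"{name}{residue}" if name else f"{residue}"


@dataclass
class FrameGeometry:
    """Bead coordinates of one frame: two (n_beads, 3) arrays in nm."""

    coords_a: np.ndarray
    coords_b: np.ndarray
    box: np.ndarray | None = None  # orthorhombic box lengths (3,) nm, or None

    def __post_init__(self):
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        if self.coords_a.shape != self.coords_b.shape or self.coords_a.shape[-1] != 3:
            raise ValueError("monomer coordinate arrays must both be (n_beads, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    def validate(self, topo: DimerTopology) -> None:
        if self.coords_a.shape[0] != topo.n_beads:
            raise ValueError(
                f"frame has {self.coords_a.shape[0]} beads per monomer, "
                f"topology expects {topo.n_beads}"
            )

    def swapped(self) -> "FrameGeometry":
        """The same frame with monomer labels exchanged."""
        return FrameGeometry(self.coords_b.copy(), self.coords_a.copy(), self.box)


@dataclass
class CVRecord:
    """One frame's collective variables: time (ps), angles (rad), d (nm)."""

    time: float
    phi1: float
    phi2: float
    d: float
    d_min: float | None = None

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("d must be non-negative")
        self.phi1 = wrap_angle(self.phi1)
        self.phi2 = wrap_angle(self.phi2)


# ---------------------------------------------------------------------------
# geometric operations
# ---------------------------------------------------------------------------

def _minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def center_of_mass(coords: np.ndarray, masses=None) -> np.ndarray:
    """Mass-weighted mean position; arithmetic mean for uniform masses."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty selection: cannot compute a center of mass")
    coords = coords.reshape(-1, 3)
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != coords.shape[0]:
        raise ValueError("one mass per bead required")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (coords * masses[:, None]).sum(axis=0) / total


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion of plane (p1,p2,p3) vs (p2,p3,p4) about p2->p3, in (-pi, pi].

    Right-hand convention: looking along p2->p3, a positive angle rotates the
    p1 side counterclockwise onto the p4 side.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise ValueError("degenerate dihedral: p2 and p3 coincide")
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral: three consecutive points are collinear")
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    x = np.dot(n1, n2)
    return wrap_angle(np.arctan2(y, x))


def _anchor_points(coords: np.ndarray, topo: DimerTopology):
    """COMs of the upper/middle/lower anchor groups of one monomer."""
    a = center_of_mass(coords[topo.bead_indices(topo.groups["anchor_upper"])])
    b = center_of_mass(coords[topo.bead_indices(topo.groups["anchor_middle"])])
    c = center_of_mass(coords[topo.bead_indices(topo.groups["anchor_lower"])])
    return a, b, c


def compute_phi1_phi2(frame: FrameGeometry, topo: DimerTopology):
    """The two interface dihedrals (phi1, phi2) of a frame, radians."""
    frame.validate(topo)
    a1, b1, c1 = _anchor_points(frame.coords_a, topo)
    a2, b2, c2 = _anchor_points(frame.coords_b, topo)
    phi1 = dihedral_angle(a1, b1, c1, c2)
    phi2 = dihedral_angle(a2, b2, c2, c1)
    return phi1, phi2


def com_distance(frame: FrameGeometry, topo: DimerTopology, masses=None) -> float:
    """Distance between whole-monomer centers of mass (minimum image if boxed)."""
    frame.validate(topo)
    g1 = center_of_mass(frame.coords_a, masses)
    g2 = center_of_mass(frame.coords_b, masses)
    return float(np.linalg.norm(_minimum_image(g2 - g1, frame.box)))


def min_distance(frame: FrameGeometry, topo: DimerTopology,
                 selection_a=None, selection_b=None) -> float:
    """Minimum bead-bead distance between residue selections of the two monomers.

    Defaults to the helical segment (residues 9-33) on both monomers, the
    selection used for the bound-state criterion.
    """
    frame.validate(topo)
    if selection_a is None:
        selection_a = topo.groups["helical_segment"]
    if selection_b is None:
        selection_b = selection_a
    if len(selection_a) == 0 or len(selection_b) == 0:
        raise ValueError("empty selection in min_distance")
    pa = frame.coords_a[topo.bead_indices(selection_a)]
    pb = frame.coords_b[topo.bead_indices(selection_b)]
    diff = _minimum_image(pa[:, None, :] - pb[None, :, :], frame.box)
    return float(np.sqrt((diff ** 2).sum(axis=-1)).min())


def is_bound(d_min: float, cutoff: float = BOUND_CUTOFF_NM) -> bool:
    """Bound-dimer criterion: d_min <= cutoff (0.60 nm by default)."""
    if d_min < 0:
        raise ValueError("d_min must be non-negative")
    return bool(d_min <= cutoff)


def _helix_axis(coords: np.ndarray, topo: DimerTopology) -> np.ndarray:
    """Axis vector: backbone COM of residues 8-11 -> backbone COM of 30-33."""
    head = center_of_mass(coords[topo.backbone_bead_indices(topo.groups["axis_head"])])
    tail = center_of_mass(coords[topo.backbone_bead_indices(topo.groups["axis_tail"])])
    return tail - head


def crossing_angle(frame: FrameGeometry, topo: DimerTopology) -> float:
    """Crossing angle Psi between the two helix axes, degrees in [0, 180].

    Both axes are oriented N->C; no handedness sign is attached.
    """
    frame.validate(topo)
    v1 = _helix_axis(frame.coords_a, topo)
    v2 = _helix_axis(frame.coords_b, topo)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length helix axis")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# batched variants operating on coordinate stacks (n_frames, 2, n_beads, 3);
# used by the reconstruction pipeline where per-frame calls would be too slow

def batch_min_distances(coords: np.ndarray, topo: DimerTopology,
                        selection=None, chunk: int = 512) -> np.ndarray:
    """Per-frame minimum inter-monomer bead distance over a residue selection."""
    if selection is None:
        selection = topo.groups["helical_segment"]
    idx = topo.bead_indices(selection)
    out = np.empty(len(coords))
    for i in range(0, len(coords), chunk):
        ca = coords[i:i + chunk, 0][:, idx]
        cb = coords[i:i + chunk, 1][:, idx]
        diff = ca[:, :, None, :] - cb[:, None, :, :]
        out[i:i + chunk] = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
    return out


def batch_crossing_angles(coords: np.ndarray, topo: DimerTopology) -> np.ndarray:
    """Per-frame crossing angle (degrees) for a coordinate stack."""
    ih = topo.backbone_bead_indices(topo.groups["axis_head"])
    it = topo.backbone_bead_indices(topo.groups["axis_tail"])
    v1 = coords[:, 0][:, it].mean(1) - coords[:, 0][:, ih].mean(1)
    v2 = coords[:, 1][:, it].mean(1) - coords[:, 1][:, ih].mean(1)
    c = (v1 * v2).sum(-1) / (np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def batch_contact_matrices(coords: np.ndarray, topo: DimerTopology,
                           cutoff: float = CONTACT_CUTOFF_NM,
                           chunk: int = 256) -> np.ndarray:
    """Per-frame boolean residue contact matrices (n_frames, n_res, n_res)."""
    n, k = topo.n_residues_per_monomer, topo.beads_per_residue
    out = np.empty((len(coords), n, n), dtype=bool)
    for i in range(0, len(coords), chunk):
        ca = coords[i:i + chunk, 0].reshape(-1, n, k, 3)
        cb = coords[i:i + chunk, 1].reshape(-1, n, k, 3)
        diff = ca[:, :, None, :, None, :] - cb[:, None, :, None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        out[i:i + chunk] = dist.min(axis=(3, 4)) < cutoff
    return out


def residue_contact_matrix(frame: FrameGeometry, topo: DimerTopology,
                           cutoff: float = CONTACT_CUTOFF_NM) -> np.ndarray:
    """Boolean matrix: (i, j) true iff any bead of residue i of monomer 1 lies
    within ``cutoff`` (strictly closer) of any bead of residue j of monomer 2."""
    frame.validate(topo)
    n = topo.n_residues_per_monomer
    k = topo.beads_per_residue
    pa = frame.coords_a.reshape(n, k, 3)
    pb = frame.coords_b.reshape(n, k, 3)
    diff = _minimum_image(pa[:, None, :, None, :] - pb[None, :, None, :, :], frame.box)
    dist = np.sqrt((diff ** 2).sum(axis=-1))  # (n, n, k, k)
    return dist.min(axis=(2, 3)) < cutoff
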