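"""Static and time-dependent bias potentials of the sampling campaign.

Each umbrella window restrains the two interface dihedrals harmonically
(k = 500 kJ mol^-1 rad^-2 by default, centers on a 10 degree grid).  Within
every window the inter-monomer distance d is sampled by well-tempered
metadynamics (bias factor gamma = 50, hill width 0.05 nm, initial height
0.1 kJ/mol) accumulated on a grid over [0.5, 4.5] nm with 0.01 nm spacing,
plus a half-harmonic wall at 5 nm keeping d bounded.

For reweighting, the per-window static bias is the umbrella energy plus the
*final* metadynamics grid plus the wall (final-bias approximation; with
gamma = 50 the un-flattened residual F/gamma is at the 2% level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .topology import wrap_angle

__all__ = [
    "WindowSpec",
    "HillsLog",
    "BiasGrid",
    "WallSpec",
    "build_window_grid",
    "umbrella_energy",
    "wt_hill_height",
    "deposit_hill",
    "wall_energy",
    "total_static_bias",
]

log = logging.getLogger(__name__)

DEFAULT_K_PHI = 500.0      # kJ mol^-1 rad^-2
DEFAULT_GAMMA = 50.0
DEFAULT_SIGMA = 0.05       # nm
DEFAULT_H0 = 0.1           # kJ/mol
DEFAULT_HILL_STRIDE_PS = 500.0


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: restraint centers (rad) and force constant."""

    window_id: int
    phi1_center: float
    phi2_center: float
    k_phi: float = DEFAULT_K_PHI

    def __post_init__(self):
        if self.k_phi <= 0:
            raise ValueError("k_phi must be positive")
        object.__setattr__(self, "phi1_center", wrap_angle(self.phi1_center))
        object.__setattr__(self, "phi2_center", wrap_angle(self.phi2_center))


@dataclass
class HillsLog:
    """Ordered metadynamics hill records for one window."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigmas: np.ndarray = field(default_factory=lambda: np.empty(0))
    heights: np.ndarray = field(default_factory=lambda: np.empty(0))
    bias_factor: float = DEFAULT_GAMMA

    def append(self, time, center, sigma, height):
        self.times = np.append(self.times, time)
        self.centers = np.append(self.centers, center)
        self.sigmas = np.append(self.sigmas, sigma)
        self.heights = np.append(self.heights, height)

    def validate(self, h0: float = DEFAULT_H0) -> None:
        if len(self.times) == 0:
            return
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("hill deposit times must be strictly increasing")
        if np.any(self.sigmas <= 0):
            raise ValueError("hill widths must be positive")
        if np.any(self.heights <= 0) or np.any(self.heights > h0 + 1e-12):
            raise ValueError("hill heights must lie in (0, h0]")

    def __len__(self):
        return len(self.times)


class BiasGrid:
    """Accumulated metadynamics bias V(d) on a regular grid over [d_lo, d_hi]."""

    def __init__(self, d_lo: float = 0.5, d_hi: float = 4.5, spacing: float = 0.01):
        self.d_lo = float(d_lo)
        self.d_hi = float(d_hi)
        self.spacing = float(spacing)
        n = int(round((d_hi - d_lo) / spacing)) + 1
        self.nodes = d_lo + spacing * np.arange(n)
        self.values = np.zeros(n)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def value_at(self, d):
        """Bias at d by linear interpolation, clamped to end nodes outside."""
        return np.interp(np.asarray(d, dtype=float), self.nodes, self.values)

    def copy(self) -> "BiasGrid":
        g = BiasGrid(self.d_lo, self.d_hi, self.spacing)
        g.values = self.values.copy()
        return g


def build_window_grid(spacing_deg: float = 10.0, k_phi: float = DEFAULT_K_PHI):
    """All umbrella windows: Cartesian product of dihedral centers.

    Centers cover the full period in ``spacing_deg`` steps, giving
    (360/spacing)^2 windows (1296 at the default 10 degrees).
    """
    if not float(360.0 / spacing_deg).is_integer():
        raise ValueError(f"{spacing_deg} deg does not divide 360 deg")
    n = int(360.0 / spacing_deg)
    centers = np.radians(-180.0 + spacing_deg * (np.arange(n) + 1))  # (-pi, pi]
    windows = []
    wid = 0
    for c1 in centers:
        for c2 in centers:
            windows.append(WindowSpec(wid, c1, c2, k_phi))
            wid += 1
    return windows


def umbrella_energy(phi1, phi2, window: WindowSpec):
    """Harmonic dihedral restraint energy with periodic minimum-difference."""
    d1 = wrap_angle(np.asarray(phi1, dtype=float) - window.phi1_center)
    d2 = wrap_angle(np.asarray(phi2, dtype=float) - window.phi2_center)
    return 0.5 * window.k_phi * (np.square(d1) + np.square(d2))


def wt_hill_height(v_current, h0: float = DEFAULT_H0,
                   gamma: float = DEFAULT_GAMMA, temperature: float = 310.0):
    """Well-tempered deposit height h0 * exp(-V/(kB*(gamma-1)*T))."""
    if gamma <= 1:
        raise ValueError("well-tempered bias factor gamma must exceed 1")
    v_current = np.asarray(v_current, dtype=float)
    if np.any(v_current < 0):
        raise ValueError("accumulated bias must be non-negative")
    kb_dt = KB * (gamma - 1.0) * temperature
    out = h0 * np.exp(-v_current / kb_dt)
    return float(out) if out.ndim == 0 else out


def deposit_hill(grid: BiasGrid, center: float, sigma: float, height: float) -> BiasGrid:
    """Add a Gaussian hill to the grid in place (and return the grid).

    Hills centered outside the grid interval are skipped with a warning: no
    bias is ever added outside the stated deposition interval.
    """
    if sigma <= 0:
        raise ValueError("hill width must be positive")
    if not (grid.d_lo <= center <= grid.d_hi):
        log.warning("hill center %.3f nm outside [%.2f, %.2f] nm: skipped",
                    center, grid.d_lo, grid.d_hi)
        return grid
    grid.values += height * np.exp(-((grid.nodes - center) ** 2) / (2.0 * sigma ** 2))
    return grid


@dataclass(frozen=True)
class WallSpec:
    """One-sided harmonic wall acting for d > location."""

    location: float = 5.0          # nm
    k_wall: float = 500.0          # kJ mol^-1 nm^-2

    def __post_init__(self):
        if self.k_wall < 0:
            raise ValueError("k_wall must be non-negative")


def wall_energy(d, wall: WallSpec):
    """0 for d <= wall.location, (k/2)(d - location)^2 beyond."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("d must be non-negative")
    excess = np.clip(d - wall.location, 0.0, None)
    out = 0.5 * wall.k_wall * excess ** 2
    return float(out) if out.ndim == 0 else out


def total_static_bias(phi1, phi2, d, window: WindowSpec,
                      final_grid: BiasGrid, wall: WallSpec):
    """Umbrella + final metadynamics grid (linear interp) + wall, kJ/mol."""
    return umbrella_energy(phi1, phi2, window) + final_grid.value_at(d) + wall_energy(d, wall)
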