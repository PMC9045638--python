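"""Binless multistate reweighting of the biased windows.

Every window w sampled the same underlying surface under a static bias
B_w(x) = umbrella_w(phi1, phi2) + V_w(d) + wall(d), where V_w is the final
accumulated metadynamics grid of that window (final-bias approximation; the
well-tempered bias factor of 50 leaves only a ~2% un-flattened residual).
The self-consistent multistate equations

    w_i  propto  [ sum_w N_w exp((f_w - B_w(x_i)) / kT) ]^-1
    f_w  =  -kT ln sum_i w_i exp(-B_w(x_i) / kT)

yield one normalized weight per frame; all free-energy profiles and
averages are weighted estimates over this pooled ensemble.  The fixed point
is found by minimizing the standard convex multistate objective (L-BFGS)
and polished by direct iteration to max|delta f| < 1e-8 kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bias import total_static_bias
from .constants import DEFAULT_TEMPERATURE, kt

__all__ = [
    "WeightedEnsemble", "PMFProfile", "bias_matrix",
    "solve_window_offsets", "ensemble_from_runs",
    "project_pmf", "free_energy_difference", "conditional_region_profile",
]


@dataclass
class WeightedEnsemble:
    """Frames pooled over windows with normalized statistical weights."""

    window_ids: np.ndarray
    frame_indices: np.ndarray
    weights: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    provenance: str = ""
    total_weight: float = 1.0    # weight share before any sub-selection

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValueError(f"weights must sum to 1 (got {s!r})")

    def __len__(self):
        return len(self.weights)

    @property
    def kT(self) -> float:
        return kt(self.temperature)

    def select(self, mask: np.ndarray, provenance: str = "") -> "WeightedEnsemble":
        """Sub-ensemble with renormalized weights; the original share of the
        selection is recorded in ``total_weight``."""
        share = float(self.weights[mask].sum())
        if share <= 0:
            raise ValueError("selection has zero weight")
        return WeightedEnsemble(
            self.window_ids[mask], self.frame_indices[mask],
            self.weights[mask] / share, self.temperature,
            provenance or self.provenance, self.total_weight * share)


@dataclass
class PMFProfile:
    """A binned free-energy profile; empty bins are NaN and flagged."""

    cv_name: str
    bin_edges: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    reference: str = "plateau"
    occupied: np.ndarray = field(default=None)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bias_matrix(runs, kT: float) -> np.ndarray:
    """B[i, w]: static bias of window w evaluated on every pooled frame i.

    ``runs`` carry per-frame (phi1, phi2, d) plus each window's final grid;
    frames are pooled in window order.
    """
    phi1 = np.concatenate([r.phi1 for r in runs])
    phi2 = np.concatenate([r.phi2 for r in runs])
    d = np.concatenate([r.d for r in runs])
    n = len(phi1)
    B = np.empty((n, len(runs)))
    from .bias import WallSpec  # wall identical across windows
    wall = WallSpec()
    for j, r in enumerate(runs):
        B[:, j] = total_static_bias(phi1, phi2, d, r.window, r.grid, wall)
    return B


def _mbar_objective(g, u, log_n):
    """Convex multistate objective and gradient in reduced units."""
    # u: (n_frames, n_windows) reduced biases; g: window free energies / kT
    a = log_n[None, :] + g[None, :] - u
    lse = logsumexp(a, axis=1)
    n_tot = np.exp(log_n).sum()
    f = lse.sum() / n_tot - (np.exp(log_n) * g).sum() / n_tot
    p = np.exp(a - lse[:, None])
    grad = p.sum(axis=0) / n_tot - np.exp(log_n) / n_tot
    return f, grad


def _newton_offsets(g, u, log_n, max_iter=200):
    """Damped Newton on the convex multistate objective; the gauge freedom
    (a constant shift of g) is removed by pinning g[0]."""
    n, W = u.shape
    n_tot = np.exp(log_n).sum()
    f_cur, grad = _mbar_objective(g, u, log_n)
    for _ in range(max_iter):
        if np.abs(grad).max() < 1e-13:
            break
        a = log_n[None, :] + g[None, :] - u
        lse = logsumexp(a, axis=1)
        p = np.exp(a - lse[:, None])
        h = (np.diag(p.sum(axis=0)) - p.T @ p) / n_tot
        try:
            step = np.zeros(W)
            step[1:] = np.linalg.solve(h[1:, 1:] + 1e-12 * np.eye(W - 1),
                                       -grad[1:])
        except np.linalg.LinAlgError:
            step = -grad
        scale = 1.0
        for _bt in range(30):
            f_new, grad_new = _mbar_objective(g + scale * step, u, log_n)
            if f_new <= f_cur + 1e-15:
                g = g + scale * step
                f_cur, grad = f_new, grad_new
                break
            scale *= 0.5
        else:
            break
    return g


def solve_window_offsets(u: np.ndarray, counts: np.ndarray,
                         tol: float = 1e-8, max_iter: int = 2000,
                         g0: np.ndarray | None = None):
    """Solve the self-consistent equations for reduced biases ``u`` (units of
    kT) and per-window frame counts.  Returns (offsets g in kT relative to
    window 0, normalized frame weights)."""
    n, W = u.shape
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("every window must contribute at least one frame")
    if n == 0:
        raise ValueError("no frames to reweight")
    log_n = np.log(counts)
    g = np.zeros(W) if g0 is None else np.asarray(g0, dtype=float).copy()
    if W > 1:
        g = _newton_offsets(g, u, log_n, max_iter)
    # direct-iteration polish certifies the stated fixed-point tolerance;
    # Newton has done the heavy lifting, so few sweeps are needed
    converged = W == 1
    for _round in range(6):
        if converged:
            break
        for _ in range(40):
            log_den = logsumexp(log_n[None, :] + g[None, :] - u, axis=1)
            g_new = -logsumexp(-u.T - log_den[None, :], axis=1)
            g_new = g_new - g_new[0]
            delta = np.abs(g_new - (g - g[0])).max()
            g = g_new
            if delta < tol:
                converged = True
                break
        if not converged:
            g = _newton_offsets(g, u, log_n, max_iter)
    if not converged:
        raise RuntimeError(
            f"window-offset iteration did not reach {tol} kT (residual {delta:.2e})")
    log_den = logsumexp(log_n[None, :] + g[None, :] - u, axis=1)
    logw = -log_den - logsumexp(-log_den)
    return g, np.exp(logw)


def ensemble_from_runs(runs, temperature: float = DEFAULT_TEMPERATURE,
                       equilibration: float = 0.1, subsample: int = 10,
                       window_factors=None, g0=None, bias=None):
    """Reweight a campaign's windows into one pooled ensemble.

    The first ``equilibration`` fraction of every window is discarded and the
    remainder strided by ``subsample``.  ``window_factors`` (one per window)
    rescale effective frame counts — the hook used by the Bayesian block
    bootstrap.  Returns (ensemble, offsets g, pooled frame views, bias matrix)
    so repeated calls can reuse the bias matrix.
    """
    kT = kt(temperature)
    views = []
    for r in runs:
        start = int(len(r.times) * equilibration)
        sl = slice(start, None, subsample)
        views.append(_RunView(r.window, r.times[sl], r.phi1[sl], r.phi2[sl],
                              r.d[sl], r.grid))
    counts = np.array([len(v.times) for v in views], dtype=float)
    if np.any(counts == 0):
        raise ValueError("a window has no frames after equilibration discard")
    if bias is None:
        bias = bias_matrix(views, kT)
    if window_factors is not None:
        counts = counts * np.asarray(window_factors, dtype=float)
    g, w = solve_window_offsets(bias / kT, counts, g0=g0)
    window_ids = np.concatenate(
        [np.full(len(v.times), v.window.window_id, dtype=int) for v in views])
    frame_indices = np.concatenate(
        [np.arange(len(v.times)) for v in views])
    ens = WeightedEnsemble(window_ids, frame_indices, w, temperature,
                           provenance="binless multistate reweighting, "
                                      "final-bias approximation")
    return ens, g, views, bias


@dataclass
class _RunView:
    window: object
    times: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    d: np.ndarray
    grid: object


def pooled_cvs(views):
    """Concatenated (phi1, phi2, d) arrays aligned with the pooled ensemble."""
    return (np.concatenate([v.phi1 for v in views]),
            np.concatenate([v.phi2 for v in views]),
            np.concatenate([v.d for v in views]))


def project_pmf(ensemble: WeightedEnsemble, cv_values, bins,
                cv_name: str = "cv", reference: str = "plateau",
                plateau_window=(2.0, 3.5), errors=None) -> PMFProfile:
    """F(bin) = -kT ln(sum of weights in bin / bin width), shifted so the
    mean over the dissociated plateau window (or the minimum) is zero."""
    cv_values = np.asarray(cv_values, dtype=float)
    if len(cv_values) != len(ensemble):
        raise ValueError("cv_values must align with the ensemble frames")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    edges = np.asarray(bins, dtype=float)
    hist, _ = np.histogram(cv_values, bins=edges, weights=ensemble.weights)
    occupied = hist > 0
    with np.errstate(divide="ignore"):
        values = -ensemble.kT * np.log(hist / np.diff(edges))
    values[~occupied] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    if reference == "plateau":
        sel = occupied & (centers >= plateau_window[0]) & (centers <= plateau_window[1])
        if not sel.any():
            raise ValueError("no occupied bins inside the plateau window")
        shift = values[sel].mean()
    elif reference == "min":
        shift = np.nanmin(values)
    elif reference == "none":
        shift = 0.0
    else:
        raise ValueError(f"unknown reference convention {reference!r}")
    return PMFProfile(cv_name, edges, values - shift, errors=errors,
                      reference=reference, occupied=occupied)


def free_energy_difference(ensemble: WeightedEnsemble, indicator_bound,
                           kT: float | None = None) -> float:
    """Delta F = -kT ln(W_bound / W_unbound); negative means bound favored."""
    indicator_bound = np.asarray(indicator_bound, dtype=bool)
    if len(indicator_bound) != len(ensemble):
        raise ValueError("indicator must align with the ensemble frames")
    kT = ensemble.kT if kT is None else kT
    wb = ensemble.weights[indicator_bound].sum()
    wu = ensemble.weights[~indicator_bound].sum()
    if wb <= 0 or wu <= 0:
        raise ValueError("both bound and unbound classes must carry weight "
                         "(untapped region)")
    return float(-kT * np.log(wb / wu))


def conditional_region_profile(ensemble: WeightedEnsemble, x, y, bins):
    """Weighted mean of y per bin of x; returns (centers, means, weight
    totals) with empty bins NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.asarray(bins, dtype=float)
    idx = np.digitize(x, edges) - 1
    nb = len(edges) - 1
    wsum = np.zeros(nb)
    wy = np.zeros(nb)
    valid = (idx >= 0) & (idx < nb)
    np.add.at(wsum, idx[valid], ensemble.weights[valid])
    np.add.at(wy, idx[valid], ensemble.weights[valid] * y[valid])
    with np.errstate(invalid="ignore"):
        means = np.where(wsum > 0, wy / np.maximum(wsum, 1e-300), np.nan)
    return 0.5 * (edges[:-1] + edges[1:]), means, wsum
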