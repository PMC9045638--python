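"""Bound-dimer selection, symmetry-aware clustering, and interface analysis.

Bound dimers (d_min <= 0.60 nm over the helical segment, residues 9-33) are
clustered by agglomerative clustering on the pairwise RMSD matrix, where the
RMSD of two frames is the minimum over the two monomer-label permutations of
the least-squares-superposed (Kabsch) RMSD of the helical-segment beads —
the two monomers of a homodimer are indistinguishable.  Per-cluster weighted
free energies, region-distance and crossing-angle distributions, residue
contact-probability maps and the interface-motif report follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .reweight import WeightedEnsemble
from .topology import (BOUND_CUTOFF_NM, CONTACT_CUTOFF_NM, DimerTopology,
                       batch_contact_matrices, batch_crossing_angles,
                       batch_min_distances)

__all__ = [
    "select_bound", "symmetric_rmsd", "symmetric_rmsd_matrix",
    "cluster_bound", "choose_n_clusters", "cluster_free_energies",
    "cluster_centroid", "topology_descriptors", "contact_probability_map",
    "motif_report", "ClusterReport", "ContactProbabilityMap",
]


def select_bound(ensemble: WeightedEnsemble, d_min, cutoff: float = BOUND_CUTOFF_NM,
                 strict: bool = False) -> WeightedEnsemble:
    """Sub-ensemble of bound dimers (d_min <= cutoff; ``strict`` uses <).

    Weights are renormalized; the original bound share is retained in
    ``total_weight``.  Raises if no frame is bound.
    """
    d_min = np.asarray(d_min, dtype=float)
    mask = d_min < cutoff if strict else d_min <= cutoff
    if not mask.any():
        raise ValueError("no bound dimers below the cutoff")
    return ensemble.select(mask, provenance="bound dimers"), mask


# ---------------------------------------------------------------------------
# monomer-swap-symmetric RMSD
# ---------------------------------------------------------------------------

def _segment_coords(coords, topo: DimerTopology, selection):
    """(n, 2m, 3) direct and (n, 2m, 3) monomer-swapped selected beads."""
    idx = topo.bead_indices(selection)
    direct = np.concatenate([coords[:, 0][:, idx], coords[:, 1][:, idx]], axis=1)
    swapped = np.concatenate([coords[:, 1][:, idx], coords[:, 0][:, idx]], axis=1)
    return direct, swapped


def _kabsch_rmsd_one_to_many(a: np.ndarray, bs: np.ndarray,
                             exact: bool = False) -> np.ndarray:
    """Least-squares superposed RMSD of one centered frame vs a centered stack.

    The singular-value shortcut suffers ~1e-8 cancellation error near zero;
    ``exact`` applies the optimal rotation and measures the residual
    directly (used for single-pair calls where exact zeros matter).
    """
    m = a.shape[0]
    h = np.einsum("mi,kmj->kij", a, bs)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(np.einsum("kij,kjl->kil", u, vt)))
    if exact:
        corr = np.ones((len(bs), 3))
        corr[:, -1] = sign
        rot = np.einsum("kij,kj,kjl->kil", u, corr, vt)
        aligned = np.einsum("kmj,kij->kmi", bs, rot)
        return np.sqrt(((aligned - a[None]) ** 2).sum(axis=(1, 2)) / m)
    s[:, -1] *= sign
    ssd = (a ** 2).sum() + (bs ** 2).sum(axis=(1, 2)) - 2.0 * s.sum(axis=1)
    return np.sqrt(np.clip(ssd / m, 0.0, None))


def symmetric_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                   topo: DimerTopology, selection=None) -> float:
    """Monomer-swap-symmetric superposed RMSD of two frames (nm).

    ``coords_*`` are (2, n_beads, 3) arrays; the default selection is the
    helical segment, residues 9-33.
    """
    if coords_a.shape != coords_b.shape:
        raise ValueError("frames must have matching bead counts")
    topo = topo or DimerTopology()
    if selection is None:
        selection = topo.groups["helical_segment"]
    da, sa = _segment_coords(coords_a[None], topo, selection)
    db, _ = _segment_coords(coords_b[None], topo, selection)
    a = da[0] - da[0].mean(axis=0)
    a_swapped = sa[0] - sa[0].mean(axis=0)
    b = db[0] - db[0].mean(axis=0)
    r1 = _kabsch_rmsd_one_to_many(a, b[None], exact=True)[0]
    r2 = _kabsch_rmsd_one_to_many(a_swapped, b[None], exact=True)[0]
    return float(min(r1, r2))


def symmetric_rmsd_matrix(coords: np.ndarray, topo: DimerTopology,
                          selection=None) -> np.ndarray:
    """Full pairwise symmetric-RMSD matrix of a coordinate stack (n, 2, nb, 3)."""
    topo = topo or DimerTopology()
    if selection is None:
        selection = topo.groups["helical_segment"]
    direct, swapped = _segment_coords(coords, topo, selection)
    direct = direct - direct.mean(axis=1, keepdims=True)
    swapped = swapped - swapped.mean(axis=1, keepdims=True)
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n - 1):
        r1 = _kabsch_rmsd_one_to_many(direct[i], direct[i + 1:])
        r2 = _kabsch_rmsd_one_to_many(swapped[i], direct[i + 1:])
        mat[i, i + 1:] = np.minimum(r1, r2)
    return mat + mat.T


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_bound(rmsd: np.ndarray, n_clusters: int = 3,
                  linkage_policy: str = "average"):
    """Agglomerative clustering on a precomputed symmetric-RMSD matrix.

    Labels come from scikit-learn's agglomerative clustering; the dendrogram
    merge heights (scipy linkage on the same matrix) are returned alongside
    so the cluster-count choice is inspectable.  Returns (labels 0..k-1 in
    order of first occurrence, merge heights, linkage matrix).
    """
    from sklearn.cluster import AgglomerativeClustering

    n = rmsd.shape[0]
    if n < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from {n} frames")
    model = AgglomerativeClustering(n_clusters=n_clusters, metric="precomputed",
                                    linkage=linkage_policy)
    labels = model.fit_predict(rmsd)
    z = linkage(squareform(rmsd, checks=False), method=linkage_policy)
    return _relabel_first_occurrence(labels), z[:, 2].copy(), z


def choose_n_clusters(merge_heights: np.ndarray, k_min: int = 2,
                      k_max: int = 8, method: str = "ratio") -> int:
    """Cluster count at the largest dendrogram merge-height gap.

    Cutting into k clusters removes the k-1 highest merges; the gap for k
    compares the (k-1)-th and k-th highest merge heights.  The default
    ``ratio`` criterion takes the largest gap on a log scale (the ratio of
    successive merge heights), which is what a visual cut of a dendrogram
    responds to and is invariant to the overall RMSD scale; ``absolute``
    uses plain height differences.
    """
    h = np.sort(np.asarray(merge_heights, dtype=float))
    n_merge = len(h)
    k_hi = min(k_max, n_merge)
    if method == "ratio":
        gaps = {k: h[n_merge - k + 1] / max(h[n_merge - k], 1e-12)
                for k in range(k_min, k_hi + 1)}
    elif method == "absolute":
        gaps = {k: h[n_merge - k + 1] - h[n_merge - k]
                for k in range(k_min, k_hi + 1)}
    else:
        raise ValueError(f"unknown gap method {method!r}")
    return max(gaps, key=lambda k: (gaps[k], -k))


def cluster_free_energies(labels: np.ndarray, bound: WeightedEnsemble,
                          unbound_weight: float, kT: float | None = None):
    """Per-cluster Delta F = -kT ln(W_cluster / W_unbound), kJ/mol.

    ``bound.total_weight`` is the bound share of the full ensemble;
    ``unbound_weight`` the unbound share (same normalization).
    """
    labels = np.asarray(labels)
    if len(labels) != len(bound):
        raise ValueError("labels must align with the bound ensemble")
    kT = bound.kT if kT is None else kT
    out = {}
    for lab in np.unique(labels):
        w = bound.weights[labels == lab].sum() * bound.total_weight
        if w <= 0:
            raise ValueError(f"cluster {lab} carries no weight")
        out[int(lab)] = float(-kT * np.log(w / unbound_weight))
    return out


def cluster_centroid(labels: np.ndarray, rmsd: np.ndarray,
                     weights: np.ndarray):
    """Weighted medoid per cluster: the member frame minimizing the weighted
    sum of symmetric RMSD to all cluster members; ties break to the lowest
    frame index."""
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    out = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        cost = (rmsd[np.ix_(idx, idx)] * weights[idx][None, :]).sum(axis=1)
        out[int(lab)] = int(idx[np.argmin(cost)])  # argmin takes first on ties
    return out


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def _weighted_mode(values, weights, bin_width, v_lo=None):
    v_lo = np.floor(values.min() / bin_width) * bin_width if v_lo is None else v_lo
    nb = max(int(np.ceil((values.max() - v_lo) / bin_width)), 1)
    edges = v_lo + bin_width * np.arange(nb + 1)
    hist, _ = np.histogram(values, bins=edges, weights=weights)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1]), edges, hist


def topology_descriptors(labels: np.ndarray, coords: np.ndarray,
                         weights: np.ndarray, topo: DimerTopology,
                         distance_bin: float = 0.05, angle_bin: float = 2.0):
    """Per-cluster region-distance and crossing-angle distributions.

    Returns {label: {region name: {mode, mean, values}, crossing_angle:
    {...}}} with the histogram modes at the stated bin widths (0.05 nm for
    distances, 2 degrees for angles) and weighted means.
    """
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    regions = {"nterm": topo.groups["region_nterm"],
               "mid": topo.groups["region_mid"],
               "cterm": topo.groups["region_cterm"]}
    region_d = {k: batch_min_distances(coords, topo, sel)
                for k, sel in regions.items()}
    psi = batch_crossing_angles(coords, topo)
    out = {}
    for lab in np.unique(labels):
        m = labels == lab
        w = weights[m]
        entry = {}
        for k, vals in region_d.items():
            mode, _, _ = _weighted_mode(vals[m], w, distance_bin, v_lo=0.0)
            entry[k] = {"mode": float(mode),
                        "mean": float(np.average(vals[m], weights=w)),
                        "values": vals[m]}
        mode, _, _ = _weighted_mode(psi[m], w, angle_bin, v_lo=0.0)
        entry["crossing_angle"] = {"mode": float(mode),
                                   "mean": float(np.average(psi[m], weights=w)),
                                   "values": psi[m]}
        out[int(lab)] = entry
    return out


@dataclass
class ClusterReport:
    """Summary of one bound-dimer cluster."""

    label: int
    topology_name: str
    free_energy: float                 # kJ/mol relative to the unbound state
    free_energy_error: float | None
    mean_d_min: float
    mean_d_min_error: float | None
    centroid_frame: int
    member_count: int
    weight_share: float                # share of the full ensemble weight


@dataclass
class ContactProbabilityMap:
    """Residue-residue weighted contact probabilities of one cluster."""

    probabilities: np.ndarray          # (n_res, n_res) in [0, 1]
    marginal: np.ndarray               # per-residue contact probability
    display_threshold: float = 0.20

    def displayed(self) -> np.ndarray:
        """Masked copy for rendering; stored data are never masked."""
        shown = self.probabilities.copy()
        shown[shown <= self.display_threshold] = 0.0
        return shown


def contact_probability_map(labels: np.ndarray, coords: np.ndarray,
                            weights: np.ndarray, topo: DimerTopology,
                            cutoff: float = CONTACT_CUTOFF_NM,
                            display_threshold: float = 0.20,
                            symmetrize: bool = True,
                            marginal_mode: str = "any"):
    """Per-cluster contact-probability maps and per-residue profiles.

    The per-residue marginal is the probability that a residue contacts ANY
    residue of the partner (``marginal_mode='max'`` instead reports the
    maximum pair probability).  ``symmetrize`` averages the map with its
    monomer-swapped transpose, the homodimer symmetry.
    """
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    contacts = batch_contact_matrices(coords, topo, cutoff)
    out = {}
    for lab in np.unique(labels):
        m = labels == lab
        w = weights[m] / weights[m].sum()
        prob = np.clip(np.tensordot(w, contacts[m].astype(float), axes=1), 0, 1)
        any_contact = contacts[m].any(axis=2) | contacts[m].any(axis=1)
        marg_any = np.clip(np.tensordot(w, any_contact.astype(float), axes=1), 0, 1)
        if symmetrize:
            prob = 0.5 * (prob + prob.T)
        marginal = marg_any if marginal_mode == "any" else prob.max(axis=1)
        out[int(lab)] = ContactProbabilityMap(prob, marginal, display_threshold)
    return out


def motif_report(marginal: np.ndarray, topo: DimerTopology,
                 threshold: float = 0.5):
    """Interface residues above threshold and the motif string spanning them.

    The contiguous span between the first and last interface residues is
    rendered with residue letters at interface positions and 'x' elsewhere,
    e.g. peaks at 21/25/29/33 give 'V21xxxVxxxGxxxM33'.
    """
    marginal = np.asarray(marginal, dtype=float)
    residues = [i + 1 for i in range(len(marginal)) if marginal[i] > threshold]
    report = {"residues": residues,
              "probabilities": {r: float(marginal[r - 1]) for r in residues},
              "motif": ""}
    if not residues:
        return report
    first, last = residues[0], residues[-1]
    parts = [topo.residue_label(first)]
    for r in range(first + 1, last):
        if r in residues:
            name = topo.residue_names.get(r)
            parts.append(name if name else str(r))
        else:
            parts.append("x")
    if last != first:
        parts.append(topo.residue_label(last))
    report["motif"] = "".join(parts)
    return report
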