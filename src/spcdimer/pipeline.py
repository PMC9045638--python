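"""End-to-end orchestration: campaign -> reweight -> uncertainty -> clusters.

``run_pipeline`` drives a full reproducible run from a single
:class:`RunConfig` (YAML-serializable): synthesize or ingest a campaign,
reweight all windows into one weighted ensemble, project the PMF along
d_min, estimate the bound/unbound free-energy difference, select and
cluster the bound dimers, and write per-cluster free energies, descriptor
distributions, contact maps and the interface-motif report, with Bayesian
block-bootstrap errors throughout.  Every stage checkpoints its status so a
partial failure is diagnosable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as cio
from .bootstrap import BootstrapSpec, bayesian_block_weights
from .constants import DEFAULT_TEMPERATURE, kt
from .ensemble import (choose_n_clusters, cluster_bound, cluster_centroid,
                       cluster_free_energies, contact_probability_map,
                       motif_report, select_bound, symmetric_rmsd_matrix,
                       topology_descriptors, ClusterReport)
from .reweight import (conditional_region_profile, ensemble_from_runs,
                       free_energy_difference, pooled_cvs, project_pmf)
from .synthetic import (Campaign, CampaignConfig, config_from_dict,
                        load_campaign, make_campaign, reconstruct_frames)
from .topology import (BOUND_CUTOFF_NM, CONTACT_CUTOFF_NM, DimerTopology,
                       batch_min_distances)

__all__ = ["RunConfig", "run_pipeline", "validate_campaign", "analyze_campaign"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs; round-trips through YAML."""

    mode: str = "synthesize"               # synthesize | analyze
    campaign_dir: str = "campaign"
    output_dir: str = "run_output"
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    bound_cutoff: float = BOUND_CUTOFF_NM
    contact_cutoff: float = CONTACT_CUTOFF_NM
    display_threshold: float = 0.20
    motif_threshold: float = 0.5
    equilibration: float = 0.4   # past the campaign's bias-deposition phase
    subsample: int = 10
    n_clusters: int = 3
    linkage_policy: str = "average"
    n_cluster_frames: int = 400
    bootstrap_replicates: int = 100
    bootstrap_seed: int = 1
    pmf_bin_width: float = 0.05
    pmf_range: tuple = (0.30, 3.60)
    plateau_window: tuple = (2.0, 3.5)
    campaign: CampaignConfig = field(default_factory=CampaignConfig)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.mode not in ("synthesize", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        raw["campaign"] = config_from_dict(raw["campaign"])
        raw["pmf_range"] = tuple(raw["pmf_range"])
        raw["plateau_window"] = tuple(raw["plateau_window"])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


class _Stages:
    """Stage-level checkpointing: status written after every stage."""

    def __init__(self, path: Path):
        self.path = path
        self.status = {}

    def run(self, name, fn, *args, **kwargs):
        t0 = time.time()
        log.info("stage %s: started", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            self.status[name] = {"state": "failed", "error": str(exc)}
            self._flush()
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        self.status[name] = {"state": "done",
                             "seconds": round(time.time() - t0, 2)}
        self._flush()
        return out

    def _flush(self):
        cio.write_json(self.path, self.status)


def run_pipeline(config: RunConfig, topo: DimerTopology | None = None) -> dict:
    """Execute the full pipeline; returns the result summary dict."""
    topo = topo or DimerTopology()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = _Stages(out_dir / "run_status.json")
    log.info("pipeline start: seed=%d temperature=%.1fK mode=%s",
             config.seed, config.temperature, config.mode)

    if config.mode == "synthesize":
        campaign = stages.run(
            "synthesize", make_campaign, Path(config.campaign_dir),
            replace(config.campaign, temperature=config.temperature),
            config.seed, topo)
    else:
        campaign = stages.run("ingest", load_campaign,
                              Path(config.campaign_dir), topo)

    results = stages.run("analyze", analyze_campaign, campaign, config,
                         topo, out_dir)
    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "bootstrap_seed": config.bootstrap_seed,
        "version": __version__,
        "summary": results["summary"],
        "stages": stages.status,
    }
    cio.write_json(out_dir / "manifest.json", manifest)
    return results


def analyze_campaign(campaign: Campaign, config: RunConfig,
                     topo: DimerTopology | None = None,
                     out_dir: Path | None = None) -> dict:
    """Reweight, project, cluster and report (the analyze stages)."""
    topo = topo or DimerTopology()
    kT = kt(config.temperature)
    runs = campaign.runs
    fes = campaign.fes

    # --- reweight all windows into one pooled weighted ensemble
    ens, offsets, views, bias = ensemble_from_runs(
        runs, config.temperature, config.equilibration, config.subsample)
    phi1, phi2, d = pooled_cvs(views)
    coords = reconstruct_frames(fes, phi1, phi2, d, topo)
    d_min = batch_min_distances(coords, topo)

    # --- bootstrap block factors (shared by every weighted error below)
    spec = BootstrapSpec(config.bootstrap_replicates, config.bootstrap_seed)
    factors = bayesian_block_weights(len(runs), spec.n_replicates, spec.seed)
    rep_weights = []
    for r in range(spec.n_replicates):
        ens_r, _, _, _ = ensemble_from_runs(
            runs, config.temperature, config.equilibration, config.subsample,
            window_factors=factors[r], g0=offsets, bias=bias)
        rep_weights.append(ens_r.weights)
    rep_weights = np.stack(rep_weights)

    # --- PMF along d_min with bootstrap errors
    edges = np.arange(config.pmf_range[0],
                      config.pmf_range[1] + config.pmf_bin_width / 2,
                      config.pmf_bin_width)
    pmf = project_pmf(ens, d_min, edges, "d_min",
                      plateau_window=config.plateau_window)
    rep_pmf = []
    for w in rep_weights:
        ens_r = _with_weights(ens, w)
        rep_pmf.append(project_pmf(ens_r, d_min, edges, "d_min",
                                   plateau_window=config.plateau_window).values)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        pmf.errors = np.nanstd(np.stack(rep_pmf), axis=0, ddof=1)

    # --- bound/unbound free-energy difference
    bound_mask = d_min <= config.bound_cutoff
    delta_f = free_energy_difference(ens, bound_mask)
    rep_df = [free_energy_difference(_with_weights(ens, w), bound_mask)
              for w in rep_weights]
    delta_f_err = float(np.std(rep_df, ddof=1))

    # --- association mechanism: region distances vs COM-COM distance
    regions = {"nterm": topo.groups["region_nterm"],
               "mid": topo.groups["region_mid"],
               "cterm": topo.groups["region_cterm"]}
    region_d = {k: batch_min_distances(coords, topo, sel)
                for k, sel in regions.items()}
    d_edges = np.arange(0.9, 4.0, 0.1)
    assoc = {k: conditional_region_profile(ens, d, v, d_edges)
             for k, v in region_d.items()}

    # --- bound selection; the clustered subsample is importance-resampled by
    # weight (systematic resampling) so it represents the equilibrium bound
    # ensemble rather than the biased windows' visiting frequencies
    bound_ens, _ = select_bound(ens, d_min, config.bound_cutoff)
    bound_idx = np.flatnonzero(bound_mask)
    n_cl = min(config.n_cluster_frames, len(bound_idx))
    cl_idx = bound_idx[_systematic_resample(
        bound_ens.weights, n_cl, np.random.default_rng(config.seed + 7))]
    cl_coords = coords[cl_idx]
    rmsd = symmetric_rmsd_matrix(cl_coords, topo)
    labels, merge_heights, _ = cluster_bound(rmsd, config.n_clusters,
                                             config.linkage_policy)
    gap_choice = choose_n_clusters(merge_heights)

    # resampled members are equally weighted; replicate estimates reweight
    # them by the ratio of replicate to base frame weights
    bound_share = float(ens.weights[bound_mask].sum())
    w_cl = np.full(n_cl, 1.0 / n_cl)

    def cluster_delta_f_from(weights):
        wb = weights[bound_mask].sum()
        ratio = weights[cl_idx] / ens.weights[cl_idx]
        out = {}
        for lab in np.unique(labels):
            w_c = ratio[labels == lab].sum() / ratio.sum() * wb
            out[int(lab)] = float(-kT * np.log(w_c / (1.0 - wb)))
        return out

    cdf = cluster_delta_f_from(ens.weights)
    rep_cdf = [cluster_delta_f_from(w) for w in rep_weights]
    cdf_err = {lab: float(np.std([r[lab] for r in rep_cdf], ddof=1))
               for lab in cdf}

    centroids = cluster_centroid(labels, rmsd, w_cl)
    descriptors = topology_descriptors(labels, cl_coords, w_cl, topo)
    maps = contact_probability_map(labels, cl_coords, w_cl, topo,
                                   config.contact_cutoff,
                                   config.display_threshold)

    # name clusters by matching centroid CVs to the planted basins if known
    names = _assign_topology_names(fes, labels, phi1[cl_idx], phi2[cl_idx])

    cl_dmin = d_min[cl_idx]
    reports = []
    for lab in sorted(cdf, key=lambda k: cdf[k]):
        m = labels == lab
        mean_dmin = float(np.average(cl_dmin[m], weights=w_cl[m]))
        rep_means = []
        for w in rep_weights:
            ww = w[cl_idx][m] / ens.weights[cl_idx][m]
            rep_means.append(np.average(cl_dmin[m], weights=ww))
        reports.append(ClusterReport(
            label=int(lab), topology_name=names.get(int(lab), f"cluster-{lab}"),
            free_energy=cdf[lab], free_energy_error=cdf_err[lab],
            mean_d_min=mean_dmin,
            mean_d_min_error=float(np.std(rep_means, ddof=1)),
            centroid_frame=int(cl_idx[centroids[lab]]),
            member_count=int(m.sum()),
            weight_share=float(w_cl[m].sum() / w_cl.sum() * bound_share)))

    # interface motif from the most stable cluster's per-residue profile
    best = reports[0].label
    motif = motif_report(maps[best].marginal, topo, config.motif_threshold)

    summary = {
        "delta_f_bound_unbound": float(delta_f),
        "delta_f_error": delta_f_err,
        "bound_weight_share": bound_share,
        "pmf_min_d_min": float(pmf.bin_centers[np.nanargmin(pmf.values)]),
        "n_clusters_requested": config.n_clusters,
        "n_clusters_by_gap": int(gap_choice),
        "clusters": [asdict(r) for r in reports],
        "motif": motif,
    }
    results = {
        "summary": summary, "ensemble": ens, "offsets": offsets,
        "pmf": pmf, "d_min": d_min, "bound_mask": bound_mask,
        "association": assoc, "labels": labels, "cluster_indices": cl_idx,
        "rmsd": rmsd, "merge_heights": merge_heights,
        "descriptors": descriptors, "contact_maps": maps,
        "coords": coords, "reports": reports,
    }
    if out_dir is not None:
        _write_outputs(out_dir, results, topo, config)
    return results


def _systematic_resample(weights, n, rng):
    """Deterministic-stride (systematic) importance resampling indices."""
    positions = (rng.random() + np.arange(n)) / n
    cumulative = np.cumsum(weights)
    cumulative[-1] = 1.0
    return np.searchsorted(cumulative, positions)


def _with_weights(ens, weights):
    from .reweight import WeightedEnsemble
    return WeightedEnsemble(ens.window_ids, ens.frame_indices, weights,
                            ens.temperature, ens.provenance, ens.total_weight)


def _assign_topology_names(fes, labels, phi1, phi2):
    """Majority basin assignment of each cluster's members, if a planted
    surface is available."""
    if fes is None:
        return {}
    from .synthetic import assign_basins
    basin = assign_basins(fes, phi1, phi2)
    names = {}
    for lab in np.unique(labels):
        counts = np.bincount(basin[labels == lab], minlength=len(fes.basins))
        names[int(lab)] = fes.basins[int(np.argmax(counts))].template_name
    return names


def _write_outputs(out_dir: Path, results: dict, topo: DimerTopology,
                   config: RunConfig) -> None:
    out_dir = Path(out_dir)
    pmf = results["pmf"]
    with open(out_dir / "pmf_dmin.tsv", "w") as fh:
        fh.write("bin_center\tfree_energy\terror\toccupied\n")
        for c, v, e, o in zip(pmf.bin_centers, pmf.values, pmf.errors,
                              pmf.occupied):
            fh.write(f"{c:.6g}\t{v:.6g}\t{e:.6g}\t{int(o)}\n")
    with open(out_dir / "association_profile.tsv", "w") as fh:
        fh.write("d_center\tnterm\tmid\tcterm\tweight\n")
        centers, _, wsum = results["association"]["nterm"]
        cols = {k: results["association"][k][1] for k in ("nterm", "mid", "cterm")}
        for i, c in enumerate(centers):
            fh.write(f"{c:.6g}\t{cols['nterm'][i]:.6g}\t{cols['mid'][i]:.6g}\t"
                     f"{cols['cterm'][i]:.6g}\t{wsum[i]:.6g}\n")
    with open(out_dir / "cluster_report.tsv", "w") as fh:
        fh.write("label\ttopology\tfree_energy\terror\tmean_d_min\t"
                 "mean_d_min_error\tcentroid_frame\tmembers\tweight_share\n")
        for r in results["reports"]:
            fh.write(f"{r.label}\t{r.topology_name}\t{r.free_energy:.4f}\t"
                     f"{r.free_energy_error:.4f}\t{r.mean_d_min:.4f}\t"
                     f"{r.mean_d_min_error:.4f}\t{r.centroid_frame}\t"
                     f"{r.member_count}\t{r.weight_share:.6g}\n")
    with open(out_dir / "dendrogram_heights.tsv", "w") as fh:
        fh.write("merge_height\n")
        for h in results["merge_heights"]:
            fh.write(f"{h:.8g}\n")
    for lab, cmap in results["contact_maps"].items():
        np.savetxt(out_dir / f"contact_map_cluster{lab}.tsv",
                   cmap.probabilities, fmt="%.5f", delimiter="\t")
    cio.write_json(out_dir / "summary.json", results["summary"])
    # centroid structures, one model per cluster in stability order
    cent = np.stack([results["coords"][r.centroid_frame]
                     for r in results["reports"]])
    cio.write_pdb_models(out_dir / "centroids.pdb", cent, topo)


# ---------------------------------------------------------------------------
# campaign validation
# ---------------------------------------------------------------------------

def validate_campaign(path) -> list:
    """Structural checks of a campaign directory; returns a violation list
    (empty when the campaign is intact).  Unreadable files are reported as
    violations, not raised."""
    path = Path(path)
    violations = []

    def bad(file, message):
        violations.append({"file": str(file), "message": message})

    manifest_path = path / "manifest.json"
    try:
        cio.read_json(manifest_path)
    except Exception as exc:
        bad(manifest_path, f"unreadable manifest: {exc}")
    windows_path = path / "windows.tsv"
    try:
        windows = cio.read_window_manifest(windows_path)
    except Exception as exc:
        bad(windows_path, f"unreadable window manifest: {exc}")
        return violations
    seen = set()
    for w in windows:
        if w.window_id in seen:
            bad(windows_path, f"duplicate window id {w.window_id}")
        seen.add(w.window_id)
        if not (-np.pi < w.phi1_center <= np.pi) or not (-np.pi < w.phi2_center <= np.pi):
            bad(windows_path, f"window {w.window_id}: center outside (-pi, pi]")
    for w in windows:
        cpath = path / "colvar" / f"window_{w.window_id:04d}.colvar"
        try:
            col = cio.read_colvar(cpath)
        except Exception as exc:
            bad(cpath, f"unreadable COLVAR: {exc}")
            continue
        if len(col["time"]) and np.any(np.diff(col["time"]) <= 0):
            bad(cpath, "non-monotonic time")
        for ang in ("phi1", "phi2"):
            if np.any(col[ang] > np.pi + 1e-9) or np.any(col[ang] <= -np.pi - 1e-9):
                bad(cpath, f"{ang} outside (-pi, pi]")
        if np.any(col["d"] < 0):
            bad(cpath, "negative distance d")
        hpath = path / "hills" / f"window_{w.window_id:04d}.hills"
        try:
            hills = cio.read_hills(hpath)
        except Exception as exc:
            bad(hpath, f"unreadable HILLS: {exc}")
            continue
        if len(hills) == 0:
            continue
        if np.any(np.diff(hills.times) <= 0):
            bad(hpath, "non-monotonic hill times")
        for line_no, s in enumerate(hills.sigmas, start=2):
            if s <= 0:
                bad(hpath, f"line {line_no}: non-positive hill width")
        if np.any(hills.heights <= 0):
            bad(hpath, "non-positive hill height")
    return violations
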