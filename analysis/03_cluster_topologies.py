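#!/usr/bin/env python
"""Summarize the bound-dimer topology clusters of the analyzed campaign.

Reads the cluster report and dendrogram written by
analysis/02_reweight_free_energy.py and prints the per-topology free
energies, mean contact distances and the dendrogram-gap cluster-count
choice.
"""

from pathlib import Path

import numpy as np

from spcdimer.ensemble import choose_n_clusters
from spcdimer.io import read_json

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "run"


def main():
    summary_path = OUT / "summary.json"
    if not summary_path.exists():
        raise SystemExit("no analysis output - run analysis/02_reweight_free_energy.py first")
    s = read_json(summary_path)
    heights = np.loadtxt(OUT / "dendrogram_heights.tsv", skiprows=1)
    print(f"dendrogram gap selects {choose_n_clusters(heights)} clusters "
          f"(analysis used {s['n_clusters_requested']})")
    print(f"{'topology':<12s} {'dF (kJ/mol)':>14s} {'<d_min> (nm)':>14s} "
          f"{'members':>8s} {'weight':>8s}")
    for c in s["clusters"]:
        print(f"{c['topology_name']:<12s} "
              f"{c['free_energy']:>8.2f} +/- {c['free_energy_error']:<4.2f} "
              f"{c['mean_d_min']:>7.3f} +/- {c['mean_d_min_error']:<5.3f} "
              f"{c['member_count']:>6d} {c['weight_share']:>8.3f}")
    order = [c["topology_name"] for c in s["clusters"]]
    print("stability order (most to least stable):", " > ".join(order))


if __name__ == "__main__":
    main()
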