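#!/usr/bin/env python
"""Report the dimerization interface: contact residues and motif string.

Reads the per-cluster contact-probability maps written by
analysis/02_reweight_free_energy.py, lists the residues most likely to
touch the partner helix in each topology, and prints the contiguous
interface motif of the most stable cluster.
"""

from pathlib import Path

import numpy as np

from spcdimer.io import read_json
from spcdimer.topology import DimerTopology

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "run"


def main():
    summary_path = OUT / "summary.json"
    if not summary_path.exists():
        raise SystemExit("no analysis output - run analysis/02_reweight_free_energy.py first")
    s = read_json(summary_path)
    topo = DimerTopology()
    for c in s["clusters"]:
        path = OUT / f"contact_map_cluster{c['label']}.tsv"
        if not path.exists():
            raise SystemExit(f"{path} missing - rerun analysis/02_reweight_free_energy.py")
        prob = np.loadtxt(path)
        marginal = np.clip(prob, 0, 1).max(axis=1)
        top = np.argsort(marginal)[::-1][:6] + 1
        labels = ", ".join(topo.residue_label(int(r)) for r in sorted(top))
        print(f"{c['topology_name']:<12s} top contact residues: {labels}")
    motif = s["motif"]
    print(f"interface residues (most stable topology): {motif['residues']}")
    print(f"interface motif: {motif['motif']}")


if __name__ == "__main__":
    main()
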