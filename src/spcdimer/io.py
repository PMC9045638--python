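"""Plain-text campaign I/O: COLVAR/HILLS files, window manifests, bead frames.

All tabular files are tab-separated with floats written at full ``repr``
precision, so write -> read -> write round-trips are byte-stable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .bias import BiasGrid, HillsLog, WindowSpec
from .topology import DimerTopology, FrameGeometry

__all__ = [
    "write_colvar", "read_colvar",
    "write_hills", "read_hills",
    "write_window_manifest", "read_window_manifest",
    "write_coordinate_table", "read_coordinate_table",
    "write_pdb_models", "read_pdb_models",
    "write_json", "read_json",
]

COLVAR_FIELDS = ("time", "phi1", "phi2", "d")
HILLS_FIELDS = ("time", "center", "sigma", "height", "biasf")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_colvar(path, times, phi1, phi2, d, d_min=None) -> None:
    """COLVAR-style file with a '#! FIELDS ...' header line.

    Floats are written with 17 significant digits, so values survive
    write -> read -> write byte-identically.
    """
    fields = list(COLVAR_FIELDS) + (["d_min"] if d_min is not None else [])
    cols = [times, phi1, phi2, d] + ([d_min] if d_min is not None else [])
    data = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter="\t")


def read_colvar(path):
    """Read a COLVAR file -> dict of column name -> array."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        names = header.split()[2:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = np.loadtxt(fh, ndmin=2)
    if data.size == 0:
        data = np.empty((0, len(names)))
    if data.shape[1] != len(names):
        raise ValueError(f"{path}: {data.shape[1]} columns but {len(names)} fields")
    return {n: data[:, i] for i, n in enumerate(names)}


def write_hills(path, log: HillsLog) -> None:
    data = np.column_stack([log.times, log.centers, log.sigmas, log.heights,
                            np.full(len(log.times), log.bias_factor)])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(HILLS_FIELDS) + "\n")
        np.savetxt(fh, data.reshape(-1, 5), fmt="%.17g", delimiter="\t")


def read_hills(path) -> HillsLog:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        names = header.split()[2:]
        if tuple(names) != HILLS_FIELDS:
            raise ValueError(f"{path}: unexpected HILLS fields {names}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = np.loadtxt(fh, ndmin=2)
    if data.size == 0:
        return HillsLog()
    return HillsLog(times=data[:, 0], centers=data[:, 1], sigmas=data[:, 2],
                    heights=data[:, 3], bias_factor=float(data[0, 4]))


def grid_from_hills(log: HillsLog, d_lo=0.5, d_hi=4.5, spacing=0.01) -> BiasGrid:
    """Rebuild the final accumulated bias grid from a hill log."""
    grid = BiasGrid(d_lo, d_hi, spacing)
    for c, s, h in zip(log.centers, log.sigmas, log.heights):
        if d_lo <= c <= d_hi:
            grid.values += h * np.exp(-((grid.nodes - c) ** 2) / (2.0 * s ** 2))
    return grid


def write_window_manifest(path, windows) -> None:
    with open(path, "w") as fh:
        fh.write("window_id\tcenter_phi1_deg\tcenter_phi2_deg\tkappa\n")
        for w in windows:
            fh.write(f"{w.window_id}\t{_fmt(np.degrees(w.phi1_center))}\t"
                     f"{_fmt(np.degrees(w.phi2_center))}\t{_fmt(w.k_phi)}\n")


def read_window_manifest(path):
    windows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("window_id"):
            raise ValueError(f"{path}: missing window manifest header")
        for line in fh:
            wid, c1, c2, k = line.split("\t")
            windows.append(WindowSpec(int(wid), np.radians(float(c1)),
                                      np.radians(float(c2)), float(k)))
    return windows


def write_coordinate_table(path, coords, topo: DimerTopology) -> None:
    """Per-frame bead coordinate table; ``coords`` is (n_frames, 2, n_beads, 3) nm."""
    with open(path, "w") as fh:
        fh.write("frame\tmonomer\tresidue\tbead\tx\ty\tz\n")
        for f, frame in enumerate(coords):
            for m in range(2):
                for b in range(topo.n_beads):
                    res = b // topo.beads_per_residue + 1
                    x, y, z = frame[m, b]
                    fh.write(f"{f}\t{m + 1}\t{res}\t{topo.bead_tag(b)}\t"
                             f"{_fmt(x)}\t{_fmt(y)}\t{_fmt(z)}\n")


def read_coordinate_table(path, topo: DimerTopology) -> np.ndarray:
    rows = np.loadtxt(path, skiprows=1,
                      converters={3: lambda s: 0.0}, ndmin=2,
                      usecols=(0, 1, 2, 4, 5, 6))
    n_frames = int(rows[:, 0].max()) + 1
    coords = np.empty((n_frames, 2, topo.n_beads, 3))
    per_frame = 2 * topo.n_beads
    if len(rows) != n_frames * per_frame:
        raise ValueError(f"{path}: expected {n_frames * per_frame} rows, got {len(rows)}")
    coords = rows[:, 3:6].reshape(n_frames, 2, topo.n_beads, 3)
    return coords


def write_pdb_models(path, coords, topo: DimerTopology) -> None:
    """Multi-model PDB (chains A/B, atoms BB/SC) from a coordinate stack in nm."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        coords = coords[None]
    n_frames = coords.shape[0]
    n_atoms = 2 * topo.n_beads
    atoms = struc.AtomArray(n_atoms)
    chain, res_id, name, res_name = [], [], [], []
    for m, ch in enumerate("AB"):
        for b in range(topo.n_beads):
            res = b // topo.beads_per_residue + 1
            chain.append(ch)
            res_id.append(res)
            name.append(topo.bead_tag(b) if topo.beads_per_residue > 1 else "BB")
            res_name.append((topo.residue_names.get(res) or "X") + "AA")
    atoms.chain_id = np.array(chain)
    atoms.res_id = np.array(res_id)
    atoms.atom_name = np.array(name)
    atoms.res_name = np.array([r[:3].upper() for r in res_name])
    atoms.element = np.full(n_atoms, "C")
    stack = struc.stack([atoms] * n_frames)
    stack.coord = coords.reshape(n_frames, n_atoms, 3) * 10.0  # nm -> Angstrom
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_models(path, topo: DimerTopology) -> np.ndarray:
    """Read a multi-model two-chain PDB into a (n_frames, 2, n_beads, 3) nm stack."""
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure()
    coords = stack.coord / 10.0
    n_frames = coords.shape[0]
    chains = stack.chain_id if stack.chain_id.ndim == 1 else stack.chain_id[0]
    a_mask = chains == "A"
    b_mask = chains == "B"
    if a_mask.sum() != topo.n_beads or b_mask.sum() != topo.n_beads:
        raise ValueError(f"{path}: chain sizes do not match the topology")
    return np.stack([coords[:, a_mask], coords[:, b_mask]], axis=1)


def frame_from_pdb(path, topo: DimerTopology, model: int = 0) -> FrameGeometry:
    coords = read_pdb_models(path, topo)
    return FrameGeometry(coords[model, 0], coords[model, 1])


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
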