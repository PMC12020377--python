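"""Structure and table I/O.

Multi-model PDB files are read and written through biotite; atom-name
dialects are normalised on input (O1P/O2P → OP1/OP2, ``*`` → ``'``,
terminal-phosphate variants) so that atom maps resolve identically for
canonical and legacy files.  Additional trajectory formats can be plugged
in by registering a reader callable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import Conformation
from .states import StateTimeline

__all__ = [
    "normalize_atom_name",
    "read_structures",
    "write_structures",
    "register_reader",
    "write_timeline_csv",
    "read_indicator_csv",
    "write_indicator_csv",
]

# legacy -> canonical PDB v3 atom names
_NAME_FIXES = {
    "O1P": "OP1",
    "O2P": "OP2",
    "O3P": "OP3",
}


def normalize_atom_name(name: str) -> str:
    """Canonicalise an atom-name dialect (O1P→OP1, trailing * → ')."""
    name = name.strip().replace("*", "'")
    return _NAME_FIXES.get(name, name)


def _to_conformation(atoms: struc.AtomArray, frame_time: float) -> Conformation:
    heavy = atoms.element != "H"
    atoms = atoms[heavy]
    names = np.array([normalize_atom_name(n) for n in atoms.atom_name], dtype=object)
    resnames = np.array([str(r).strip() for r in atoms.res_name], dtype=object)
    return Conformation(
        residue_index=np.asarray(atoms.res_id, dtype=int),
        residue_name=resnames,
        atom_name=names,
        coords=np.asarray(atoms.coord, dtype=float),
        frame_time=frame_time,
    )


def _read_pdb(path) -> list[Conformation]:
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack, one entry per MODEL
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - biotite returns stacks
        stack = struc.stack([stack])
    return [_to_conformation(stack[i], float(i)) for i in range(stack.stack_depth())]


_READERS: dict[str, Callable[[object], list[Conformation]]] = {"pdb": _read_pdb}


def register_reader(fmt: str, reader: Callable[[object], list[Conformation]]) -> None:
    """Register a trajectory reader for an additional format."""
    _READERS[fmt.lower()] = reader


def read_structures(path, format: str = "pdb") -> list[Conformation]:
    """Read all models of a coordinate file as Conformations (file order)."""
    fmt = format.lower()
    if fmt not in _READERS:
        raise ValueError(f"no reader registered for format {format!r}")
    return _READERS[fmt](path)


def write_structures(frames: Sequence[Conformation], path) -> None:
    """Write conformations as a multi-model PDB file."""
    frames = list(frames)
    if not frames:
        raise ValueError("nothing to write")
    first = frames[0]
    n = len(first)
    arrays = []
    for fr in frames:
        if len(fr) != n:
            raise ValueError("all frames must share one topology")
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(fr.coords, dtype=np.float32)
        arr.res_id = np.asarray(fr.residue_index, dtype=int)
        arr.res_name = np.array([str(r) for r in fr.residue_name])
        arr.atom_name = np.array([str(a) for a in fr.atom_name])
        arr.chain_id = np.full(n, "A")
        arr.element = np.array([str(a)[0] for a in fr.atom_name])
        arr.hetero = np.full(n, False)
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def write_timeline_csv(timeline: StateTimeline, path) -> None:
    """Timeline CSV: frame, time, state, weight plus the eight features."""
    rows = []
    for i, lab in enumerate(timeline.labels):
        row = {
            "frame": i,
            "time": float(timeline.times[i]),
            "state": lab.value,
            "weight": float(timeline.weights[i]),
        }
        if timeline.features is not None:
            row.update(timeline.features[i].as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_indicator_csv(indicator, path, weights=None, run_id=None) -> None:
    """Folded-indicator CSV with columns frame, folded, weight, run_id."""
    indicator = np.asarray(indicator, dtype=bool)
    n = len(indicator)
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "folded": indicator.astype(int),
            "weight": np.ones(n) if weights is None else np.asarray(weights, float),
            "run_id": np.zeros(n, dtype=int) if run_id is None else np.asarray(run_id, int),
        }
    )
    df.to_csv(path, index=False)


def read_indicator_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a folded-indicator CSV: (indicator, weights, run_id)."""
    df = pd.read_csv(path)
    ind = df["folded"].to_numpy().astype(bool)
    weights = df["weight"].to_numpy(dtype=float) if "weight" in df else np.ones(len(ind))
    run_id = df["run_id"].to_numpy(dtype=int) if "run_id" in df else np.zeros(len(ind), dtype=int)
    return ind, weights, run_id
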