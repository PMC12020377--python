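"""Seeded generators for every input the analysis pipeline consumes.

The centrepiece is a deterministic, idealised 14-mer hairpin scaffold
(sequence GGCACUUCGGUGCC, five-base-pair stem, UUCG loop) built from
internal coordinates: planar bases with correct ring topology, puckered
ribose rings, and a loop refined so that all four native hydrogen-bond
distances, the 7BPh base-phosphate contact and the syn glycosidic torsion
of the loop guanosine satisfy the native-state criteria.  The scaffold is a
classifier/metric fixture — geometrically plausible, but an idealised
construct, not a model of any experimental structure; a user-supplied
native PDB can be used everywhere instead.

On top of the scaffold sit constrained randomisers: per-state conformers
(rejection sampling with documented perturbation operators), Markov state
timelines with a known stationary distribution, two-state folded/unfolded
ensembles with a prescribed folded fraction, and noisy NMR observable
tables back-calculated from a known ensemble.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import AtomMap, AtomRef, Conformation, dihedral, distance
from .nmr import (
    DEFAULT_KARPLUS_SETS,
    Observable,
    ObservableTable,
    back_calculate,
)
from .states import (
    ClassifierConfig,
    StateLabel,
    StateTimeline,
    classify_features,
    extract_features,
)
from .ermsd import FOLDED_THRESHOLD as _FOLDED_THRESHOLD, ermsd as _ermsd_fn

__all__ = [
    "GenerationError",
    "GeneratorConfig",
    "TransitionMatrix",
    "SCAFFOLD_SEQUENCE",
    "build_reference_scaffold",
    "generate_state_conformer",
    "generate_markov_timeline",
    "generate_two_state_ensemble",
    "generate_unfolded_conformer",
    "generate_nmr_dataset",
]


class GenerationError(RuntimeError):
    """Constraint satisfaction failed within the retry budget."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed and scale knobs shared by the generators.

    ``jitter_sd`` is the Gaussian coordinate noise in Å applied to every
    generated conformer; ``max_retries`` bounds rejection sampling.
    """

    seed: int = 0
    n_frames: int = 1000
    jitter_sd: float = 0.04
    max_retries: int = 1000


SCAFFOLD_SEQUENCE: tuple[str, ...] = ("G", "G", "C", "A", "C", "U", "U", "C", "G", "G", "U", "G", "C", "C")

# ---------------------------------------------------------------------------
# Idealised nucleotide templates

_BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "G": ("N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9"),
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
}
_SUGAR_ATOMS: tuple[str, ...] = (
    "C1'", "C2'", "C3'", "C4'", "O4'", "O2'", "O3'", "C5'", "O5'", "P", "OP1", "OP2",
)


def _hexagon_base(resname: str) -> dict[str, np.ndarray]:
    """Planar base atoms in a local frame (ring in the z = 0 plane)."""
    r_hex = 1.39
    atoms: dict[str, np.ndarray] = {}
    ring = ("N1", "C2", "N3", "C4", "C5", "C6")
    for k, name in enumerate(ring):
        ang = math.radians(90.0 - 60.0 * k)
        atoms[name] = np.array([r_hex * math.cos(ang), r_hex * math.sin(ang), 0.0])

    purine = resname in ("A", "G")
    if purine:
        # Fused five-ring beyond the C4-C5 edge: vertices C4, N9, C8, N7, C5.
        c4, c5 = atoms["C4"], atoms["C5"]
        mid = (c4 + c5) / 2.0
        out = mid / np.linalg.norm(mid)
        side = float(np.linalg.norm(c5 - c4))
        apothem = side / (2.0 * math.tan(math.radians(36.0)))
        center = mid + apothem * out
        ang4 = math.atan2(c4[1] - center[1], c4[0] - center[0])
        ang5 = math.atan2(c5[1] - center[1], c5[0] - center[0])
        # step from C4 towards C5 the long way round (through N9, C8, N7)
        step = math.radians(72.0)
        if (ang4 + 4 * step - ang5) % (2 * math.pi) > 1e-6:
            step = -step
        rad = side / (2.0 * math.sin(math.radians(36.0)))
        for j, name in enumerate(("N9", "C8", "N7"), start=1):
            a = ang4 + j * step
            atoms[name] = center + np.array([rad * math.cos(a), rad * math.sin(a), 0.0])

    def _exo(on: str, name: str, bond: float) -> None:
        pos = atoms[on]
        centre = np.zeros(3)
        u = pos - centre
        u = u / np.linalg.norm(u)
        atoms[name] = pos + bond * u

    if resname == "G":
        _exo("C6", "O6", 1.23)
        _exo("C2", "N2", 1.34)
    elif resname == "A":
        _exo("C6", "N6", 1.34)
    elif resname == "U":
        _exo("C2", "O2", 1.22)
        _exo("C4", "O4", 1.23)
    elif resname == "C":
        _exo("C2", "O2", 1.22)
        _exo("C4", "N4", 1.34)
    else:  # pragma: no cover
        raise ValueError(f"unknown residue type {resname!r}")
    return atoms


def _sugar_template() -> dict[str, np.ndarray]:
    """Ribose + backbone arm in a local frame, C1' at the origin."""
    side = 1.48
    rad = side / (2.0 * math.sin(math.radians(36.0)))
    ring = ("C1'", "C2'", "C3'", "C4'", "O4'")
    atoms: dict[str, np.ndarray] = {}
    for k, name in enumerate(ring):
        ang = math.radians(90.0 - 72.0 * k)
        atoms[name] = np.array([rad * math.cos(ang), rad * math.sin(ang), 0.0])
    atoms["C3'"] = atoms["C3'"] + np.array([0.0, 0.0, 0.45])  # C3'-endo-ish pucker

    def _out(on: str, name: str, bond: float, dz: float) -> None:
        pos = atoms[on]
        u = pos.copy()
        u[2] = 0.0
        u = u / np.linalg.norm(u)
        atoms[name] = pos + bond * u + np.array([0.0, 0.0, dz])

    _out("C2'", "O2'", 1.41, -0.35)
    _out("C3'", "O3'", 1.42, 0.45)
    _out("C4'", "C5'", 1.51, 0.70)
    atoms["O5'"] = atoms["C5'"] + np.array([-0.4, 0.5, 1.2])
    atoms["P"] = atoms["O5'"] + np.array([-0.5, 0.3, 1.4])
    atoms["OP1"] = atoms["P"] + np.array([-1.2, -0.7, 0.5])
    atoms["OP2"] = atoms["P"] + np.array([0.9, -0.9, 0.8])
    c1 = atoms["C1'"].copy()
    return {name: pos - c1 for name, pos in atoms.items()}


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(math.radians(angle_deg) * axis).as_matrix()


def _nucleotide_template(resname: str, chi_deg: float) -> dict[str, np.ndarray]:
    """Full heavy-atom nucleotide: base in the z = 0 plane, glycosidic N at origin."""
    base = _hexagon_base(resname)
    purine = resname in ("A", "G")
    glyco = "N9" if purine else "N1"
    # glycosidic bond bisects the two ring neighbours of the glycosidic N
    nbr_a, nbr_b = ("C4", "C8") if purine else ("C2", "C6")
    u = base[glyco] - (base[nbr_a] + base[nbr_b]) / 2.0
    u = u / np.linalg.norm(u)
    origin = base[glyco].copy()
    base = {name: pos - origin for name, pos in base.items()}
    c1 = 1.48 * u

    sugar = _sugar_template()
    # orient the sugar: its pentagon in-plane -y axis (C1'->centre) maps to u,
    # its x axis to the base normal; then dial chi about the glycosidic bond.
    ex = np.array([0.0, 0.0, 1.0])
    ey = -u
    ez = np.cross(ex, ey)
    m = np.column_stack([ex, ey, ez])
    placed = {name: c1 + m @ pos for name, pos in sugar.items()}

    atoms = dict(base)
    atoms.update(placed)
    chi_ref = "C4" if resname in ("A", "G") else "C2"

    def _measure() -> float:
        return _dihedral4(atoms["O4'"], atoms["C1'"], atoms[glyco], atoms[chi_ref])

    def _spin(angle: float) -> None:
        rot = _axis_rotation(u, angle)
        for name in _SUGAR_ATOMS:
            atoms[name] = rot @ atoms[name]  # pivot: glycosidic N at origin

    # probe the rotation sense, then dial chi exactly
    before = _measure()
    _spin(1.0)
    sense = 1.0 if _normdeg(_measure() - before) > 0 else -1.0
    _spin(sense * _normdeg(chi_deg - _measure()))
    return atoms


def _dihedral4(p0, p1, p2, p3) -> float:
    from .geometry import dihedral_from_points

    return dihedral_from_points(p0, p1, p2, p3)


def _normdeg(angle: float) -> float:
    from .geometry import normalize_angle

    return normalize_angle(angle)


# ---------------------------------------------------------------------------
# Scaffold assembly

_RISE = 2.8
_TWIST = 32.7
_RADIUS = 4.2


def _place(template: dict[str, np.ndarray], matrix: np.ndarray, shift: np.ndarray) -> dict[str, np.ndarray]:
    return {name: matrix @ pos + shift for name, pos in template.items()}


def _residue_coords(conf: Conformation, residue: int) -> np.ndarray:
    return conf.coords[conf.residue_index == residue]


def _apply_to_residues(conf: Conformation, residues: Sequence[int], fn) -> None:
    mask = np.isin(conf.residue_index, list(residues))
    conf.coords[mask] = fn(conf.coords[mask])


def _assemble(poses: dict[int, tuple[np.ndarray, np.ndarray]], chis: dict[int, float]) -> Conformation:
    res_idx: list[int] = []
    res_name: list[str] = []
    atom_name: list[str] = []
    coords: list[np.ndarray] = []
    for i, resname in enumerate(SCAFFOLD_SEQUENCE, start=1):
        template = _nucleotide_template(resname, chis.get(i, -160.0))
        matrix, shift = poses[i]
        placed = _place(template, matrix, shift)
        for name, pos in placed.items():
            res_idx.append(i)
            res_name.append(resname)
            atom_name.append(name)
            coords.append(pos)
    return Conformation(np.array(res_idx), np.array(res_name, dtype=object),
                        np.array(atom_name, dtype=object), np.array(coords))


def _initial_poses() -> dict[int, tuple[np.ndarray, np.ndarray]]:
    poses: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    shift_in = np.array([_RADIUS, 0.0, 0.0])
    for i in range(1, 6):  # 5' strand of the stem, bases stacked along +z
        rz = _axis_rotation([0, 0, 1], _TWIST * i)
        poses[i] = (rz, rz @ shift_in + np.array([0.0, 0.0, _RISE * i]))
    flip = _axis_rotation([1, 0, 0], 180.0)
    for j in range(10, 15):  # 3' strand, antiparallel, paired with 15-j
        i = 15 - j
        rz = _axis_rotation([0, 0, 1], _TWIST * i + 165.0)
        m = rz @ flip
        poses[j] = (m, rz @ np.array([_RADIUS, 0.0, 0.0]) + np.array([0.0, 0.0, _RISE * i]))
    # loop starting guesses: continue the arc above the stem
    top = _RISE * 5
    loop_guess = {
        6: (_axis_rotation([0, 0, 1], _TWIST * 6), np.array([3.0, 2.0, top + 2.0])),
        7: (_axis_rotation([0, 1, 0], 70.0), np.array([6.5, -1.0, top + 5.0])),
        8: (_axis_rotation([1, 0, 0], -60.0), np.array([2.0, -4.5, top + 4.0])),
        9: (_axis_rotation([0, 0, 1], 200.0) @ _axis_rotation([1, 0, 0], 180.0),
            np.array([-1.5, -1.0, top + 3.0])),
    }
    poses.update(loop_guess)
    return poses


# native contact targets of the refined loop, Å; the latter entries are
# shape targets keeping non-bonded neighbours at realistic separations
_CONTACT_TARGETS: tuple[tuple[AtomRef, AtomRef, float], ...] = (
    ((9, "N1"), (6, "O2"), 2.90),
    ((9, "N2"), (6, "O2"), 3.25),
    ((6, "O2'"), (9, "O6"), 3.00),
    ((7, "O2'"), (9, "N7"), 3.00),
    ((8, "N4"), (6, "OP1"), 3.20),
)
_SHAPE_TARGETS: tuple[tuple[AtomRef, AtomRef, float], ...] = (
    ((6, "O2'"), (9, "N1"), 3.80),
    ((7, "O2'"), (9, "O6"), 4.20),
    ((9, "N9"), (6, "O2"), 4.60),
)


# Converged pose parameters (rotation vector + translation per movable loop
# residue U6,U7,C8,G9) of the deterministic refinement below; used as the
# starting point so the cached scaffold build only needs a short polish.
_POSE_X0 = np.array([
    -3.1235458540383432e+00, 1.9668684575450446e+00, -1.3402323982982238e+00,
    -2.0172309877522205e+00, 1.0913700059718481e+00, 3.4709813776888372e+00,
    -1.4183399723749357e+00, -5.0324652043830369e+00, 5.4807347856537580e-01,
    2.1859466304545969e+00, 2.8967593672981939e-01, 3.3541310559545581e-02,
    -1.3297809199406974e+00, 2.3680897481172197e-01, 2.6860138271551753e-01,
    2.4177249519723887e+00, -2.0883663605775999e+00, 3.7630929254368790e+00,
    1.6925620856924205e+01, 5.7888574193508910e+00, -1.3332329238976328e+00,
    4.0403003340853587e+00, 1.2936898347233106e-02, 2.2120932937302845e-01,
])


def _refine_loop(conf: Conformation) -> Conformation:
    """Rigidly adjust U7, C8 and G9 so the native contacts hit their targets.

    Deterministic Gauss-Newton least squares over 18 pose parameters
    (rotation vector + translation per residue) with a weak prior keeping
    each residue near its initial placement.
    """
    moving = (6, 7, 8, 9)
    centroids = {r: _residue_coords(conf, r).mean(axis=0) for r in moving}
    base_coords = conf.coords.copy()

    def _posed(params: np.ndarray) -> np.ndarray:
        coords = base_coords.copy()
        for k, r in enumerate(moving):
            rotvec = params[6 * k: 6 * k + 3]
            trans = params[6 * k + 3: 6 * k + 6]
            mask = conf.residue_index == r
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            coords[mask] = (coords[mask] - centroids[r]) @ rot.T + centroids[r] + trans
        return coords

    all_targets = _CONTACT_TARGETS + _SHAPE_TARGETS
    idx = {(ref): conf.atom_index(ref) for pair in all_targets for ref in pair[:2]}
    target_pairs = {frozenset((conf.atom_index(a), conf.atom_index(b))) for a, b, _ in all_targets}
    clash_floor = 2.4  # Å; soft lower bound on non-bonded separations

    # static index structure for the vectorised clash penalty
    clash_rows: list[np.ndarray] = []
    clash_cols: list[np.ndarray] = []
    clash_excl: list[np.ndarray] = []
    for r in moving:
        rows = np.flatnonzero(conf.residue_index == r)
        cols = np.flatnonzero(conf.residue_index != r)
        excl = np.zeros((len(rows), len(cols)), dtype=bool)
        row_pos = {int(a): k for k, a in enumerate(rows)}
        col_pos = {int(a): k for k, a in enumerate(cols)}
        for pair in target_pairs:
            a, b = tuple(pair)
            if a in row_pos and b in col_pos:
                excl[row_pos[a], col_pos[b]] = True
            if b in row_pos and a in col_pos:
                excl[row_pos[b], col_pos[a]] = True
        clash_rows.append(rows)
        clash_cols.append(cols)
        clash_excl.append(excl)

    def _clash_residuals(coords: np.ndarray) -> float:
        total = 0.0
        for rows, cols, excl in zip(clash_rows, clash_cols, clash_excl):
            d2 = ((coords[rows][:, None] - coords[cols][None]) ** 2).sum(-1)
            pen = clash_floor - np.sqrt(d2, out=d2)
            pen[pen < 0.0] = 0.0
            pen[excl] = 0.0
            total += float(np.sum(pen * pen))
        return total

    def _residuals(params: np.ndarray) -> np.ndarray:
        coords = _posed(params)
        res = [
            np.linalg.norm(coords[idx[a]] - coords[idx[b]]) - target
            for a, b, target in _CONTACT_TARGETS
        ]
        shape = [
            0.2 * (np.linalg.norm(coords[idx[a]] - coords[idx[b]]) - target)
            for a, b, target in _SHAPE_TARGETS
        ]
        clash = 0.5 * _clash_residuals(coords)
        return np.concatenate([np.asarray(res), np.asarray(shape), [clash], 0.01 * params])

    x0 = _POSE_X0 if len(_POSE_X0) == 6 * len(moving) else np.zeros(6 * len(moving))
    # short polish: x0 is already converged, a few LM steps absorb any drift
    sol = least_squares(_residuals, x0, method="lm",
                        xtol=1e-10, ftol=1e-10, max_nfev=120)
    out = conf.with_coords(_posed(sol.x))
    for a, b, target in _CONTACT_TARGETS:
        if abs(distance(out, a, b) - target) > 0.05:
            raise GenerationError(
                f"loop refinement missed contact {a}-{b}: "
                f"{distance(out, a, b):.3f} vs {target:.3f} Å"
            )
    return out


@functools.lru_cache(maxsize=1)
def _scaffold_cached() -> Conformation:
    chis = {i: -160.0 for i in range(1, 15)}
    chis[9] = 20.0  # syn loop guanosine
    conf = _assemble(_initial_poses(), chis)
    conf = _refine_loop(conf)
    feats = extract_features(conf, AtomMap(), conf)
    label = classify_features(feats)
    if label is not StateLabel.NATIVE:
        raise GenerationError(f"scaffold classifies as {label}, expected native")
    return conf


def build_reference_scaffold() -> Conformation:
    """Deterministic native 14-mer hairpin scaffold (fresh copy per call)."""
    return _scaffold_cached().copy()


# ---------------------------------------------------------------------------
# Perturbation operators

def _translate_residues(conf: Conformation, residues: Sequence[int], vec: np.ndarray) -> None:
    _apply_to_residues(conf, residues, lambda c: c + vec)


def _rotate_residues_about(conf: Conformation, residues: Sequence[int],
                           point: np.ndarray, axis: np.ndarray, angle_deg: float) -> None:
    rot = _axis_rotation(axis, angle_deg)
    _apply_to_residues(conf, residues, lambda c: (c - point) @ rot.T + point)


def _set_contact(conf: Conformation, residues: Sequence[int], moving_atom: AtomRef,
                 fixed_atom: AtomRef, target: float) -> None:
    """Translate *residues* along the contact axis so |moving-fixed| = target."""
    p = conf.position(moving_atom)
    q = conf.position(fixed_atom)
    sep = p - q
    norm = float(np.linalg.norm(sep))
    _translate_residues(conf, residues, (target / norm - 1.0) * sep)


def _rotate_chi(conf: Conformation, residue: int, target_chi: float) -> None:
    """Rotate the base of *residue* about its glycosidic bond to set chi."""
    resname = conf.residue_name_of(residue)
    glyco = "N9" if resname in ("A", "G") else "N1"
    chi_ref = "C4" if resname in ("A", "G") else "C2"
    axis = conf.position((residue, glyco)) - conf.position((residue, "C1'"))
    pivot = conf.position((residue, glyco)).copy()
    names = set(_BASE_ATOMS[resname])
    mask = (conf.residue_index == residue) & np.array([a in names for a in conf.atom_name])

    def _measure() -> float:
        return dihedral(conf, (residue, "O4'"), (residue, "C1'"),
                        (residue, glyco), (residue, chi_ref))

    def _spin(angle: float) -> None:
        rot = _axis_rotation(axis, angle)
        conf.coords[mask] = (conf.coords[mask] - pivot) @ rot.T + pivot

    before = _measure()
    _spin(1.0)
    sense = 1.0 if _normdeg(_measure() - before) > 0 else -1.0
    _spin(sense * _normdeg(target_chi - _measure()))


def _jitter(conf: Conformation, rng: np.random.Generator, sd: float) -> None:
    if sd > 0:
        conf.coords[:] = conf.coords + rng.normal(0.0, sd, size=conf.coords.shape)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _g9_exit_direction(conf: Conformation, m: AtomMap) -> np.ndarray:
    d = (conf.position(m.g9_n1) - conf.position(m.u6_o2)) + (
        conf.position(m.g9_o6) - conf.position(m.u6_o2p)
    )
    return d / np.linalg.norm(d)


def _sample_anti(rng: np.random.Generator) -> float:
    if rng.random() < 0.5:
        return float(rng.uniform(-170.0, -40.0))
    return float(rng.uniform(125.0, 175.0))


def _perturb_for_state(state: StateLabel, conf: Conformation, m: AtomMap,
                       rng: np.random.Generator) -> None:
    if state is StateLabel.NATIVE:
        _rotate_chi(conf, 9, float(rng.uniform(-10.0, 60.0)))
    elif state is StateLabel.SUGAR_BASE_N7_LOST:
        _set_contact(conf, [7], m.u7_o2p, m.g9_n7, float(rng.uniform(3.7, 5.5)))
    elif state is StateLabel.BPH7_LOST:
        _set_contact(conf, [8], m.c8_n4, m.u6_pro_rp, float(rng.uniform(3.9, 4.9)))
    elif state is StateLabel.BOTH_SUGAR_BASE_LOST:
        # swing G9 about a random axis through N1: keeps d(N1-O2), moves O6
        axis = _random_unit(rng)
        angle = float(rng.choice([-1.0, 1.0]) * rng.uniform(20.0, 70.0))
        _rotate_residues_about(conf, [9], conf.position(m.g9_n1).copy(), axis, angle)
        _set_contact(conf, [7], m.u7_o2p, m.g9_n7, float(rng.uniform(3.7, 5.0)))
    elif state is StateLabel.C8_BULGE_ONE_SUGAR_BASE_LOST:
        _set_contact(conf, [7], m.u7_o2p, m.g9_n7, float(rng.uniform(4.1, 6.5)))
        _set_contact(conf, [8], m.c8_n4, m.u6_pro_rp, float(rng.uniform(5.2, 8.0)))
    elif state is StateLabel.G9_BULGE_SYN:
        step = _g9_exit_direction(conf, m) * float(rng.uniform(2.8, 4.2))
        _translate_residues(conf, [9], step)
    elif state is StateLabel.G9_BULGE_ANTI:
        step = _g9_exit_direction(conf, m) * float(rng.uniform(2.8, 4.2))
        _translate_residues(conf, [9], step)
        _rotate_chi(conf, 9, _sample_anti(rng))
    elif state is StateLabel.G9_BACK_IN_POCKET_ANTI:
        _rotate_chi(conf, 9, _sample_anti(rng))
    elif state is StateLabel.U6U7C8_BULGE:
        away = conf.position(m.u6_o2) - conf.position(m.g9_n1)
        away = away / np.linalg.norm(away)
        _translate_residues(conf, [6], away * float(rng.uniform(8.0, 11.0)))
    elif state is StateLabel.LOOP_DISRUPTED:
        step = _g9_exit_direction(conf, m) * float(rng.uniform(3.2, 4.5))
        _translate_residues(conf, [9], step)
        _rotate_chi(conf, 9, _sample_anti(rng))
        _translate_residues(conf, [7], _random_unit(rng) * float(rng.uniform(6.5, 8.5)))
    elif state is StateLabel.STEM_LOOP_DISRUPTED:
        for res in range(1, 15):
            _translate_residues(conf, [res], _random_unit(rng) * float(rng.uniform(5.0, 9.0)))
    else:
        raise ValueError(f"cannot generate frames for state {state}")


def generate_state_conformer(
    state: StateLabel,
    cfg: GeneratorConfig | None = None,
    atom_map: AtomMap | None = None,
    classifier: ClassifierConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Conformation:
    """A conformer that classifies as *state* against the scaffold reference.

    Constrained randomisation (rigid residue moves, glycosidic rotation,
    Gaussian jitter) followed by verification through the classifier;
    rejection sampling with a bounded retry budget, never silent.
    """
    state = StateLabel(state)
    if state is StateLabel.UNCLASSIFIED:
        raise ValueError("cannot target the unclassified label")
    cfg = cfg or GeneratorConfig()
    atom_map = atom_map or AtomMap()
    classifier = classifier or ClassifierConfig()
    if rng is None:
        state_tag = list(StateLabel).index(state)
        rng = np.random.default_rng([cfg.seed, state_tag])
    reference = _scaffold_cached()
    for _ in range(cfg.max_retries):
        conf = reference.copy()
        _perturb_for_state(state, conf, atom_map, rng)
        _jitter(conf, rng, cfg.jitter_sd)
        feats = extract_features(conf, atom_map, reference)
        if classify_features(feats, classifier) is state:
            return conf
    raise GenerationError(f"could not realise state {state} in {cfg.max_retries} attempts")


# ---------------------------------------------------------------------------
# Markov timelines

@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix over an ordered list of state labels."""

    states: list[StateLabel]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.states)
        if self.P.shape != (n, n):
            raise ValueError("P must be square over the state list")
        if np.any(self.P < 0) or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of P must be non-negative and sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution from the unit-eigenvalue left eigenvector."""
        w, v = np.linalg.eig(self.P.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


def generate_markov_timeline(
    tm: TransitionMatrix,
    n: int,
    cfg: GeneratorConfig | None = None,
) -> StateTimeline:
    """Seeded chain of length *n* sampled from *tm*, started at stationarity."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng([cfg.seed, 1001])
    pi = tm.stationary()
    cum = np.cumsum(tm.P, axis=1)
    states = np.empty(n, dtype=int)
    states[0] = int(np.searchsorted(np.cumsum(pi), rng.random()))
    u = rng.random(n)
    for t in range(1, n):
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t]))
    labels = [tm.states[s] for s in states]
    return StateTimeline(labels, np.arange(n, dtype=float), np.ones(n))


# ---------------------------------------------------------------------------
# Two-state ensembles

def generate_unfolded_conformer(rng: np.random.Generator, jitter_sd: float = 0.04) -> Conformation:
    """An extended-chain conformer (εRMSD >= 0.7 against the scaffold)."""
    conf = _scaffold_cached().copy()
    for k, res in enumerate(conf.residues()):
        mask = conf.residue_index == res
        centroid = conf.coords[mask].mean(axis=0)
        rot = Rotation.random(random_state=rng).as_matrix()
        target = np.array([7.0 * k, 2.0 * (k % 2), 0.0])
        conf.coords[mask] = (conf.coords[mask] - centroid) @ rot.T + target
    _jitter(conf, rng, jitter_sd)
    return conf


def generate_two_state_ensemble(
    p_star: float,
    n: int,
    cfg: GeneratorConfig | None = None,
    pool_size: int = 16,
) -> tuple[list[Conformation], np.ndarray]:
    """Frames drawn Bernoulli(p*) from folded / unfolded conformer pools.

    Folded pool members are jittered scaffolds verified to lie below the
    εRMSD folding threshold; unfolded members are extended chains verified
    to lie at or above it.  Returns the frames and the ground-truth folded
    indicator.  Frames reference shared pool conformers.
    """
    if not 0.0 < p_star <= 1.0:
        raise ValueError("p_star must be in (0, 1]")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng([cfg.seed, 2002])
    reference = _scaffold_cached()
    folded_pool: list[Conformation] = []
    unfolded_pool: list[Conformation] = []
    for _ in range(pool_size):
        for attempt in range(cfg.max_retries):
            c = reference.copy()
            _jitter(c, rng, max(cfg.jitter_sd, 0.05))
            if _ermsd_fn(c, reference) < _FOLDED_THRESHOLD:
                folded_pool.append(c)
                break
        else:
            raise GenerationError("could not realise a folded pool member")
        for attempt in range(cfg.max_retries):
            c = generate_unfolded_conformer(rng, cfg.jitter_sd)
            if _ermsd_fn(c, reference) >= _FOLDED_THRESHOLD:
                unfolded_pool.append(c)
                break
        else:
            raise GenerationError("could not realise an unfolded pool member")
    indicator = rng.random(n) < p_star
    picks = rng.integers(0, pool_size, size=n)
    frames = [
        (folded_pool if folded else unfolded_pool)[k]
        for folded, k in zip(indicator, picks)
    ]
    return frames, indicator


# ---------------------------------------------------------------------------
# Noisy NMR observable tables

_BACKBONE_QUADS: tuple[tuple[str, str, str, str], ...] = (
    ("P", "O5'", "C5'", "C4'"),
    ("O5'", "C5'", "C4'", "C3'"),
    ("C5'", "C4'", "C3'", "O3'"),
)
_SUGAR_QUADS: tuple[tuple[str, str, str, str], ...] = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
)
_BACKBONE_SETS = ("HCOP", "CCOP")


def _random_close_pair(
    conf: Conformation, rng: np.random.Generator, max_dist: float = 6.0
) -> tuple[AtomRef, AtomRef]:
    n = len(conf)
    for _ in range(10000):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        if float(np.linalg.norm(conf.coords[i] - conf.coords[j])) < max_dist:
            return (
                (int(conf.residue_index[i]), str(conf.atom_name[i])),
                (int(conf.residue_index[j]), str(conf.atom_name[j])),
            )
    raise GenerationError("no close atom pair found")


def generate_nmr_dataset(
    frames: Sequence[Conformation],
    sigma: float,
    cfg: GeneratorConfig | None = None,
    counts: tuple[int, int, int, int] = (63, 33, 253, 27),
    noise_sd: float | None = None,
    weights: Sequence[float] | None = None,
) -> ObservableTable:
    """Observable table back-calculated from *frames* with Gaussian noise.

    *sigma* is the reported experimental error of every row; *noise_sd*
    (default: sigma) is the SD of the noise actually added, so a noiseless
    self-consistent table is obtained with ``noise_sd=0``.  Class counts
    default to 63 backbone couplings, 33 sugar couplings, 253 NOEs and 27
    ambiguous NOEs.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if noise_sd is None:
        noise_sd = sigma
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng([cfg.seed, 3003])
    frames = list(frames)
    first = frames[0]
    residues = first.residues()
    observables: list[Observable] = []
    n_bb, n_sugar, n_noe, n_amb = counts

    def _add(obs_id: str, klass: str, atoms: tuple[AtomRef, ...], karplus: str = "") -> None:
        calc = back_calculate(
            Observable(obs_id, klass, atoms, exp_value=0.0, exp_error=sigma, karplus_set=karplus),
            frames, weights, DEFAULT_KARPLUS_SETS,
        )
        exp = calc + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else calc
        observables.append(Observable(obs_id, klass, atoms, exp_value=exp,
                                      exp_error=sigma, karplus_set=karplus))

    for k in range(n_bb):
        res = int(rng.choice(residues))
        quad = _BACKBONE_QUADS[int(rng.integers(len(_BACKBONE_QUADS)))]
        karplus = _BACKBONE_SETS[int(rng.integers(len(_BACKBONE_SETS)))]
        _add(f"bb{k}", "backbone_3J", tuple((res, a) for a in quad), karplus)
    for k in range(n_sugar):
        res = int(rng.choice(residues))
        quad = _SUGAR_QUADS[int(rng.integers(len(_SUGAR_QUADS)))]
        _add(f"sug{k}", "sugar_3J", tuple((res, a) for a in quad), "HCCH")
    for k in range(n_noe):
        a, b = _random_close_pair(first, rng)
        _add(f"noe{k}", "NOE", (a, b))
    for k in range(n_amb):
        n_pairs = int(rng.integers(2, 5))
        atoms: list[AtomRef] = []
        for _ in range(n_pairs):
            a, b = _random_close_pair(first, rng)
            atoms.extend([a, b])
        _add(f"amb{k}", "ambNOE", tuple(atoms))
    return ObservableTable(observables, karplus_sets=dict(DEFAULT_KARPLUS_SETS))
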