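"""Frame-level geometric primitives for nucleic-acid conformers.

Distances, signed torsions, angular-window membership, optimal-superposition
RMSD and the Altona–Sundaralingam sugar-pucker descriptor, all operating on a
lightweight :class:`Conformation` container (residue-indexed heavy-atom
coordinates in Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomLookupError",
    "DegenerateGeometryError",
    "Conformation",
    "AtomRef",
    "AtomMap",
    "AngularWindow",
    "SYN_WINDOW",
    "ANTI_WINDOW",
    "normalize_angle",
    "in_window",
    "distance",
    "dihedral",
    "superpose_rmsd",
    "pseudorotation_phase",
    "phase_from_torsions",
    "torsions_from_phase",
    "pucker_class",
]


class AtomLookupError(KeyError):
    """An atom reference does not resolve to exactly one atom."""


class DegenerateGeometryError(ValueError):
    """Geometry is degenerate (zero-length bond, collinear axis, zero amplitude)."""


#: An atom reference: (1-based residue index, atom name).
AtomRef = tuple[int, str]


@dataclass
class Conformation:
    """One frame of heavy-atom coordinates.

    Parameters
    ----------
    residue_index : (n,) int array, 1-based.
    residue_name : (n,) str array (e.g. ``"G"``, ``"U"``).
    atom_name : (n,) str array, canonical PDB v3 names with prime characters
        (``O2'``, ``OP1`` ...).
    coords : (n, 3) float array, Å.
    frame_time : optional time stamp, arbitrary units.
    """

    residue_index: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    coords: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_index)
        if not (len(self.residue_name) == len(self.atom_name) == len(self.coords) == n):
            raise ValueError("field lengths differ")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._index: dict[AtomRef, int] = {}
        for i in range(n):
            key = (int(self.residue_index[i]), str(self.atom_name[i]))
            if key in self._index:
                raise ValueError(f"duplicate atom {key[0]}:{key[1]}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.residue_index)

    def atom_index(self, ref: AtomRef) -> int:
        try:
            return self._index[(int(ref[0]), str(ref[1]))]
        except KeyError:
            raise AtomLookupError(f"atom {ref[0]}:{ref[1]} not found") from None

    def has_atom(self, ref: AtomRef) -> bool:
        return (int(ref[0]), str(ref[1])) in self._index

    def position(self, ref: AtomRef) -> np.ndarray:
        return self.coords[self.atom_index(ref)]

    def residues(self) -> list[int]:
        """Distinct residue indices in order of first appearance."""
        seen: dict[int, None] = {}
        for r in self.residue_index:
            seen.setdefault(int(r), None)
        return list(seen)

    def residue_name_of(self, residue: int) -> str:
        mask = self.residue_index == residue
        if not mask.any():
            raise AtomLookupError(f"residue {residue} not found")
        return str(self.residue_name[mask][0])

    def atoms_of(self, residue: int) -> list[str]:
        mask = self.residue_index == residue
        return [str(a) for a in self.atom_name[mask]]

    def copy(self) -> "Conformation":
        return Conformation(
            self.residue_index.copy(),
            self.residue_name.copy(),
            self.atom_name.copy(),
            self.coords.copy(),
            self.frame_time,
        )

    def with_coords(self, coords: np.ndarray, frame_time: float | None = None) -> "Conformation":
        return Conformation(
            self.residue_index,
            self.residue_name,
            self.atom_name,
            np.asarray(coords, dtype=float),
            self.frame_time if frame_time is None else frame_time,
        )


# Loop numbering of the 14-mer hairpin: stem 1-5 / loop U6 U7 C8 G9 / stem 10-14.
LOOP_RESIDUES: tuple[int, ...] = (6, 7, 8, 9)

# PDB atom names regarded as heavy (non-hydrogen) — everything we store is
# heavy; hydrogens are never used by any criterion.


@dataclass(frozen=True)
class AtomMap:
    """Named references for every monitored interaction of the UUCG loop.

    Defaults follow the 2KOC-style numbering (loop U6,U7,C8,G9).  ``pro_rp``
    is the pro-R phosphate oxygen of U6, stored under its PDB v3 name OP1.
    """

    u6_o2: AtomRef = (6, "O2")
    u6_o2p: AtomRef = (6, "O2'")
    u6_pro_rp: AtomRef = (6, "OP1")
    u7_o2p: AtomRef = (7, "O2'")
    c8_n4: AtomRef = (8, "N4")
    g9_n1: AtomRef = (9, "N1")
    g9_n2: AtomRef = (9, "N2")
    g9_n7: AtomRef = (9, "N7")
    g9_o6: AtomRef = (9, "O6")
    g9_o4p: AtomRef = (9, "O4'")
    g9_c1p: AtomRef = (9, "C1'")
    g9_n9: AtomRef = (9, "N9")
    g9_c4: AtomRef = (9, "C4")
    loop_residues: tuple[int, ...] = LOOP_RESIDUES

    def all_refs(self) -> list[AtomRef]:
        return [
            self.u6_o2, self.u6_o2p, self.u6_pro_rp, self.u7_o2p, self.c8_n4,
            self.g9_n1, self.g9_n2, self.g9_n7, self.g9_o6,
            self.g9_o4p, self.g9_c1p, self.g9_n9, self.g9_c4,
        ]

    def validate(self, conf: Conformation) -> None:
        for ref in self.all_refs():
            conf.atom_index(ref)

    def loop_heavy_atoms(self, conf: Conformation) -> list[AtomRef]:
        out = []
        for res in self.loop_residues:
            out.extend((res, name) for name in conf.atoms_of(res))
        return out

    def all_heavy_atoms(self, conf: Conformation) -> list[AtomRef]:
        out = []
        for res in conf.residues():
            out.extend((res, name) for name in conf.atoms_of(res))
        return out


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees onto (−180, 180]."""
    a = math.fmod(float(angle), 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class AngularWindow:
    """Union of closed angular intervals on (−180°, 180°].

    Endpoints are inclusive; intervals may jointly wrap through ±180° (e.g.
    the anti/high-anti union [−180, −25] ∪ [115, 180]).
    """

    intervals: tuple[tuple[float, float], ...]

    def __contains__(self, angle: float) -> bool:
        return in_window(angle, self)


#: syn glycosidic window of the loop guanosine, degrees.
SYN_WINDOW = AngularWindow(((-25.0, 115.0),))
#: anti/high-anti union, degrees.
ANTI_WINDOW = AngularWindow(((-180.0, -25.0), (115.0, 180.0)))


def in_window(angle: float, window: AngularWindow) -> bool:
    """True iff *angle* (degrees, any branch) lies in the window.

    The angle is normalized to (−180, 180] first, so membership is unchanged
    by adding multiples of 360°.  −180° and 180° denote the same direction and
    an interval endpoint at either matches both.
    """
    a = normalize_angle(angle)
    for lo, hi in window.intervals:
        if lo <= a <= hi:
            return True
        # (−180, 180] normalization puts the wrap point at 180; an interval
        # touching −180 must also capture a = 180.
        if lo <= a - 360.0 <= hi or lo <= a + 360.0 <= hi:
            return True
    return False


def distance(conf: Conformation, a: AtomRef, b: AtomRef) -> float:
    """Euclidean distance in Å between two referenced atoms."""
    return float(np.linalg.norm(conf.position(a) - conf.position(b)))


def dihedral(conf: Conformation, a: AtomRef, b: AtomRef, c: AtomRef, d: AtomRef) -> float:
    """Signed torsion a-b-c-d in degrees on (−180, 180], IUPAC convention (cis = 0°)."""
    p = [conf.position(r) for r in (a, b, c, d)]
    return dihedral_from_points(p[0], p[1], p[2], p[3])


def dihedral_from_points(p0, p1, p2, p3) -> float:
    """Torsion angle of four points in degrees, cis = 0°.

    Positive sense: right-handed rotation of the c-d bond about the b→c
    axis, the convention shared by the major trajectory-analysis packages.
    Invariant under order reversal (a,b,c,d) → (d,c,b,a).
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        raise DegenerateGeometryError("zero-length central bond")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise DegenerateGeometryError("collinear atoms: torsion undefined")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return normalize_angle(math.degrees(math.atan2(y, x)))


def _selected_coords(conf: Conformation, selection: Sequence[AtomRef]) -> np.ndarray:
    idx = [conf.atom_index(ref) for ref in selection]
    return conf.coords[idx]


def superpose_rmsd(
    mobile: Conformation,
    reference: Conformation,
    selection: Sequence[AtomRef],
) -> float:
    """Least-squares RMSD (Å) after optimal rigid superposition over *selection*.

    The optimal rotation is the Kabsch solution (SVD with reflection guard,
    via :func:`scipy.spatial.transform.Rotation.align_vectors`); translation
    is removed by centroid subtraction.  Both structures must resolve the
    selection in the same order.
    """
    selection = list(selection)
    if len(selection) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 atoms")
    x = _selected_coords(mobile, selection)
    y = _selected_coords(reference, selection)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([xc, yc])) < 2:
        raise DegenerateGeometryError("selection is collinear")
    _, rssd = Rotation.align_vectors(yc, xc)
    return float(rssd / math.sqrt(len(selection)))


def raw_rmsd(mobile: Conformation, reference: Conformation, selection: Sequence[AtomRef]) -> float:
    """RMSD without superposition (used only as an upper bound in diagnostics)."""
    x = _selected_coords(mobile, list(selection))
    y = _selected_coords(reference, list(selection))
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Sugar pucker (Altona–Sundaralingam pseudorotation)

_SUGAR_TORSION_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)


def phase_from_torsions(nu: Sequence[float]) -> tuple[float, float]:
    """Pseudorotation phase P in [0, 360) and amplitude τm from ν0..ν4 (degrees).

    tan P = (ν4 + ν1 − ν3 − ν0) / (2 ν2 (sin 36° + sin 72°)); τm = ν2 / cos P.
    """
    nu = [float(v) for v in nu]
    if len(nu) != 5:
        raise ValueError("need the five ring torsions nu0..nu4")
    num = nu[4] + nu[1] - nu[3] - nu[0]
    den = 2.0 * nu[2] * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    if abs(num) < 1e-12 and abs(den) < 1e-12:
        raise DegenerateGeometryError("zero pucker amplitude: phase undefined")
    p = math.degrees(math.atan2(num, den)) % 360.0
    cos_p = math.cos(math.radians(p))
    tau_m = nu[2] / cos_p if abs(cos_p) > 1e-12 else num / (
        2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))) * math.sin(math.radians(p))
    )
    if abs(tau_m) < 1e-9:
        raise DegenerateGeometryError("zero pucker amplitude: phase undefined")
    return p, abs(tau_m)


def torsions_from_phase(p: float, tau_m: float) -> list[float]:
    """Inverse of :func:`phase_from_torsions`: νj = τm cos(P + 144°(j−2))."""
    return [tau_m * math.cos(math.radians(p + 144.0 * (j - 2))) for j in range(5)]


def pucker_class(p: float) -> str:
    """north (C3'-endo) for P∈[0,36), south (C2'-endo) for P∈[144,180), else 'other'."""
    p = p % 360.0
    if 0.0 <= p < 36.0:
        return "north"
    if 144.0 <= p < 180.0:
        return "south"
    return "other"


def pseudorotation_phase(conf: Conformation, residue: int) -> tuple[float, float, str]:
    """Sugar pseudorotation of one residue: (P degrees, τm degrees, pucker class)."""
    nu = []
    for quad in _SUGAR_TORSION_ATOMS:
        refs = [(residue, name) for name in quad]
        for ref in refs:
            if not conf.has_atom(ref):
                raise AtomLookupError(f"missing sugar atom {ref[0]}:{ref[1]}")
        nu.append(dihedral(conf, *refs))
    p, tau = phase_from_torsions(nu)
    return p, tau, pucker_class(p)


def rigid_transform(
    conf: Conformation,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> Conformation:
    """Apply a rigid transform (rotation about the origin, then translation)."""
    coords = conf.coords
    if rotation is not None:
        coords = coords @ np.asarray(rotation, float).T
    if translation is not None:
        coords = coords + np.asarray(translation, float)
    return conf.with_coords(coords)
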