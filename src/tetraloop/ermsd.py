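"""Base-centric εRMSD metric between nucleic-acid conformers.

Each nucleobase is reduced to a local orthonormal frame anchored on its
six-membered ring.  The position of every other base in that frame,
rescaled anisotropically (a = 5 Å in-plane, b = 3 Å normal), is mapped
through a smooth bounded 4-vector G; εRMSD is the root-mean-square
difference of all pairwise G vectors between two structures, normalised by
the number of residues.  Pairs whose scaled separation exceeds the cutoff
(2.4) contribute zero, which makes the metric local and contact-driven.

The folded/unfolded indicator uses the 0.7 threshold adopted for two-state
folding analysis of the UUCG tetraloop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import AtomLookupError, Conformation, DegenerateGeometryError

__all__ = [
    "SCALE_A",
    "SCALE_B",
    "CUTOFF",
    "FOLDED_THRESHOLD",
    "RING_ATOMS",
    "BaseFrame",
    "base_frame",
    "gvectors",
    "ermsd",
    "is_folded",
]

#: In-plane ellipsoidal scale (Å).
SCALE_A = 5.0
#: Out-of-plane ellipsoidal scale (Å).
SCALE_B = 3.0
#: Cutoff on the scaled inter-base distance (dimensionless).
CUTOFF = 2.4
#: εRMSD below which a conformer counts as folded.
FOLDED_THRESHOLD = 0.7

# Six-membered-ring atoms per residue type.  Purine and pyrimidine six-rings
# share the PDB names N1,C2,N3,C4,C5,C6.  Modified residues are rejected.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


@dataclass(frozen=True)
class BaseFrame:
    """Local frame of one base: ring-centroid origin and right-handed axes.

    Convention: origin is the centroid of the six ring atoms; z is the
    best-fit ring normal with its sign fixed by (C2−o)×(C4−o); x is the
    in-plane projection of C2−o; y completes the right-handed triad.
    """

    origin: np.ndarray
    axes: np.ndarray  # rows are x, y, z


def base_frame(conf: Conformation, residue: int) -> BaseFrame:
    """Build the local base frame of *residue*."""
    resname = conf.residue_name_of(residue)
    key = resname.strip().upper()[-1] if resname.strip() else resname
    if key not in RING_ATOMS:
        raise AtomLookupError(f"residue type {resname!r} has no tabulated ring atoms")
    names = RING_ATOMS[key]
    coords = np.array([conf.position((residue, n)) for n in names])
    origin = coords.mean(axis=0)
    centered = coords - origin
    # Best-fit normal: singular vector of the smallest singular value.
    _, _, vt = np.linalg.svd(centered)
    z = vt[2]
    c2 = conf.position((residue, "C2")) - origin
    c4 = conf.position((residue, "C4")) - origin
    ref_normal = np.cross(c2, c4)
    if np.linalg.norm(ref_normal) < 1e-9:
        raise DegenerateGeometryError("degenerate ring geometry")
    if float(np.dot(z, ref_normal)) < 0:
        z = -z
    x = c2 - np.dot(c2, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateGeometryError("C2 lies on the ring normal")
    x = x / nx
    y = np.cross(z, x)
    return BaseFrame(origin=origin, axes=np.vstack([x, y, z]))


def _frames(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    residues = conf.residues()
    origins = np.empty((len(residues), 3))
    axes = np.empty((len(residues), 3, 3))
    for i, res in enumerate(residues):
        fr = base_frame(conf, res)
        origins[i] = fr.origin
        axes[i] = fr.axes
    return origins, axes


def gvectors(conf: Conformation, cutoff: float = CUTOFF) -> np.ndarray:
    """G vectors of all ordered residue pairs (i≠j), shape (n, n, 4).

    For pair (i, j) the vector r from base i's origin to base j's origin is
    expressed in base i's axes and scaled to r̃ = (x/a, y/a, z/b).  With
    ρ = |r̃| and γ = π/cutoff,

        G = (sin(γρ)·x̃/ρ, sin(γρ)·ỹ/ρ, sin(γρ)·z̃/ρ, 1 + cos(γρ))

    for ρ < cutoff and G = 0 otherwise.  |G| ≤ 2, attained at ρ = 0.
    """
    origins, axes = _frames(conf)
    n = len(origins)
    sep = origins[None, :, :] - origins[:, None, :]  # (i, j, 3): j in i's lab frame
    local = np.einsum("iab,ijb->ija", axes, sep)  # rows of axes are the basis
    scaled = local / np.array([SCALE_A, SCALE_A, SCALE_B])
    rho = np.linalg.norm(scaled, axis=2)
    np.fill_diagonal(rho, np.inf)
    gamma = math.pi / cutoff
    g = np.zeros((n, n, 4))
    inside = rho < cutoff
    rho_safe = np.where(inside, rho, 1.0)
    g[..., :3] = (np.where(inside, np.sin(gamma * rho_safe) / rho_safe, 0.0))[..., None] * scaled
    g[..., 3] = np.where(inside, 1.0 + np.cos(gamma * rho_safe), 0.0)
    return g


def ermsd(conf: Conformation, reference: Conformation, cutoff: float = CUTOFF) -> float:
    """εRMSD between *conf* and *reference* (same residue sequence)."""
    res_a = [conf.residue_name_of(r) for r in conf.residues()]
    res_b = [reference.residue_name_of(r) for r in reference.residues()]
    if res_a != res_b:
        raise ValueError("residue sequences differ between structures")
    ga = gvectors(conf, cutoff)
    gb = gvectors(reference, cutoff)
    n = ga.shape[0]
    return float(np.sqrt(np.sum((ga - gb) ** 2) / n))


def is_folded(
    conf: Conformation,
    reference: Conformation,
    threshold: float = FOLDED_THRESHOLD,
) -> bool:
    """True iff εRMSD against the native reference is below *threshold*."""
    return ermsd(conf, reference) < threshold
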