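"""Back-calculation of NMR observables from a conformer ensemble.

Four observable classes are supported: backbone and sugar 3J scalar
couplings (Karplus relation on a structural torsion), NOEs (r^-6 ensemble
averaging, compared as effective distances in Å) and ambiguous NOEs (sum of
r^-6 contributions from 2–4 proton pairs before averaging).  Agreement with
experiment is scored per class as the mean squared sigma-normalised
residual, and the classes are combined into a total chi^2 as a weighted
arithmetic mean with observable counts as default weights.

Karplus coefficient sets are configuration data: the shipped defaults are
standard literature parameterisations (Haasnoot-type H-C-C-H for sugar
couplings, Lankhorst H-C-O-P and a C-C-O-P set for the backbone) and can be
overridden or extended by the caller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AtomLookupError, AtomRef, Conformation, dihedral, distance

__all__ = [
    "OBSERVABLE_CLASSES",
    "KarplusSet",
    "DEFAULT_KARPLUS_SETS",
    "Observable",
    "ObservableTable",
    "Chi2Report",
    "karplus_3j",
    "noe_effective",
    "ambnoe_effective",
    "chi2_total",
    "read_observable_table",
    "write_observable_table",
]

OBSERVABLE_CLASSES = ("backbone_3J", "sugar_3J", "NOE", "ambNOE")


@dataclass(frozen=True)
class KarplusSet:
    """Karplus coefficients: J(θ) = A·cos²(θ+offset) + B·cos(θ+offset) + C (Hz)."""

    A: float
    B: float
    C: float
    offset: float = 0.0  # degrees added to the structural torsion


#: Literature default coefficient sets, editable by the caller.
DEFAULT_KARPLUS_SETS: dict[str, KarplusSet] = {
    # H-C-C-H sugar couplings (Haasnoot-type reduced form)
    "HCCH": KarplusSet(A=9.67, B=-2.03, C=0.0),
    # H-C-O-P backbone couplings (Lankhorst)
    "HCOP": KarplusSet(A=15.3, B=-6.2, C=1.5),
    # C-C-O-P backbone couplings
    "CCOP": KarplusSet(A=6.9, B=-3.4, C=0.7),
}


def karplus_3j(theta: float, k: KarplusSet) -> float:
    """Evaluate the Karplus relation at torsion *theta* (degrees)."""
    c = math.cos(math.radians(theta + k.offset))
    return k.A * c * c + k.B * c + k.C


def noe_effective(distances: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Effective NOE distance: (weighted mean of r^-6)^(-1/6), Å."""
    r = np.asarray(distances, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    if weights is None:
        m = float(np.mean(r ** -6.0))
    else:
        w = np.asarray(weights, dtype=float)
        m = float(np.sum(w * r ** -6.0) / np.sum(w))
    return m ** (-1.0 / 6.0)


def ambnoe_effective(
    pair_distances: Sequence[Sequence[float]],
    weights: Sequence[float] | None = None,
) -> float:
    """Effective distance of an ambiguous NOE.

    *pair_distances* holds one per-frame distance series per contributing
    pair (2–4 pairs; a single pair degenerates to :func:`noe_effective`).
    Per frame the r^-6 contributions are summed over pairs, then averaged
    over frames, then mapped back through the −1/6 power.
    """
    arr = np.asarray(pair_distances, dtype=float)  # (n_pairs, n_frames)
    if arr.ndim != 2 or not 1 <= arr.shape[0] <= 4:
        raise ValueError("need 1-4 pair distance series of equal length")
    if np.any(arr <= 0):
        raise ValueError("distances must be positive")
    per_frame = np.sum(arr ** -6.0, axis=0)
    if weights is None:
        m = float(np.mean(per_frame))
    else:
        w = np.asarray(weights, dtype=float)
        m = float(np.sum(w * per_frame) / np.sum(w))
    return m ** (-1.0 / 6.0)


@dataclass(frozen=True)
class Observable:
    """One experimental observable row.

    ``atoms`` is a tuple of atom references: a dihedral quadruple for 3J
    rows; one pair for NOE rows; 2–4 pairs (flattened, length 4/6/8) for
    ambNOE rows.  ``exp_value`` is Hz for couplings and Å for (amb)NOEs.
    """

    id: str
    klass: str
    atoms: tuple[AtomRef, ...]
    exp_value: float
    exp_error: float
    karplus_set: str = ""

    def __post_init__(self) -> None:
        if self.klass not in OBSERVABLE_CLASSES:
            raise ValueError(f"unknown observable class {self.klass!r}")
        if self.exp_error <= 0:
            raise ValueError("exp_error must be positive")
        n = len(self.atoms)
        if self.klass.endswith("3J") and n != 4:
            raise ValueError("3J observables need a dihedral quadruple")
        if self.klass == "NOE" and n != 2:
            raise ValueError("NOE observables need one atom pair")
        if self.klass == "ambNOE" and (n % 2 or not 4 <= n <= 8):
            raise ValueError("ambNOE observables need 2-4 atom pairs")

    def pairs(self) -> list[tuple[AtomRef, AtomRef]]:
        return [(self.atoms[i], self.atoms[i + 1]) for i in range(0, len(self.atoms), 2)]


@dataclass
class ObservableTable:
    """A set of observables with per-class counts."""

    observables: list[Observable]
    karplus_sets: dict[str, KarplusSet] = field(default_factory=lambda: dict(DEFAULT_KARPLUS_SETS))

    def __len__(self) -> int:
        return len(self.observables)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in OBSERVABLE_CLASSES}
        for obs in self.observables:
            out[obs.klass] += 1
        return out


@dataclass
class Chi2Report:
    """Per-class chi^2 with the weighted-mean total and per-row residuals."""

    chi2_per_class: dict[str, float]
    n_per_class: dict[str, int]
    total_chi2: float
    residuals: dict[str, float]  # observable id -> (calc - exp)/sigma
    calc_values: dict[str, float]
    skipped: list[str]
    weights: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "total_chi2": self.total_chi2,
            "chi2_per_class": self.chi2_per_class,
            "n_per_class": self.n_per_class,
            "class_weights": self.weights,
            "skipped_observables": self.skipped,
            "chi2_definition": "per class: mean of squared sigma-normalised residuals; "
            "total: sum_c w_c*chi2_c / sum_c w_c with w_c = n_c by default",
        }


def back_calculate(
    obs: Observable,
    frames: Sequence[Conformation],
    weights: Sequence[float] | None,
    karplus_sets: dict[str, KarplusSet],
) -> float:
    """Ensemble-averaged value of one observable (Hz for 3J, Å for NOEs)."""
    if obs.klass.endswith("3J"):
        k = karplus_sets[obs.karplus_set]
        j = np.array([karplus_3j(dihedral(fr, *obs.atoms), k) for fr in frames])
        if weights is None:
            return float(j.mean())
        w = np.asarray(weights, dtype=float)
        return float(np.sum(w * j) / np.sum(w))
    pairs = obs.pairs()
    series = np.array([[distance(fr, a, b) for fr in frames] for a, b in pairs])
    if obs.klass == "NOE":
        return noe_effective(series[0], weights)
    return ambnoe_effective(series, weights)


def chi2_total(
    table: ObservableTable,
    frames: Sequence[Conformation],
    weights: Sequence[float] | None = None,
    class_weights: dict[str, float] | None = None,
) -> Chi2Report:
    """Score ensemble-vs-experiment agreement as the weighted total chi^2.

    Observables whose atoms do not resolve in the ensemble are skipped with
    a warning and excluded from their class count.  Default class weights
    are the per-class observable counts, so the total is the plain mean of
    all squared residuals.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty ensemble")
    residuals: dict[str, float] = {}
    calc_values: dict[str, float] = {}
    per_class_sq: dict[str, list[float]] = {c: [] for c in OBSERVABLE_CLASSES}
    skipped: list[str] = []
    for obs in table.observables:
        try:
            calc = back_calculate(obs, frames, weights, table.karplus_sets)
        except AtomLookupError as err:
            warnings.warn(f"observable {obs.id}: {err}; skipped", stacklevel=2)
            skipped.append(obs.id)
            continue
        r = (calc - obs.exp_value) / obs.exp_error
        residuals[obs.id] = r
        calc_values[obs.id] = calc
        per_class_sq[obs.klass].append(r * r)
    chi2_per_class = {c: float(np.mean(v)) for c, v in per_class_sq.items() if v}
    n_per_class = {c: len(v) for c, v in per_class_sq.items() if v}
    if class_weights is None:
        w = {c: float(n) for c, n in n_per_class.items()}
    else:
        w = {c: float(class_weights[c]) for c in chi2_per_class}
    wsum = sum(w.values())
    if wsum <= 0:
        raise ValueError("no scorable observables")
    total = sum(w[c] * chi2_per_class[c] for c in chi2_per_class) / wsum
    return Chi2Report(
        chi2_per_class=chi2_per_class,
        n_per_class=n_per_class,
        total_chi2=float(total),
        residuals=residuals,
        calc_values=calc_values,
        skipped=skipped,
        weights=w,
    )


# ---------------------------------------------------------------------------
# Tab-separated table I/O

_COLUMNS = ["id", "class", "atoms", "exp_value", "exp_error", "karplus_set"]


def _format_atoms(atoms: tuple[AtomRef, ...]) -> str:
    return ";".join(f"{res}:{name}" for res, name in atoms)


def _parse_atoms(text: str) -> tuple[AtomRef, ...]:
    refs = []
    for token in str(text).split(";"):
        res, name = token.split(":")
        refs.append((int(res), name))
    return tuple(refs)


def write_observable_table(table: ObservableTable, path) -> None:
    """Write the table as TSV (columns id, class, atoms, exp_value, exp_error, karplus_set)."""
    rows = [
        {
            "id": o.id,
            "class": o.klass,
            "atoms": _format_atoms(o.atoms),
            "exp_value": o.exp_value,
            "exp_error": o.exp_error,
            "karplus_set": o.karplus_set,
        }
        for o in table.observables
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_observable_table(
    path,
    karplus_sets: dict[str, KarplusSet] | None = None,
) -> ObservableTable:
    """Read a TSV observable table written by :func:`write_observable_table`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    observables = [
        Observable(
            id=str(row["id"]),
            klass=str(row["class"]),
            atoms=_parse_atoms(row["atoms"]),
            exp_value=float(row["exp_value"]),
            exp_error=float(row["exp_error"]),
            karplus_set=str(row.get("karplus_set", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    return ObservableTable(
        observables,
        karplus_sets=dict(karplus_sets or DEFAULT_KARPLUS_SETS),
    )
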