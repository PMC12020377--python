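"""Conformational-state classification of UUCG tetraloop frames.

Each frame is reduced to eight geometric features (five donor–acceptor
heavy-atom distances, the G9 glycosidic torsion χ, and two superposition
RMSDs against the native reference) and assigned to exactly one of eleven
published states, or to an explicit ``unclassified`` label when no printed
criterion applies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    ANTI_WINDOW,
    SYN_WINDOW,
    AngularWindow,
    AtomMap,
    Conformation,
    dihedral,
    distance,
    in_window,
    normalize_angle,
    superpose_rmsd,
)

__all__ = [
    "StateLabel",
    "GeometricFeatures",
    "ClassifierConfig",
    "StateTimeline",
    "extract_features",
    "classify_frame",
    "classify_features",
    "classify_trajectory",
    "state_rmsd_stats",
]


class StateLabel(str, enum.Enum):
    """The eleven published loop states plus an explicit catch-all."""

    NATIVE = "native"
    SUGAR_BASE_N7_LOST = "sugar_base_N7_lost"
    BPH7_LOST = "bph7_lost"
    BOTH_SUGAR_BASE_LOST = "both_sugar_base_lost"
    C8_BULGE_ONE_SUGAR_BASE_LOST = "C8_bulge_one_sugar_base_lost"
    G9_BULGE_SYN = "G9_bulge_syn"
    G9_BULGE_ANTI = "G9_bulge_anti"
    G9_BACK_IN_POCKET_ANTI = "G9_back_in_pocket_anti"
    U6U7C8_BULGE = "U6U7C8_bulge"
    LOOP_DISRUPTED = "loop_disrupted"
    STEM_LOOP_DISRUPTED = "stem_loop_disrupted"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeometricFeatures:
    """Per-frame feature vector consumed by the classifier.

    Distances in Å: G9(N1)-U6(O2), G9(N2)-U6(O2), U6(O2')-G9(O6),
    U7(O2')-G9(N7), C8(N4)-U6(pro-R_P).  chi_G9 in degrees on (−180, 180];
    RMSDs in Å against the starting/native reference after superposition.
    """

    d_N1_O2: float
    d_N2_O2: float
    d_O2p6_O6: float
    d_O2p7_N7: float
    d_N4_proRP: float
    chi_G9: float
    rmsd_loop: float
    rmsd_all: float

    def as_dict(self) -> dict[str, float]:
        return {
            "d_N1_O2": self.d_N1_O2,
            "d_N2_O2": self.d_N2_O2,
            "d_O2p6_O6": self.d_O2p6_O6,
            "d_O2p7_N7": self.d_O2p7_N7,
            "d_N4_proRP": self.d_N4_proRP,
            "chi_G9": self.chi_G9,
            "rmsd_loop": self.rmsd_loop,
            "rmsd_all": self.rmsd_all,
        }


@dataclass(frozen=True)
class ClassifierConfig:
    """Published distance/torsion/RMSD thresholds (Å, degrees).

    ``hb`` is the generic H-bond donor–acceptor cutoff; ``bph_native`` the
    slightly wider cutoff of the 7BPh base–phosphate contact; the remaining
    cutoffs appear in individual state rules.
    """

    hb: float = 3.5
    bph_native: float = 3.7
    n7_relaxed: float = 4.0
    bph_back: float = 4.2
    far: float = 5.0
    n1_back: float = 5.2
    rmsd_loop_cut: float = 3.0
    rmsd_all_cut: float = 4.6
    syn_window: AngularWindow = SYN_WINDOW
    anti_window: AngularWindow = ANTI_WINDOW

    def __post_init__(self) -> None:
        seq = (self.hb, self.bph_native, self.n7_relaxed, self.bph_back, self.far, self.n1_back)
        if not all(a > 0 for a in seq) or not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("thresholds must be positive and strictly increasing")


def extract_features(
    conf: Conformation,
    atom_map: AtomMap,
    reference: Conformation,
) -> GeometricFeatures:
    """Measure the classifier's eight features on one frame.

    RMSDs are computed over all heavy atoms of the loop nucleotides
    (``rmsd_loop``) and of all nucleotides (``rmsd_all``), against the
    user-supplied starting/native conformation, after optimal superposition.
    """
    m = atom_map
    loop_sel = m.loop_heavy_atoms(reference)
    all_sel = m.all_heavy_atoms(reference)
    return GeometricFeatures(
        d_N1_O2=distance(conf, m.g9_n1, m.u6_o2),
        d_N2_O2=distance(conf, m.g9_n2, m.u6_o2),
        d_O2p6_O6=distance(conf, m.u6_o2p, m.g9_o6),
        d_O2p7_N7=distance(conf, m.u7_o2p, m.g9_n7),
        d_N4_proRP=distance(conf, m.c8_n4, m.u6_pro_rp),
        chi_G9=dihedral(conf, m.g9_o4p, m.g9_c1p, m.g9_n9, m.g9_c4),
        rmsd_loop=superpose_rmsd(conf, reference, loop_sel),
        rmsd_all=superpose_rmsd(conf, reference, all_sel),
    )


def classify_features(f: GeometricFeatures, cfg: ClassifierConfig | None = None) -> StateLabel:
    """Assign one state label to a feature vector.

    Rules are the printed clustering criteria with strict inequalities.  The
    stem+loop-disrupted criterion overrides everything; the remaining rules
    are evaluated from least to most disrupted, and a frame matching the
    U6+U7+C8-bulge criteria is never relabelled loop-disrupted even when its
    loop RMSD exceeds the cut (the published carve-out).  A frame matching no
    rule is reported as ``unclassified``.
    """
    cfg = cfg or ClassifierConfig()
    syn = in_window(f.chi_G9, cfg.syn_window)
    anti = in_window(f.chi_G9, cfg.anti_window)
    n1_or_n2 = f.d_N1_O2 < cfg.hb or f.d_N2_O2 < cfg.hb

    if f.rmsd_all > cfg.rmsd_all_cut:
        return StateLabel.STEM_LOOP_DISRUPTED
    if (
        f.d_N1_O2 < cfg.hb
        and f.d_O2p6_O6 < cfg.hb
        and f.d_O2p7_N7 < cfg.hb
        and f.d_N4_proRP < cfg.bph_native
        and syn
    ):
        return StateLabel.NATIVE
    if (
        n1_or_n2
        and f.d_O2p6_O6 < cfg.hb
        and f.d_O2p7_N7 > cfg.hb
        and f.d_N4_proRP < cfg.bph_native
        and syn
    ):
        return StateLabel.SUGAR_BASE_N7_LOST
    if (
        n1_or_n2
        and f.d_O2p6_O6 < cfg.hb
        and f.d_O2p7_N7 < cfg.n7_relaxed
        and f.d_N4_proRP > cfg.bph_native
        and syn
    ):
        return StateLabel.BPH7_LOST
    if (
        n1_or_n2
        and f.d_O2p6_O6 > cfg.hb
        and f.d_O2p7_N7 > cfg.hb
        and f.d_N4_proRP < cfg.bph_native
        and syn
    ):
        return StateLabel.BOTH_SUGAR_BASE_LOST
    if (
        n1_or_n2
        and (f.d_O2p6_O6 > cfg.hb or f.d_O2p7_N7 > cfg.hb)
        and f.d_N4_proRP > cfg.far
        and syn
    ):
        return StateLabel.C8_BULGE_ONE_SUGAR_BASE_LOST
    if (
        f.d_N1_O2 > cfg.far
        and f.d_O2p6_O6 > cfg.far
        and syn
        and f.rmsd_loop < cfg.rmsd_loop_cut
    ):
        return StateLabel.G9_BULGE_SYN
    if (
        f.d_N1_O2 > cfg.far
        and f.d_O2p6_O6 > cfg.far
        and anti
        and f.rmsd_loop < cfg.rmsd_loop_cut
    ):
        return StateLabel.G9_BULGE_ANTI
    if (
        f.d_N1_O2 < cfg.n1_back
        and (f.d_O2p6_O6 < cfg.bph_native or f.d_N4_proRP < cfg.bph_back)
        and anti
        and f.rmsd_loop < cfg.rmsd_loop_cut
    ):
        return StateLabel.G9_BACK_IN_POCKET_ANTI
    if (
        f.d_N1_O2 > cfg.far
        and (f.d_O2p6_O6 < cfg.n7_relaxed or f.d_O2p7_N7 < cfg.n7_relaxed)
        and f.d_N4_proRP > cfg.far
        and syn
    ):
        return StateLabel.U6U7C8_BULGE
    if f.rmsd_loop > cfg.rmsd_loop_cut:
        return StateLabel.LOOP_DISRUPTED
    return StateLabel.UNCLASSIFIED


# Back-compat alias used throughout the docs: classify a single frame's features.
classify_frame = classify_features


@dataclass
class StateTimeline:
    """Per-frame state labels with times and positive weights."""

    labels: list[StateLabel]
    times: np.ndarray
    weights: np.ndarray
    features: list[GeometricFeatures] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if len(self.times) != n or len(self.weights) != n:
            raise ValueError("labels/times/weights lengths differ")
        if n == 0:
            raise ValueError("empty timeline")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and positive")

    def __len__(self) -> int:
        return len(self.labels)

    def populations(self) -> dict[StateLabel, float]:
        """Weighted state fractions; values sum to 1."""
        total = float(self.weights.sum())
        out: dict[StateLabel, float] = {}
        for lab, w in zip(self.labels, self.weights):
            out[lab] = out.get(lab, 0.0) + float(w)
        return {lab: w / total for lab, w in out.items()}


def classify_trajectory(
    frames: Sequence[Conformation],
    atom_map: AtomMap,
    reference: Conformation,
    cfg: ClassifierConfig | None = None,
    weights: Sequence[float] | None = None,
) -> tuple[StateTimeline, dict[StateLabel, float]]:
    """Classify every frame and tabulate weighted state populations."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    cfg = cfg or ClassifierConfig()
    if weights is None:
        weights = np.ones(len(frames))
    feats = [extract_features(fr, atom_map, reference) for fr in frames]
    labels = [classify_features(f, cfg) for f in feats]
    times = np.array([fr.frame_time for fr in frames], dtype=float)
    timeline = StateTimeline(labels, times, np.asarray(weights, float), features=feats)
    return timeline, timeline.populations()


def state_rmsd_stats(
    timeline: StateTimeline,
    rmsd_loop: Sequence[float] | None = None,
) -> dict[StateLabel, tuple[float, float]]:
    """Per-state mean ± population SD of the loop RMSD series.

    States with no frames are omitted.  If *rmsd_loop* is not given, the
    series stored on the timeline's features is used.
    """
    if rmsd_loop is None:
        if timeline.features is None:
            raise ValueError("no rmsd_loop series available")
        rmsd_loop = [f.rmsd_loop for f in timeline.features]
    rmsd_loop = np.asarray(rmsd_loop, dtype=float)
    if len(rmsd_loop) != len(timeline):
        raise ValueError("series length mismatch")
    out: dict[StateLabel, tuple[float, float]] = {}
    labels = np.array([lab.value for lab in timeline.labels], dtype=object)
    for lab in StateLabel:
        mask = labels == lab.value
        if mask.any():
            vals = rmsd_loop[mask]
            out[lab] = (float(vals.mean()), float(vals.std()))  # population SD
    return out
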