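import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetraloop.geometry import (
    ANTI_WINDOW,
    SYN_WINDOW,
    AtomLookupError,
    Conformation,
    DegenerateGeometryError,
    dihedral,
    dihedral_from_points,
    distance,
    in_window,
    normalize_angle,
    phase_from_torsions,
    pseudorotation_phase,
    pucker_class,
    raw_rmsd,
    superpose_rmsd,
    torsions_from_phase,
)

from _oracles import grid_search_superposition_rmsd, norm_distance


def _conf(points, names=None):
    n = len(points)
    return Conformation(
        residue_index=np.ones(n, dtype=int),
        residue_name=np.array(["G"] * n, dtype=object),
        atom_name=np.array(names or [f"X{i}" for i in range(n)], dtype=object),
        coords=np.asarray(points, dtype=float),
    )


class TestDistance:
    def test_three_four_five_triangle(self):
        c = _conf([[0, 0, 0], [3, 4, 0]])
        assert distance(c, (1, "X0"), (1, "X1")) == pytest.approx(5.0)
        assert distance(c, (1, "X0"), (1, "X0")) == 0.0

    def test_symmetry_and_oracle(self, rng):
        pts = rng.normal(scale=5.0, size=(200, 3))
        c = _conf(pts)
        for _ in range(100):
            i, j = rng.integers(0, 200, size=2)
            a, b = (1, f"X{i}"), (1, f"X{j}")
            d = distance(c, a, b)
            assert d == pytest.approx(norm_distance(pts[i], pts[j]), abs=1e-12)
            assert d == distance(c, b, a)

    def test_missing_atom_named_in_error(self):
        c = _conf([[0, 0, 0]])
        with pytest.raises(AtomLookupError, match="2:N1"):
            distance(c, (1, "X0"), (2, "N1"))


class TestDihedral:
    def test_planar_cis_and_trans(self):
        # a-b-c-d all in a plane: cis (same side) -> 0, trans -> 180
        cis = _conf([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]])
        assert dihedral(cis, (1, "X0"), (1, "X1"), (1, "X2"), (1, "X3")) == pytest.approx(0.0, abs=1e-9)
        trans = _conf([[1, 1, 0], [0, 1, 0], [0, 0, 0], [-1, 0, 0]])
        assert abs(dihedral(trans, (1, "X0"), (1, "X1"), (1, "X2"), (1, "X3"))) == pytest.approx(180.0)

    @pytest.mark.parametrize("angle", [37.0, -37.0, 90.0, 179.0, -120.5])
    def test_constructive_rotation(self, angle):
        # rotate d right-handed about the b->c axis (+z) away from cis by `angle`
        b, c = np.array([0.0, 0, 0]), np.array([0.0, 0, 1.0])
        a = np.array([1.0, 0, -1.0])
        rad = math.radians(angle)
        d = np.array([math.cos(rad), math.sin(rad), 2.0])
        got = dihedral_from_points(a, b, c, d)
        assert got == pytest.approx(angle, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_reversal_invariance(self, seed):
        # a torsion is unchanged when the four atoms are read in reverse order
        r = np.random.default_rng(seed)
        pts = r.normal(size=(4, 3)) * 3.0
        try:
            fwd = dihedral_from_points(*pts)
            rev = dihedral_from_points(*pts[::-1])
        except DegenerateGeometryError:
            return
        if abs(abs(fwd) - 180.0) > 1e-6:
            assert fwd == pytest.approx(rev, abs=1e-6)

    def test_degenerate_raises(self):
        line = _conf([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(DegenerateGeometryError):
            dihedral(line, (1, "X0"), (1, "X1"), (1, "X2"), (1, "X3"))


class TestAngularWindows:
    @pytest.mark.parametrize(
        "angle,window,expected",
        [
            (30.0, SYN_WINDOW, True),
            (150.0, SYN_WINDOW, False),
            (150.0, ANTI_WINDOW, True),
            (-170.0, ANTI_WINDOW, True),
            (-25.0, SYN_WINDOW, True),   # closed endpoints
            (115.0, SYN_WINDOW, True),
            (180.0, ANTI_WINDOW, True),
        ],
    )
    def test_membership(self, angle, window, expected):
        assert in_window(angle, window) is expected

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=-180.0, max_value=180.0, exclude_min=True),
           st.integers(min_value=-3, max_value=3))
    def test_wraparound_invariance(self, angle, k):
        for w in (SYN_WINDOW, ANTI_WINDOW):
            assert in_window(angle + 360.0 * k, w) == in_window(angle, w)

    def test_normalize_angle_range(self):
        for a in (-720.0, -180.0, 0.0, 180.0, 540.0):
            out = normalize_angle(a)
            assert -180.0 < out <= 180.0


class TestSuperposeRmsd:
    def _random_pair(self, rng, n=10):
        pts = rng.normal(scale=3.0, size=(n, 3))
        return _conf(pts), pts

    def test_identity_and_rigid_invariance(self, rng):
        conf, pts = self._random_pair(rng)
        sel = [(1, f"X{i}") for i in range(len(pts))]
        assert superpose_rmsd(conf, conf, sel) == pytest.approx(0.0, abs=1e-9)
        # arbitrary rotation + translation
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = _conf(pts @ rot.T + np.array([5.0, -2.0, 9.0]))
        assert superpose_rmsd(moved, conf, sel) == pytest.approx(0.0, abs=1e-6)

    def test_displaced_atom_matches_grid_search_oracle(self, rng):
        conf, pts = self._random_pair(rng, n=10)
        displaced = pts.copy()
        displaced[3] += np.array([1.0, 0.0, 0.0])
        mobile = _conf(displaced)
        sel = [(1, f"X{i}") for i in range(10)]
        got = superpose_rmsd(mobile, conf, sel)
        expected = grid_search_superposition_rmsd(displaced, pts)
        assert got == pytest.approx(expected, abs=1e-3)

    def test_never_exceeds_raw_rmsd(self, rng):
        sel = [(1, f"X{i}") for i in range(12)]
        for _ in range(20):
            a = _conf(rng.normal(size=(12, 3)) * 2.0)
            b = _conf(rng.normal(size=(12, 3)) * 2.0)
            assert superpose_rmsd(a, b, sel) <= raw_rmsd(a, b, sel) + 1e-12

    def test_too_few_atoms(self, rng):
        conf, _ = self._random_pair(rng)
        with pytest.raises(DegenerateGeometryError):
            superpose_rmsd(conf, conf, [(1, "X0"), (1, "X1")])


class TestPseudorotation:
    @pytest.mark.parametrize("p,tau", [(18.0, 40.0), (162.0, 38.0), (90.0, 35.0), (340.0, 42.0)])
    def test_round_trip(self, p, tau):
        nu = torsions_from_phase(p, tau)
        p_out, tau_out = phase_from_torsions(nu)
        assert p_out == pytest.approx(p, abs=0.1)
        assert tau_out == pytest.approx(tau, abs=0.1)

    def test_south_classification(self):
        p_out, _ = phase_from_torsions(torsions_from_phase(162.0, 40.0))
        assert pucker_class(p_out) == "south"
        assert pucker_class(18.0) == "north"

    def test_zero_amplitude_raises(self):
        with pytest.raises(DegenerateGeometryError):
            phase_from_torsions([0.0] * 5)

    def test_on_scaffold_sugar(self, scaffold):
        p, tau, klass = pseudorotation_phase(scaffold, 6)
        assert 0.0 <= p < 360.0
        assert tau > 0
        assert klass in ("north", "south", "other")


def test_distance_rigid_invariance(rng, scaffold):
    """Distances are unchanged when both atoms ride the same rigid transform."""
    from scipy.spatial.transform import Rotation
    from tetraloop.geometry import rigid_transform

    rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
    moved = rigid_transform(scaffold, rot, np.array([3.0, -7.0, 2.0]))
    for a, b in [((9, "N1"), (6, "O2")), ((8, "N4"), (6, "OP1"))]:
        assert distance(moved, a, b) == pytest.approx(distance(scaffold, a, b), abs=1e-9)
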