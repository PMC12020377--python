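import numpy as np
import pytest

from tetraloop.geometry import distance
from tetraloop.states import (
    ClassifierConfig,
    GeometricFeatures,
    StateLabel,
    StateTimeline,
    classify_features,
    classify_trajectory,
    extract_features,
    state_rmsd_stats,
)
from tetraloop.synthetic import GeneratorConfig, generate_state_conformer

from _oracles import decision_table, norm_distance

NATIVE_VEC = dict(
    d_N1_O2=2.9, d_N2_O2=4.5, d_O2p6_O6=3.0, d_O2p7_N7=3.1,
    d_N4_proRP=3.2, chi_G9=20.0, rmsd_loop=0.9, rmsd_all=1.0,
)


def feats(**kw):
    base = dict(NATIVE_VEC)
    base.update(kw)
    return GeometricFeatures(**base)


class TestClassifyFrame:
    def test_native_vector(self):
        assert classify_features(feats()) is StateLabel.NATIVE

    def test_sugar_base_n7_lost(self):
        f = feats(d_O2p7_N7=4.2, d_N2_O2=3.0)
        assert classify_features(f) is StateLabel.SUGAR_BASE_N7_LOST

    def test_stem_loop_override_beats_everything(self):
        f = feats(rmsd_all=5.0)
        assert classify_features(f) is StateLabel.STEM_LOOP_DISRUPTED

    def test_carve_out_bulge_over_loop_disrupted(self):
        f = feats(d_N1_O2=6.0, d_N2_O2=6.0, d_O2p6_O6=3.4, d_O2p7_N7=3.2,
                  d_N4_proRP=6.5, rmsd_loop=3.8, rmsd_all=2.0)
        assert classify_features(f) is StateLabel.U6U7C8_BULGE

    def test_monotone_n7_perturbation(self):
        assert classify_features(feats()) is StateLabel.NATIVE
        f = feats(d_O2p7_N7=3.8)
        assert classify_features(f) is StateLabel.SUGAR_BASE_N7_LOST

    def test_threshold_grid_matches_decision_table(self):
        """Exhaustive threshold-straddling grid vs independent oracle."""
        levels = [3.3, 3.6, 3.9, 4.1, 4.9, 5.1, 5.3]
        chis = [20.0, 160.0]
        rmsds = [1.0, 3.5, 5.0]
        mismatches = 0
        count = 0
        for d1 in levels:
            for d2 in (3.3, 5.3):
                for d3 in levels:
                    for d4 in levels:
                        for d5 in levels:
                            for chi in chis:
                                for rl in rmsds:
                                    for ra in (1.0, 5.0):
                                        got = classify_features(GeometricFeatures(
                                            d1, d2, d3, d4, d5, chi, rl, ra)).value
                                        want = decision_table(d1, d2, d3, d4, d5, chi, rl, ra)
                                        count += 1
                                        if got != want:
                                            mismatches += 1
        assert count >= 2 ** 10
        assert mismatches == 0

    def test_random_fuzz_total_and_oracle_equivalent(self):
        rng = np.random.default_rng(2024)
        n = 20_000
        d = rng.uniform(2.0, 8.0, size=(n, 5))
        chi = rng.uniform(-180.0, 180.0, size=n)
        rl = rng.uniform(0.0, 6.0, size=n)
        ra = rng.uniform(0.0, 6.0, size=n)
        for k in range(n):
            f = GeometricFeatures(*d[k], chi[k], rl[k], ra[k])
            got = classify_features(f)
            assert isinstance(got, StateLabel)
            assert got.value == decision_table(*d[k], chi[k], rl[k], ra[k])


class TestExtractFeatures:
    def test_identity_reference(self, scaffold, atom_map):
        f = extract_features(scaffold, atom_map, scaffold)
        assert f.rmsd_loop == pytest.approx(0.0, abs=1e-6)
        assert f.rmsd_all == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_direct_recomputation(self, scaffold, atom_map, rng):
        conf = scaffold.copy()
        conf.coords[:] += rng.normal(scale=0.2, size=conf.coords.shape)
        f = extract_features(conf, atom_map, scaffold)
        pairs = {
            "d_N1_O2": (atom_map.g9_n1, atom_map.u6_o2),
            "d_N2_O2": (atom_map.g9_n2, atom_map.u6_o2),
            "d_O2p6_O6": (atom_map.u6_o2p, atom_map.g9_o6),
            "d_O2p7_N7": (atom_map.u7_o2p, atom_map.g9_n7),
            "d_N4_proRP": (atom_map.c8_n4, atom_map.u6_pro_rp),
        }
        for name, (a, b) in pairs.items():
            direct = norm_distance(conf.position(a), conf.position(b))
            assert getattr(f, name) == pytest.approx(direct, abs=1e-10)

    def test_constructed_distance(self, scaffold, atom_map):
        conf = scaffold.copy()
        # place G9 N1 exactly 2.5 A from U6 O2 along the current separation
        i = conf.atom_index(atom_map.g9_n1)
        o2 = conf.position(atom_map.u6_o2)
        sep = conf.coords[i] - o2
        conf.coords[i] = o2 + sep / np.linalg.norm(sep) * 2.5
        f = extract_features(conf, atom_map, scaffold)
        assert f.d_N1_O2 == pytest.approx(2.5, abs=1e-6)


class TestTrajectory:
    def test_all_native(self, scaffold, atom_map):
        tl, pops = classify_trajectory([scaffold] * 4, atom_map, scaffold)
        assert pops == {StateLabel.NATIVE: pytest.approx(1.0)}

    def test_population_counting(self):
        labels = [StateLabel.NATIVE] * 8 + [StateLabel.BPH7_LOST] * 2
        tl = StateTimeline(labels, np.arange(10.0), np.ones(10))
        pops = tl.populations()
        assert pops[StateLabel.NATIVE] == pytest.approx(0.8)
        assert pops[StateLabel.BPH7_LOST] == pytest.approx(0.2)
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-12)

    def test_weighted_equals_replicated(self):
        labels = [StateLabel.NATIVE, StateLabel.LOOP_DISRUPTED, StateLabel.NATIVE]
        weights = [3.0, 2.0, 1.0]
        tl_w = StateTimeline(labels, np.arange(3.0), np.array(weights))
        replicated = [lab for lab, w in zip(labels, weights) for _ in range(int(w))]
        tl_r = StateTimeline(replicated, np.arange(6.0), np.ones(6))
        for lab, p in tl_w.populations().items():
            assert tl_r.populations()[lab] == pytest.approx(p, abs=1e-12)


class TestStateRmsdStats:
    def test_two_point_population_sd(self):
        labels = [StateLabel.NATIVE, StateLabel.NATIVE, StateLabel.BPH7_LOST]
        tl = StateTimeline(labels, np.arange(3.0), np.ones(3))
        stats = state_rmsd_stats(tl, [1.0, 3.0, 1.0])
        mean, sd = stats[StateLabel.NATIVE]
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)  # population SD of {1, 3}
        assert stats[StateLabel.BPH7_LOST] == (pytest.approx(1.0), pytest.approx(0.0))
        assert StateLabel.G9_BULGE_SYN not in stats

    def test_random_series_matches_two_pass_oracle(self, rng):
        n = 500
        labels = [StateLabel.NATIVE if b else StateLabel.LOOP_DISRUPTED
                  for b in rng.random(n) < 0.6]
        series = rng.uniform(0.5, 5.0, size=n)
        tl = StateTimeline(labels, np.arange(float(n)), np.ones(n))
        stats = state_rmsd_stats(tl, series)
        for lab in (StateLabel.NATIVE, StateLabel.LOOP_DISRUPTED):
            vals = [s for s, l in zip(series, labels) if l is lab]
            m = sum(vals) / len(vals)
            var = sum((v - m) ** 2 for v in vals) / len(vals)
            assert stats[lab][0] == pytest.approx(m, abs=1e-10)
            assert stats[lab][1] == pytest.approx(var ** 0.5, abs=1e-10)


def test_synthetic_round_trip_smoke(scaffold, atom_map):
    """Every targeted state generates a conformer that classifies back to it."""
    for state in StateLabel:
        if state is StateLabel.UNCLASSIFIED:
            continue
        conf = generate_state_conformer(state, GeneratorConfig(seed=7))
        f = extract_features(conf, atom_map, scaffold)
        assert classify_features(f) is state


def test_config_rejects_disordered_thresholds():
    with pytest.raises(ValueError):
        ClassifierConfig(hb=4.0, bph_native=3.7)
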