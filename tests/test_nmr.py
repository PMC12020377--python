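import math

import numpy as np
import pytest

from tetraloop.nmr import (
    DEFAULT_KARPLUS_SETS,
    KarplusSet,
    Observable,
    ObservableTable,
    ambnoe_effective,
    back_calculate,
    chi2_total,
    karplus_3j,
    noe_effective,
    read_observable_table,
    write_observable_table,
)
from tetraloop.synthetic import GeneratorConfig, generate_nmr_dataset


class TestKarplus:
    def test_limits(self):
        k = KarplusSet(A=9.67, B=-2.03, C=0.5)
        assert karplus_3j(0.0, k) == pytest.approx(k.A + k.B + k.C)
        assert karplus_3j(90.0, k) == pytest.approx(k.C, abs=1e-12)

    def test_random_matches_direct_arithmetic(self, rng):
        k = KarplusSet(A=15.3, B=-6.2, C=1.5, offset=-120.0)
        for theta in rng.uniform(-180.0, 180.0, size=50):
            c = math.cos(math.radians(theta - 120.0))
            assert karplus_3j(theta, k) == pytest.approx(15.3 * c * c - 6.2 * c + 1.5, abs=1e-12)


class TestNoeAveraging:
    def test_constant_series(self):
        assert noe_effective([3.2] * 10) == pytest.approx(3.2)

    def test_two_frame_example(self):
        expected = ((2.0 ** -6 + 4.0 ** -6) / 2.0) ** (-1.0 / 6.0)
        assert noe_effective([2.0, 4.0]) == pytest.approx(expected)
        assert expected == pytest.approx(2.239, abs=5e-4)

    def test_power_mean_inequality(self, rng):
        for _ in range(20):
            r = rng.uniform(1.5, 8.0, size=50)
            eff = noe_effective(r)
            assert r.min() - 1e-12 <= eff <= r.mean() + 1e-12

    def test_weighted(self):
        # weight 3 on r=2 vs 1 on r=4 equals replication
        eff_w = noe_effective([2.0, 4.0], weights=[3.0, 1.0])
        eff_r = noe_effective([2.0, 2.0, 2.0, 4.0])
        assert eff_w == pytest.approx(eff_r, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            noe_effective([2.0, 0.0])


class TestAmbNoe:
    def test_two_identical_pairs(self):
        r = 3.0
        got = ambnoe_effective([[r, r], [r, r]])
        assert got == pytest.approx(r * 2.0 ** (-1.0 / 6.0))

    def test_single_pair_reduces_to_noe(self, rng):
        series = rng.uniform(2.0, 6.0, size=30)
        assert ambnoe_effective([series]) == pytest.approx(noe_effective(series), abs=1e-12)

    def test_brute_force_oracle(self, rng):
        series = rng.uniform(2.0, 6.0, size=(3, 25))
        got = ambnoe_effective(series)
        acc = 0.0
        for frame in range(25):
            acc += sum(series[p, frame] ** -6 for p in range(3))
        expected = (acc / 25) ** (-1 / 6)
        assert got == pytest.approx(expected, abs=1e-12)


class TestChi2:
    def test_noiseless_self_consistency(self, scaffold):
        frames = [scaffold]
        table = generate_nmr_dataset(frames, sigma=0.5, cfg=GeneratorConfig(seed=4),
                                     counts=(10, 5, 20, 5), noise_sd=0.0)
        report = chi2_total(table, frames)
        assert report.total_chi2 == pytest.approx(0.0, abs=1e-16)

    def test_single_sigma_residual(self, scaffold):
        frames = [scaffold]
        sigma = 0.4
        obs = Observable("x", "NOE", ((9, "N1"), (6, "O2")), exp_value=0.0, exp_error=sigma)
        calc = back_calculate(obs, frames, None, DEFAULT_KARPLUS_SETS)
        table = ObservableTable([Observable("x", "NOE", ((9, "N1"), (6, "O2")),
                                            exp_value=calc - sigma, exp_error=sigma)])
        report = chi2_total(table, frames)
        assert report.total_chi2 == pytest.approx(1.0, abs=1e-10)

    def test_class_weighting_arithmetic(self, scaffold):
        frames = [scaffold]
        sigma = 1.0
        rows = []
        # NOE class: three rows with squared residual 2
        for i, pair in enumerate([((9, "N1"), (6, "O2")), ((9, "O6"), (6, "O2'")),
                                  ((8, "N4"), (6, "OP1"))]):
            calc = back_calculate(Observable(f"n{i}", "NOE", pair, 1.0, sigma),
                                  frames, None, DEFAULT_KARPLUS_SETS)
            rows.append(Observable(f"n{i}", "NOE", pair, calc - math.sqrt(2.0), sigma))
        # sugar coupling class: one row with squared residual 6
        quad = ((9, "C4'"), (9, "O4'"), (9, "C1'"), (9, "C2'"))
        calc = back_calculate(Observable("s0", "sugar_3J", quad, 1.0, sigma, "HCCH"),
                              frames, None, DEFAULT_KARPLUS_SETS)
        rows.append(Observable("s0", "sugar_3J", quad, calc - math.sqrt(6.0), sigma, "HCCH"))
        report = chi2_total(ObservableTable(rows), frames)
        assert report.chi2_per_class["NOE"] == pytest.approx(2.0, abs=1e-10)
        assert report.chi2_per_class["sugar_3J"] == pytest.approx(6.0, abs=1e-10)
        assert report.total_chi2 == pytest.approx((3 * 2 + 1 * 6) / 4, abs=1e-10)

    def test_invariant_under_reordering_and_replication(self, scaffold, rng):
        base = scaffold.copy()
        base.coords[:] += rng.normal(scale=0.3, size=base.coords.shape)
        frames = [scaffold, base]
        table = generate_nmr_dataset(frames, sigma=0.5, cfg=GeneratorConfig(seed=9),
                                     counts=(6, 4, 10, 3))
        ref = chi2_total(table, frames).total_chi2
        shuffled = ObservableTable(list(reversed(table.observables)), table.karplus_sets)
        assert chi2_total(shuffled, frames).total_chi2 == pytest.approx(ref, abs=1e-12)
        assert chi2_total(table, frames[::-1]).total_chi2 == pytest.approx(ref, abs=1e-12)
        assert chi2_total(table, frames * 3).total_chi2 == pytest.approx(ref, abs=1e-12)

    def test_unresolvable_observable_skipped_with_warning(self, scaffold):
        good = Observable("ok", "NOE", ((9, "N1"), (6, "O2")), 3.0, 0.5)
        bad = Observable("missing", "NOE", ((99, "XX"), (6, "O2")), 3.0, 0.5)
        with pytest.warns(UserWarning, match="missing"):
            report = chi2_total(ObservableTable([good, bad]), [scaffold])
        assert report.skipped == ["missing"]
        assert report.n_per_class["NOE"] == 1


class TestTableIO:
    def test_round_trip(self, scaffold, tmp_path):
        table = generate_nmr_dataset([scaffold], sigma=0.5, cfg=GeneratorConfig(seed=2),
                                     counts=(5, 3, 8, 4))
        path = tmp_path / "obs.tsv"
        write_observable_table(table, path)
        back = read_observable_table(path)
        assert len(back) == len(table)
        for a, b in zip(table.observables, back.observables):
            assert a.id == b.id and a.klass == b.klass and a.atoms == b.atoms
            assert a.exp_value == pytest.approx(b.exp_value, abs=1e-9)
            assert a.karplus_set == b.karplus_set

    def test_observable_validation(self):
        with pytest.raises(ValueError):
            Observable("x", "NOE", ((1, "A"),), 1.0, 0.5)  # pair needed
        with pytest.raises(ValueError):
            Observable("x", "backbone_3J", ((1, "A"), (1, "B")), 1.0, 0.5)
        with pytest.raises(ValueError):
            Observable("x", "NOE", ((1, "A"), (1, "B")), 1.0, 0.0)  # sigma > 0
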