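"""State-space container, calibration I/O, and kernel interpolation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nichefab.errors import FormatError, ValidationError
from nichefab.statespace import (
    CalibrationRecord,
    StateSpace,
    interpolate_properties,
    kernel_weights,
    load_calibration,
    save_calibration,
)
from nichefab.synth import ForwardModelParams, gen_calibration


def _record(peg_pi=50.0, focus_z=0.0, conj=0.0, E=10.0, W=100.0, bound=1.0):
    return CalibrationRecord(peg_pi, focus_z, conj, E, W, bound)


class TestCalibrationIO:
    def test_single_row_round_trip(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text(
            "peg_pi,focus_z,conjugate_conc,youngs_modulus,linewidth,bound_signal\n"
            "50,0.5,2,8.25,120.5,1.5\n"
        )
        space = load_calibration(path)
        assert len(space.records) == 1
        r = space.records[0]
        assert (r.peg_pi, r.focus_z, r.conjugate_conc) == (50.0, 0.5, 2.0)
        assert (r.youngs_modulus, r.linewidth, r.bound_signal) == (8.25, 120.5, 1.5)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("peg_pi,focus_z,conjugate_conc,youngs_modulus,linewidth\n"
                        "50,0,0,8,120\n")
        with pytest.raises(FormatError, match="bound_signal"):
            load_calibration(path)

    def test_invalid_row_cites_row_index(self, tmp_path):
        lines = ["peg_pi,focus_z,conjugate_conc,youngs_modulus,linewidth,bound_signal"]
        for i in range(5):
            E = -1.0 if i == 3 else 8.0
            lines.append(f"50,0,0,{E},120,1")
        path = tmp_path / "neg.csv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="row 3"):
            load_calibration(path)

    def test_100_record_write_read_round_trip(self, tmp_path):
        space, _ = gen_calibration(
            ForwardModelParams(seed=7),
            pegpi_levels=np.linspace(10, 90, 10),
            focus_levels=np.linspace(-3, 3, 10),
            conjugate_levels=(1.0,),
        )
        assert len(space.records) == 100
        path = tmp_path / "cal.csv"
        save_calibration(space, path)
        reloaded = load_calibration(path)
        for a, b in zip(space.records, reloaded.records):
            for f in ("peg_pi", "focus_z", "conjugate_conc", "youngs_modulus",
                      "linewidth", "bound_signal"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)


class TestRecordValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"E": -1.0},
            {"E": 0.0},
            {"W": -5.0},
            {"conj": -0.1},
            {"peg_pi": 95.0},
            {"peg_pi": 5.0},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValidationError):
            _record(**kwargs)

    def test_empty_space_rejected(self):
        with pytest.raises(ValidationError):
            StateSpace([])


class TestKernelWeights:
    def test_query_at_record_gets_maximal_weight(self):
        space = StateSpace(
            [_record(peg_pi=30), _record(peg_pi=50), _record(peg_pi=70)]
        )
        tau = kernel_weights(space, 50.0, 0.0)
        assert np.argmax(tau) == 1
        assert np.all(tau > 0)

    def test_symmetric_records_get_equal_weights(self):
        space = StateSpace([_record(peg_pi=40), _record(peg_pi=60)])
        tau = kernel_weights(space, 50.0, 0.0)
        assert tau[0] == pytest.approx(tau[1], rel=1e-14)

    def test_scalar_loop_oracle(self, small_calibration):
        """Vectorized weights equal an element-wise kernel re-evaluation."""
        space, _ = small_calibration
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(10, 90)
            z = rng.uniform(-3, 3)
            tau = kernel_weights(space, x, z)
            h = space.bandwidth
            for i, r in enumerate(space.records):
                dx = (r.peg_pi - x) / space.range_x
                dz = (r.focus_z - z) / space.range_z
                expected = (1.0 / (h * 2 * math.pi)) * math.exp(
                    -0.5 * ((dx / h) ** 2 + (dz / h) ** 2)
                )
                assert tau[i] == pytest.approx(expected, abs=1e-12, rel=1e-12)

    def test_literal_summed_form_selectable(self):
        space = StateSpace(
            [_record(peg_pi=40), _record(peg_pi=60)], kernel_form="literal_summed"
        )
        tau = space.kernel_weights(50.0, 0.0)
        h = space.bandwidth
        expected = [
            (1 / (h * 2 * math.pi)) * math.exp(-0.5 * ((r - 50) / 40) / h)
            for r in (40.0, 60.0)
        ]
        assert tau == pytest.approx(expected, rel=1e-12)


class TestInterpolation:
    def test_single_record_returns_record_anywhere(self):
        space = StateSpace([_record(E=8.5, W=150.0, bound=2.0)])
        for x, z in [(10, -3), (50, 0), (90, 3), (73.2, 1.1)]:
            E, W, b = interpolate_properties(space, x, z)
            assert (E, W, b) == pytest.approx((8.5, 150.0, 2.0), rel=1e-12)

    def test_equidistant_midpoint(self):
        space = StateSpace(
            [_record(peg_pi=40, E=2.0, W=50.0), _record(peg_pi=60, E=20.0, W=250.0)]
        )
        E, W, _ = interpolate_properties(space, 50.0, 0.0)
        assert E == pytest.approx(11.0, rel=1e-12)
        assert W == pytest.approx(150.0, rel=1e-12)

    def test_brute_force_weighted_mean_oracle(self):
        """Dense scalar Nadaraya-Watson re-evaluation on a 50-record table."""
        space, _ = gen_calibration(
            ForwardModelParams(seed=3),
            pegpi_levels=np.linspace(10, 90, 10),
            focus_levels=np.linspace(-2, 2, 5),
            conjugate_levels=(0.0,),
        )
        assert len(space.records) == 50
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, z = rng.uniform(10, 90), rng.uniform(-2, 2)
            E, W, b = interpolate_properties(space, x, z)
            num_E = num_W = num_b = den = 0.0
            for r in space.records:
                dx = (r.peg_pi - x) / 40.0
                dz = (r.focus_z - z) / 6.0
                tau = math.exp(-0.5 * ((dx / 0.1) ** 2 + (dz / 0.1) ** 2)) / (
                    0.1 * 2 * math.pi
                )
                num_E += tau * r.youngs_modulus
                num_W += tau * r.linewidth
                num_b += tau * r.bound_signal
                den += tau
            assert E == pytest.approx(num_E / den, abs=1e-10)
            assert W == pytest.approx(num_W / den, abs=1e-10)
            assert b == pytest.approx(num_b / den, abs=1e-10)

    @given(x=st.floats(10, 90), z=st.floats(-3, 3))
    def test_convex_combination_bounds(self, x, z):
        space = StateSpace(
            [
                _record(peg_pi=20, focus_z=-2, E=2.0, W=50.0, bound=0.1),
                _record(peg_pi=50, focus_z=0, E=9.0, W=120.0, bound=1.0),
                _record(peg_pi=80, focus_z=2, E=20.0, W=280.0, bound=3.0),
            ]
        )
        E, W, b = interpolate_properties(space, x, z)
        assert 2.0 - 1e-9 <= E <= 20.0 + 1e-9
        assert 50.0 - 1e-9 <= W <= 280.0 + 1e-9
        assert 0.1 - 1e-9 <= b <= 3.0 + 1e-9

    def test_small_bandwidth_converges_to_record(self, small_calibration):
        space, _ = small_calibration
        tight = StateSpace(list(space.records), bandwidth=1e-4)
        r = space.records[17]
        E, W, b = tight.interpolate(r.peg_pi, r.focus_z)
        # records at identical (peg_pi, focus) differ only in conjugate level,
        # whose E/W values share the same noiseless base but different noise
        same = [
            rec
            for rec in space.records
            if rec.peg_pi == r.peg_pi and rec.focus_z == r.focus_z
        ]
        assert E == pytest.approx(np.mean([s.youngs_modulus for s in same]), rel=1e-9)
        assert W == pytest.approx(np.mean([s.linewidth for s in same]), rel=1e-9)

    def test_record_permutation_invariance(self, small_calibration):
        space, _ = small_calibration
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(space.records))
        shuffled = StateSpace([space.records[i] for i in perm])
        for x, z in [(25.0, -1.0), (50.0, 0.5), (75.0, 2.0)]:
            assert shuffled.interpolate(x, z) == pytest.approx(
                space.interpolate(x, z), rel=1e-12
            )

    def test_conjugate_nearest_neighbor_restriction(self):
        space = StateSpace(
            [
                _record(conj=0.0, bound=0.0),
                _record(conj=4.0, bound=4.0),
            ]
        )
        _, _, b0 = interpolate_properties(space, 50.0, 0.0, conjugate=0.5)
        _, _, b4 = interpolate_properties(space, 50.0, 0.0, conjugate=3.8)
        assert b0 == pytest.approx(0.0)
        assert b4 == pytest.approx(4.0)
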