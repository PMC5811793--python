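"""Sequence timing, q/b algebra, reference schedules and b-matrix integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steamref.sequence_models import (
    AcquisitionProtocol,
    BMatrix,
    EffectiveWaveform,
    GradientEvent,
    ReferenceScheme,
    SequenceTiming,
    WaveformError,
    b_matrix,
    build_steam_waveform,
    crusher_q_for_b0,
    diffusion_gradient_strength,
    fibonacci_directions,
    imaging_b,
    narrow_pulse_b,
    reference_schedule,
)

PRINTED_TOL = 0.01  # published protocol numbers are rounded/nominal


class TestScalarAlgebra:
    @pytest.mark.parametrize(
        "q,Delta,delta,n_axes,expected",
        [
            (0.0, 100.0, 2.22, 3, 0.0),
            (0.2, 100.0, 1e-12, 1, 4.0),  # delta -> 0 limit
            (0.2227, 70.0, 2.22, 1, 0.2227**2 * (70 - 2.22 / 3)),
        ],
    )
    def test_narrow_pulse_b(self, q, Delta, delta, n_axes, expected):
        assert narrow_pulse_b(q, Delta, delta, n_axes) == pytest.approx(
            expected, rel=1e-9, abs=1e-12
        )

    def test_three_axis_crusher_b_matches_printed_protocol(self):
        """q0 = 0.023 um^-1 on three axes at Delta = 400 gives the printed 0.631."""
        b = narrow_pulse_b(0.023, 400.0, 2.22, n_axes=3)
        assert b == pytest.approx(0.6336, abs=5e-4)
        assert b == pytest.approx(0.631, rel=PRINTED_TOL)

    @pytest.mark.parametrize(
        "b0,Delta,expected",
        [(0.631, 400.0, 0.02295), (0.631, 70.0, 0.05511)],
    )
    def test_crusher_q_inversion(self, b0, Delta, expected):
        q0 = crusher_q_for_b0(b0, Delta, 2.22, n_axes=3)
        assert q0 == pytest.approx(expected, abs=5e-5)

    def test_crusher_q_zero_and_negative(self):
        assert crusher_q_for_b0(0.0, 400.0, 2.22, 3) == 0.0
        with pytest.raises(ValueError):
            crusher_q_for_b0(-0.1, 400.0, 2.22, 3)
        with pytest.raises(ValueError):
            narrow_pulse_b(0.1, 0.5, 2.22)  # Delta - delta/3 <= 0

    @settings(max_examples=200, deadline=None)
    @given(
        b0=st.floats(1e-6, 10.0),
        Delta=st.floats(5.0, 500.0),
        delta=st.floats(0.1, 4.0),
        n_axes=st.sampled_from([1, 2, 3]),
    )
    def test_q_b_round_trip(self, b0, Delta, delta, n_axes):
        q = crusher_q_for_b0(b0, Delta, delta, n_axes)
        assert narrow_pulse_b(q, Delta, delta, n_axes) == pytest.approx(b0, rel=1e-12)

    @pytest.mark.parametrize(
        "b,Delta,printed",
        [(3.5, 400.0, 157.0), (3.5, 70.0, 375.0)],
    )
    def test_gradient_strength_matches_printed(self, b, Delta, printed):
        G = diffusion_gradient_strength(b, Delta, 2.22)
        assert G == pytest.approx(printed, rel=PRINTED_TOL)

    def test_gradient_strength_vanishes_with_b(self):
        assert diffusion_gradient_strength(1e-12, 400.0, 2.22) < 1e-3


class TestReferenceSchedule:
    def test_fixed_b0_constant_and_q0_scaling(self):
        scheme = ReferenceScheme("fixed_b0", 0.631, 400.0, 3)
        Deltas = np.array([70.0, 100.0, 200.0, 400.0])
        b0, q0 = reference_schedule(scheme, Deltas, 2.22)
        assert np.allclose(b0, 0.631)
        # q0 ~ (Delta - delta/3)^(-1/2)
        scaled = q0 * np.sqrt(Deltas - 2.22 / 3)
        assert np.allclose(scaled, scaled[0], rtol=1e-12)

    def test_fixed_q0_affine_in_effective_time(self):
        scheme = ReferenceScheme("fixed_q0", 0.631, 400.0, 3)
        Deltas = np.array([70.0, 150.0, 400.0])
        b0, q0 = reference_schedule(scheme, Deltas, 2.22)
        assert np.allclose(q0, q0[0], rtol=1e-12)
        # affine in (Delta - delta/3) with zero intercept
        ratio = b0 / (Deltas - 2.22 / 3)
        assert np.allclose(ratio, ratio[0], rtol=1e-12)
        assert b0[0] / b0[-1] == pytest.approx(0.17347, abs=1e-5)

    def test_schemes_coincide_at_delta_max(self):
        for mode in ("fixed_b0", "fixed_q0"):
            scheme = ReferenceScheme(mode, 0.631, 400.0, 3)
            b0, q0 = reference_schedule(scheme, [400.0], 2.22)
            assert b0[0] == pytest.approx(0.631, rel=1e-12)
            assert q0[0] == pytest.approx(
                crusher_q_for_b0(0.631, 400.0, 2.22, 3), rel=1e-12
            )

    def test_schedule_undefined_beyond_delta_max(self):
        scheme = ReferenceScheme("fixed_q0", 0.631, 400.0, 3)
        with pytest.raises(ValueError, match="delta_max"):
            reference_schedule(scheme, [450.0], 2.22)


class TestTimingInvariants:
    def test_tau_m(self):
        t = SequenceTiming(delta=2.22, Delta=70.0, te=16.0)
        assert t.tau_m == pytest.approx(62.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(delta=-1.0, Delta=70.0),
            dict(delta=2.22, Delta=1.0),
            dict(delta=2.22, Delta=70.0, te=-1.0),
            dict(delta=2.22, Delta=5.0, te=16.0),  # tau_m < 0
        ],
    )
    def test_invalid_timing(self, kwargs):
        with pytest.raises(ValueError):
            SequenceTiming(**kwargs)

    def test_protocol_validation(self):
        scheme = ReferenceScheme("fixed_b0", 0.631, 400.0, 3)
        with pytest.raises(ValueError, match="unit norm"):
            AcquisitionProtocol((70.0, 400.0), 2.22, 3.5, [[1.0, 1.0, 0.0]], scheme)
        with pytest.raises(ValueError, match="increasing"):
            AcquisitionProtocol((400.0, 70.0), 2.22, 3.5, [[1.0, 0, 0]], scheme)
        with pytest.raises(ValueError, match="exceed the reference"):
            AcquisitionProtocol((70.0, 400.0), 2.22, 0.5, [[1.0, 0, 0]], scheme)


class TestBMatrix:
    def test_zero_waveform(self):
        wf = EffectiveWaveform(SequenceTiming(2.22, 70.0), ())
        assert np.allclose(b_matrix(wf).matrix, 0.0)

    def test_rectangular_pair_closed_form(self):
        timing = SequenceTiming(delta=2.22, Delta=70.0, te=16.0)
        wf = build_steam_waveform(
            timing, "modified", q_diffusion=0.2227, direction=(1, 0, 0),
            q_crusher=0.0, q_slice=0.0,
        )
        B = b_matrix(wf)
        expected = 0.2227**2 * (70 - 2.22 / 3)
        assert B.matrix[0, 0] == pytest.approx(expected, rel=1e-9)
        assert B.b == pytest.approx(3.436, abs=2e-3)
        assert abs(B.matrix[0, 1]) < 1e-15 and abs(B.matrix[0, 2]) < 1e-15

    def test_two_axis_pair_additivity(self):
        timing = SequenceTiming(delta=2.22, Delta=70.0, te=16.0)
        one = b_matrix(build_steam_waveform(
            timing, "modified", 0.2227, (1, 0, 0), q_crusher=0.0, q_slice=0.0))
        both = b_matrix(build_steam_waveform(
            timing, "modified", 0.2227 * np.sqrt(2), (1, 1, 0), q_crusher=0.0,
            q_slice=0.0))
        assert both.b == pytest.approx(2 * one.b, rel=1e-9)
        v = both.direction
        assert v[0] == pytest.approx(v[1], rel=1e-6)
        assert abs(v[2]) < 1e-9

    def test_trace_matches_closed_form_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            q = rng.uniform(0.01, 0.3)
            delta = rng.uniform(0.5, 4.0)
            Delta = rng.uniform(40.0, 400.0)
            timing = SequenceTiming(delta=delta, Delta=Delta, te=16.0)
            wf = build_steam_waveform(
                timing, "modified", q, (0, 1, 0), q_crusher=0.0, q_slice=0.0)
            assert b_matrix(wf).b == pytest.approx(
                q**2 * (Delta - delta / 3), rel=1e-6
            )

    def test_bmatrix_type_invariants(self):
        with pytest.raises(ValueError):
            BMatrix(np.array([[1.0, 2.0, 0], [0, 1, 0], [0, 0, 1]]))  # asymmetric
        with pytest.raises(ValueError):
            BMatrix(-np.eye(3))  # not PSD


class TestSteamWaveform:
    def test_zero_areas_give_zero_waveform(self):
        timing = SequenceTiming(2.22, 70.0)
        wf = build_steam_waveform(timing, "conventional", 0.0, q_crusher=0.0, q_slice=0.0)
        assert b_matrix(wf).b == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("variant", ["conventional", "modified"])
    def test_refocusing_invariant(self, variant):
        timing = SequenceTiming(2.22, 250.0)
        wf = build_steam_waveform(timing, variant, 0.2, (0, 0, 1))
        assert wf.is_refocused()
        assert np.abs(wf.net_area()).max() < 1e-12

    def test_conventional_imaging_b_grows_with_Delta(self):
        b70 = imaging_b(SequenceTiming(2.22, 70.0), "conventional")
        b400 = imaging_b(SequenceTiming(2.22, 400.0), "conventional")
        assert b400 > b70

    def test_modified_imaging_b_is_Delta_invariant(self):
        b70 = imaging_b(SequenceTiming(2.22, 70.0), "modified")
        b400 = imaging_b(SequenceTiming(2.22, 400.0), "modified")
        assert b400 == pytest.approx(b70, rel=1e-9)

    def test_overlapping_events_rejected(self):
        timing = SequenceTiming(2.22, 70.0)
        events = (
            GradientEvent("x", 0.1, 1.0, 2.0, 1),
            GradientEvent("x", -0.1, 2.0, 2.0, 1),
        )
        with pytest.raises(WaveformError, match="overlap"):
            EffectiveWaveform(timing, events)

    def test_event_inside_mixing_interval_rejected(self):
        timing = SequenceTiming(2.22, 70.0)  # mixing = [8, 70]
        with pytest.raises(WaveformError, match="mixing"):
            EffectiveWaveform(timing, (GradientEvent("x", 0.1, 20.0, 1.0, 1),))

    def test_unrefocused_waveform_rejected_by_b_matrix(self):
        timing = SequenceTiming(2.22, 70.0)
        wf = EffectiveWaveform(timing, (GradientEvent("x", 0.1, 1.0, 1.0, 1),))
        with pytest.raises(WaveformError, match="refocus"):
            b_matrix(wf)

    def test_pathway_mask_zero_during_mixing(self):
        timing = SequenceTiming(2.22, 100.0)
        wf = build_steam_waveform(timing, "conventional", 0.2)
        t, g, mask = wf.sample(0.05)
        in_mix = ~mask
        assert np.allclose(g[:, in_mix], 0.0)


def test_fibonacci_directions_unit_norm():
    d = fibonacci_directions(30)
    assert d.shape == (30, 3)
    assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
    # reasonably spread: mean direction near zero
    assert np.linalg.norm(d.mean(axis=0)) < 0.15
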