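"""Two-point ADC, scheme curves and differences, tensor fitting, masks, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steamref.adc_analysis import (
    adc_scheme_difference,
    adc_time_curve,
    adc_two_point,
    analyze_dataset,
    fit_tensor,
    fractional_anisotropy,
    time_dependence_summary,
    tissue_masks,
)
from steamref.sequence_models import postmortem_protocol
from steamref.tissue_signals import BiexponentialModel, CylinderTwoCompartmentModel

from conftest import make_protocol


class TestTwoPointADC:
    @settings(max_examples=100, deadline=None)
    @given(
        D=st.floats(0.05, 3.0),
        b=st.floats(0.5, 8.0),
        frac=st.floats(0.0, 0.9),
    )
    def test_mono_exponential_invariant_to_b0(self, D, b, frac):
        b0 = frac * b
        adc = adc_two_point(np.exp(-b * D), np.exp(-b0 * D), b, b0)
        assert adc == pytest.approx(D, rel=1e-10)

    def test_biexp_published_values(self, biexp):
        from steamref.tissue_signals import biexp_attenuation

        S = biexp_attenuation(2.5, biexp)
        assert adc_two_point(S, 1.0, 2.5, 0.0) == pytest.approx(0.5718, abs=1e-4)
        S0 = biexp_attenuation(0.5, biexp)
        assert adc_two_point(S, S0, 2.5, 0.5) == pytest.approx(0.5336, abs=1e-4)

    def test_underestimation_grows_with_b0(self, biexp):
        from steamref.tissue_signals import biexp_attenuation

        S = biexp_attenuation(2.5, biexp)
        adcs = [
            adc_two_point(S, biexp_attenuation(b0, biexp), 2.5, b0)
            for b0 in (0.0, 0.25, 0.5, 0.75)
        ]
        assert all(b < a for a, b in zip(adcs, adcs[1:]))

    def test_errors(self):
        with pytest.raises(ValueError):
            adc_two_point(0.5, 1.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            adc_two_point(-0.5, 1.0, 2.0, 0.0)


class TestADCTimeCurve:
    def test_mono_exponential_flat_all_schemes(self):
        mono = BiexponentialModel(1.0, 0.5, 0.5)
        curve = adc_time_curve(mono, make_protocol(b=2.5, b0_frac=0.2))
        for vals in curve.adc.values():
            assert np.allclose(vals, 0.5, rtol=1e-12)

    def test_biexp_fixed_b0_flat_fixed_q0_declining(self, biexp):
        curve = adc_time_curve(biexp, make_protocol(b=2.5, b0_frac=0.2))
        fb = curve.adc["fixed_b0"]
        fq = curve.adc["fixed_q0"]
        assert np.ptp(fb) < 1e-12
        assert np.all(np.diff(fq) < 0)  # strictly decreasing in Delta
        assert fq[-1] == pytest.approx(fb[-1], rel=1e-12)  # coincide at Delta_max

    def test_scheme_ordering(self, biexp, cylinder):
        """Fixed-b0 has the larger b0 at Delta < Delta_max, so it underestimates
        most: ADC_fixed_b0 <= ADC_fixed_q0 <= ADC_true."""
        for model, b in ((biexp, 2.5), (cylinder, 4.0)):
            curve = adc_time_curve(model, make_protocol(b=b, b0_frac=0.2))
            fb, fq, tr = (curve.adc[k] for k in ("fixed_b0", "fixed_q0", "b0_zero"))
            assert np.all(fb <= fq + 1e-12)
            assert np.all(fq <= tr + 1e-12)
            assert fq[-1] == pytest.approx(fb[-1], rel=1e-12)

    def test_underestimation_monotone_in_b0_fraction(self, biexp):
        prev = None
        for frac in (0.0, 0.1, 0.2, 0.3):
            curve = adc_time_curve(biexp, make_protocol(b=2.5, b0_frac=frac))
            under = curve.adc["b0_zero"] - curve.adc["fixed_q0"]
            if prev is not None:
                assert np.all(under >= prev - 1e-12)
            prev = under

    def test_unknown_scheme_rejected(self, biexp):
        with pytest.raises(ValueError, match="unknown schemes"):
            adc_time_curve(biexp, make_protocol(), schemes=("nope",))


class TestSchemeDifference:
    def test_zero_at_delta_max_and_for_zero_b0(self, biexp):
        curve = adc_time_curve(biexp, make_protocol(b=2.5, b0_frac=0.2))
        diff = adc_scheme_difference(curve)
        assert diff[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(diff[:-1] > 0)  # positive for Delta < Delta_max
        assert np.all(np.diff(diff) < 0)  # largest at the shortest Delta
        curve0 = adc_time_curve(biexp, make_protocol(b=2.5, b0_frac=0.0))
        assert np.allclose(adc_scheme_difference(curve0), 0.0, atol=1e-6)

    def test_mono_exponential_gives_zero_map(self):
        mono = BiexponentialModel(0.4, 0.7, 0.7)
        curve = adc_time_curve(mono, make_protocol(b=2.5, b0_frac=0.2))
        assert np.allclose(adc_scheme_difference(curve), 0.0, atol=1e-9)

    def test_difference_grows_with_b0_over_b(self, biexp):
        peaks = []
        for frac in (0.1, 0.2, 0.3):
            curve = adc_time_curve(biexp, make_protocol(b=2.5, b0_frac=frac))
            peaks.append(np.abs(adc_scheme_difference(curve)).max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_sign_flip_for_free_intracellular_at_short_Delta(self):
        """When D_i > D_h and Delta is short, intracellular diffusion is nearly
        free and the fixed_q0-minus-fixed_b0 difference becomes negative."""
        model = CylinderTwoCompartmentModel(D_h=0.5)  # D_h = 0.25 D_i
        proto = make_protocol(
            b=4.0, b0_frac=0.2, Delta_list=(10.0, 50.0, 150.0, 400.0)
        )
        diff = adc_scheme_difference(adc_time_curve(model, proto))
        assert diff[0] < 0
        assert diff[2] > 0

    def test_missing_scheme_rejected(self, biexp):
        curve = adc_time_curve(
            biexp, make_protocol(), schemes=("fixed_b0", "fixed_q0")
        )
        with pytest.raises(ValueError, match="missing"):
            adc_scheme_difference(curve)


class TestTensorFit:
    @staticmethod
    def _forward(tensor, bmats):
        return np.exp(-np.einsum("vij,ij->v", bmats, tensor))

    @staticmethod
    def _design(protocol, Delta=70.0):
        t_eff = Delta - protocol.delta / 3
        mats = [np.zeros((3, 3))]
        q0 = 0.05
        mats[0] = t_eff * q0**2 * np.ones((3, 3)) / 3  # 3-axis reference
        for d in protocol.directions:
            q = np.sqrt(protocol.nominal_b / t_eff) * d
            mats.append(t_eff * np.outer(q, q))
        return np.array(mats)

    def test_noiseless_recovery(self, protocol):
        D = np.diag([1.0, 0.3, 0.3])
        B = self._design(protocol)
        S = self._forward(D, B)
        fit = fit_tensor(S, B)
        assert np.abs(fit.tensors - D).max() < 1e-6
        assert fit.fa == pytest.approx(0.6444, abs=1e-4)
        assert fit.longitudinal == pytest.approx(1.0, abs=1e-6)
        assert fit.radial == pytest.approx(0.3, abs=1e-6)
        assert not fit.flagged

    def test_isotropic_fa_zero(self, protocol):
        B = self._design(protocol)
        fit = fit_tensor(self._forward(0.7 * np.eye(3), B), B)
        assert fit.fa == pytest.approx(0.0, abs=1e-9)

    def test_eigenvalues_sorted_and_md(self, protocol):
        B = self._design(protocol)
        D = np.diag([0.2, 1.1, 0.5])
        fit = fit_tensor(self._forward(D, B), B)
        assert np.all(np.diff(fit.evals) <= 0)
        assert fit.md == pytest.approx(np.trace(D) / 3, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        B = np.array([np.diag([3.5, 0.0, 0.0])] * 10)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_tensor(np.ones(10), B)

    def test_nonpositive_signal_flagged(self, protocol):
        B = self._design(protocol)
        S = self._forward(np.diag([1.0, 0.3, 0.3]), B)
        bad = S.copy()
        bad[3] = 0.0
        fit = fit_tensor(np.stack([S, bad]), B)
        assert not fit.flagged[0] and fit.flagged[1]
        assert np.isnan(fit.md[1])

    def test_fa_closed_form(self):
        assert fractional_anisotropy(np.array([1.0, 0.3, 0.3])) == pytest.approx(
            0.6444, abs=1e-4
        )
        assert fractional_anisotropy(np.zeros(3)) == 0.0


class TestMasks:
    def test_threshold_logic(self):
        fa = np.array([[0.5, 0.1, 0.1]])
        md = np.array([[0.3, 0.6, 0.2]])
        masks = tissue_masks(fa, md)
        assert masks["wm"].tolist() == [[True, False, False]]
        assert masks["gm"].tolist() == [[False, True, False]]

    def test_support_and_shape_checks(self):
        fa = np.full((2, 2), 0.5)
        md = np.full((2, 2), 0.6)
        support = np.array([[True, False], [True, True]])
        masks = tissue_masks(fa, md, support=support)
        assert masks["wm"].sum() == 3
        with pytest.raises(ValueError, match="grid"):
            tissue_masks(fa, md[:1])


class TestTimeDependenceSummary:
    def test_arithmetic(self):
        curves = {
            "fixed_q0": ([70.0, 400.0], [0.6, 0.48]),
            "fixed_b0": ([70.0, 400.0], [0.6, 0.48]),
        }
        s = time_dependence_summary(curves)
        assert s.delta_adc_pct["fixed_q0"] == pytest.approx(20.0)
        assert s.added_dependence_pct == pytest.approx(0.0)

    def test_added_dependence(self):
        curves = {
            "fixed_q0": ([70.0, 400.0], [1.0, 0.93]),  # 7%
            "fixed_b0": ([70.0, 400.0], [1.0, 0.96]),  # 4%
        }
        s = time_dependence_summary(curves)
        assert s.added_dependence_pct == pytest.approx(75.0)
        s_alt = time_dependence_summary(curves, denominator="fixed_q0")
        assert s_alt.added_dependence_pct == pytest.approx(300.0 / 7.0)

    def test_missing_delta_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            time_dependence_summary({"fixed_b0": ([100.0, 400.0], [0.5, 0.4])})


class TestPipelineT1Invariance:
    def test_two_point_adc_invariant_to_T1(self):
        """Per-Delta reference normalization cancels T1 in the dataset pipeline."""
        from steamref.synthetic_data import make_phantom, simulate_dataset

        proto = postmortem_protocol(n_directions=8)
        tables = []
        for T1 in (300.0, 600.0, 1200.0):
            cfg = {
                "shape": [6, 6, 1],
                "gm_model": {"type": "biexp", "f_s": 0.3, "D_s": 0.2, "D_f": 1.0},
                "relaxation": {
                    "wm": {"T1": T1, "T2": 50.0, "S_base": 1.0},
                    "gm": {"T1": T1, "T2": 50.0, "S_base": 1.0},
                },
                "sigma": 0.0,
                "snr": None,
                "seed": 1,
            }
            ds = simulate_dataset(make_phantom(cfg), proto)
            res = analyze_dataset(ds)
            tables.append(res["curves"][["longitudinal", "radial", "md"]].values)
        assert np.allclose(tables[0], tables[1], rtol=1e-10)
        assert np.allclose(tables[0], tables[2], rtol=1e-10)
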