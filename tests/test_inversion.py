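import numpy as np
import pytest

import uedkit as u
from uedkit.geometry import Atom, MolecularGeometry
from uedkit.inversion import InversionSettings, default_damping
from uedkit.scattering import DiffractionCurve

from conftest import rel_rms


def diatomic(r0, element="C"):
    return MolecularGeometry(
        [Atom(element, (0, 0, 0)), Atom(element, (0, 0, r0))]
    )


def dense_quadrature_peak(r0, k, s_max=10.0):
    """Brute-force oracle: damped sine transform of the diatomic sM on a grid
    ten times denser than production, peak by direct argmax."""
    s = np.linspace(0, s_max, 5001)
    sm = s * np.sinc(s * r0 / np.pi)
    r = np.linspace(0.5, 6.0, 5501)
    f = np.trapezoid(
        sm[None, :] * np.sin(np.outer(r, s)) * np.exp(-k * s**2), s, axis=1
    )
    return r[np.argmax(f)]


class TestExtractSm:
    def test_background_free_round_trip(self, gas_curves):
        atomic, molecular, total = gas_curves
        sm_true = u.modified_scattering(molecular, atomic).intensity
        sm = u.extract_sm(total, atomic, background_order=0).intensity
        assert rel_rms(sm, sm_true) < 0.03

    def test_total_equals_atomic_gives_zero(self, gas_curves, s_grid):
        atomic, _, _ = gas_curves
        fake_total = DiffractionCurve(s_grid, atomic.intensity.copy(), role="total")
        assert np.all(u.extract_sm(fake_total, atomic, 0).intensity == 0)

    def test_cubic_background_preserves_structure(self, gas_curves, s_grid):
        # a smooth cubic pedestal must not displace the real-space peaks
        atomic, molecular, total = gas_curves
        bg = 2.0 - 0.45 * s_grid + 0.04 * s_grid**2 - 0.0012 * s_grid**3
        with_bg = DiffractionCurve(s_grid, total.intensity + bg, role="total")
        sm = u.extract_sm(with_bg, atomic, background_order=3)
        sm_true = u.modified_scattering(molecular, atomic).intensity
        assert rel_rms(sm.intensity, sm_true) < 0.35
        dist = u.sine_transform(sm)
        p1 = u.find_peaks(dist, (1.0, 2.0))[0][0]
        p2 = u.find_peaks(dist, (2.0, 3.0))[0][0]
        assert p1 == pytest.approx(1.42, abs=0.05)
        assert p2 == pytest.approx(2.43, abs=0.05)

    def test_order_too_large_rejected(self, gas_curves):
        atomic, _, total = gas_curves
        with pytest.raises(ValueError):
            u.extract_sm(total, atomic, background_order=len(total.s))


class TestSplice:
    def test_smin_zero_is_pure_experiment(self, gas_curves, s_grid):
        atomic, molecular, _ = gas_curves
        exp = u.modified_scattering(molecular, atomic)
        theo = DiffractionCurve(s_grid, np.full_like(s_grid, 0.5), role="modified")
        out = u.splice_low_s(exp, theo, s_min_experimental=0.0)
        assert np.array_equal(out.intensity, exp.intensity)

    def test_smin_beyond_grid_is_pure_theory(self, gas_curves, s_grid):
        atomic, molecular, _ = gas_curves
        exp = u.modified_scattering(molecular, atomic)
        theo = DiffractionCurve(s_grid, np.full_like(s_grid, 0.5), role="modified")
        out = u.splice_low_s(exp, theo, s_min_experimental=s_grid[-1] + 1.0)
        assert np.array_equal(out.intensity, theo.intensity)

    def test_identical_inputs_unchanged(self, gas_curves):
        atomic, molecular, _ = gas_curves
        sm = u.modified_scattering(molecular, atomic)
        out = u.splice_low_s(sm, sm, s_min_experimental=0.8)
        assert np.allclose(out.intensity, sm.intensity, rtol=1e-12)

    def test_crossfade_is_continuous(self, gas_curves, s_grid):
        atomic, molecular, _ = gas_curves
        exp = u.modified_scattering(molecular, atomic)
        theo = DiffractionCurve(
            s_grid, exp.intensity + 1.0, role="modified"
        )
        out = u.splice_low_s(exp, theo, s_min_experimental=2.0).intensity
        assert np.abs(np.diff(out)).max() < np.abs(np.diff(exp.intensity)).max() + 0.2


class TestSineTransform:
    def test_zero_in_zero_out(self, s_grid):
        sm = DiffractionCurve(s_grid, np.zeros_like(s_grid), role="modified")
        dist = u.sine_transform(sm)
        assert np.all(dist.f == 0)

    def test_f_at_origin_is_exactly_zero(self, gas_curves):
        atomic, molecular, _ = gas_curves
        dist = u.sine_transform(u.modified_scattering(molecular, atomic))
        assert dist.f[0] == 0.0

    @pytest.mark.parametrize("r0", [1.0, 1.5, 2.5, 4.0])
    def test_diatomic_peak_at_bond_length(self, s_grid, r0):
        geom = diatomic(r0)
        sm = u.modified_scattering(
            u.molecular_intensity(geom, s_grid), u.atomic_intensity(geom, s_grid)
        )
        dist = u.sine_transform(sm)
        peak = u.find_peaks(dist, (0.5, 6.0))[0][0]
        oracle = dense_quadrature_peak(r0, dist.settings.k)
        assert abs(peak - oracle) <= 0.011  # one r-grid step
        assert abs(peak - r0) <= 0.011

    @pytest.mark.parametrize("r0", [1.0, 1.5, 2.5, 4.0])
    def test_forward_extract_invert_round_trip(self, s_grid, r0):
        geom = diatomic(r0)
        total = u.total_intensity(geom, s_grid)
        atomic = u.atomic_intensity(geom, s_grid)
        sm = u.extract_sm(total, atomic, background_order=0)
        peak = u.find_peaks(u.sine_transform(sm), (0.5, 6.0))[0][0]
        assert abs(peak - r0) <= 0.011

    def test_linearity(self, s_grid, gas_curves):
        atomic, molecular, _ = gas_curves
        sm1 = u.modified_scattering(molecular, atomic)
        sm2 = DiffractionCurve(s_grid, np.sin(2.0 * s_grid), role="modified")
        combo = DiffractionCurve(
            s_grid, 2.0 * sm1.intensity - 0.5 * sm2.intensity, role="modified"
        )
        f_combo = u.sine_transform(combo).f
        f_parts = 2.0 * u.sine_transform(sm1).f - 0.5 * u.sine_transform(sm2).f
        assert np.allclose(f_combo, f_parts, rtol=1e-10, atol=1e-12)

    def test_damping_broadens_and_lowers(self, s_grid):
        geom = diatomic(1.5)
        sm = u.modified_scattering(
            u.molecular_intensity(geom, s_grid), u.atomic_intensity(geom, s_grid)
        )
        peaks = {}
        for k in (0.01, 0.023, 0.05):
            dist = u.sine_transform(sm, InversionSettings(k=k))
            pos, height = u.find_peaks(dist, (1.0, 2.0))[0]
            peaks[k] = (pos, height)
        heights = [peaks[k][1] for k in (0.01, 0.023, 0.05)]
        assert heights[0] > heights[1] > heights[2]
        positions = [peaks[k][0] for k in (0.01, 0.023, 0.05)]
        assert max(positions) - min(positions) < 0.011

    def test_default_damping_definition(self):
        assert np.exp(-default_damping() * 10.0**2) == pytest.approx(0.1, rel=1e-9)

    def test_smax_beyond_data_rejected(self, s_grid):
        sm = DiffractionCurve(s_grid, np.zeros_like(s_grid), role="modified")
        with pytest.raises(ValueError):
            u.sine_transform(sm, InversionSettings(s_max=12.0))


class TestFindPeaks:
    def test_single_lobe_refined_position(self):
        x = np.linspace(0, 10, 1001)
        y = np.exp(-((x - 3.217) ** 2) / 0.5)
        (pos, height), = u.find_peaks((x, y), (2.0, 4.5))
        assert pos == pytest.approx(3.217, abs=0.01)
        assert height == pytest.approx(1.0, abs=1e-3)

    def test_monotone_curve_has_no_peaks(self):
        x = np.linspace(0, 5, 100)
        assert u.find_peaks((x, x**2)) == []

    def test_sorted_by_height(self):
        x = np.linspace(0, 10, 2001)
        y = 1.0 * np.exp(-((x - 2) ** 2)) + 0.4 * np.exp(-((x - 7) ** 2))
        peaks = u.find_peaks((x, y))
        assert peaks[0][0] == pytest.approx(2.0, abs=0.01)
        assert peaks[1][0] == pytest.approx(7.0, abs=0.01)

    def test_window_outside_grid_rejected(self):
        x = np.linspace(0, 5, 100)
        with pytest.raises(ValueError):
            u.find_peaks((x, x), (6.0, 7.0))
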