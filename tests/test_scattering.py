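import numpy as np
import pytest

import uedkit as u
from uedkit.geometry import Atom, MolecularGeometry, build_glycerol
from uedkit.scattering import DEFAULT_TABLE, DiffractionCurve


def naive_debye(geom, s, table=DEFAULT_TABLE):
    """Literal double-loop interference sum: the oracle for the fast path."""
    symbols = geom.symbols
    coords = geom.coords
    out = np.zeros_like(s)
    for i in range(len(symbols)):
        for j in range(len(symbols)):
            if i == j:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            fi = table.amplitude(symbols[i], s)
            fj = table.amplitude(symbols[j], s)
            out = out + fi * fj * np.sinc(s * r / np.pi)
    return out


def random_geometry(rng, n):
    elements = rng.choice(["H", "C", "O"], size=n)
    # spread out so the 0.5 Å sanity bound never triggers
    coords = rng.uniform(-4.0, 4.0, (n, 3)) + np.arange(n)[:, None] * [1.1, 0, 0]
    return MolecularGeometry([Atom(e, tuple(c)) for e, c in zip(elements, coords)])


class TestWavelength:
    def test_100kv_value(self):
        # hc / sqrt(E(E + 2 mc^2)) evaluated independently: 0.037014 Å
        assert u.electron_wavelength(100.0) == pytest.approx(0.037014, abs=1e-5)

    def test_decreases_with_energy(self):
        assert u.electron_wavelength(200.0) < u.electron_wavelength(100.0)

    @pytest.mark.parametrize("kv", [0.0, -5.0, 700.0])
    def test_rejects_unsupported_voltage(self, kv):
        with pytest.raises(ValueError):
            u.electron_wavelength(kv)


class TestScatteringTable:
    def test_amplitudes_positive_and_decreasing(self, s_grid):
        for el in ("H", "C", "O"):
            f = DEFAULT_TABLE.amplitude(el, s_grid)
            assert np.all(f > 0)
            assert np.all(np.diff(f) <= 0)

    def test_untabulated_element(self, s_grid):
        with pytest.raises(KeyError):
            DEFAULT_TABLE.amplitude("U", s_grid)


class TestAtomicIntensity:
    def test_additivity_independent_of_coordinates(self, s_grid):
        one = u.atomic_intensity(
            MolecularGeometry([Atom("O", (0, 0, 0))]), s_grid
        ).intensity
        two = u.atomic_intensity(
            MolecularGeometry([Atom("O", (0, 0, 0)), Atom("O", (5, 3, 1))]), s_grid
        ).intensity
        assert np.allclose(two, 2 * one, rtol=1e-12)

    def test_glycerol_equals_per_atom_sum(self, glycerol, s_grid):
        acc = np.zeros_like(s_grid)
        for atom in glycerol.atoms:
            acc += DEFAULT_TABLE.amplitude(atom.element, s_grid) ** 2
        assert np.allclose(
            u.atomic_intensity(glycerol, s_grid).intensity, acc, rtol=1e-12
        )


class TestMolecularIntensity:
    def test_single_atom_is_zero(self, s_grid):
        geom = MolecularGeometry([Atom("C", (0, 0, 0))])
        assert np.all(u.molecular_intensity(geom, s_grid).intensity == 0)

    def test_homonuclear_diatomic_closed_form(self, s_grid):
        r = 1.1
        geom = MolecularGeometry([Atom("C", (0, 0, 0)), Atom("C", (0, 0, r))])
        f = DEFAULT_TABLE.amplitude("C", s_grid)
        expected = 2 * f**2 * np.sinc(s_grid * r / np.pi)
        got = u.molecular_intensity(geom, s_grid).intensity
        assert np.allclose(got, expected, rtol=1e-12)
        assert got[0] == pytest.approx(2 * f[0] ** 2)  # sinc -> 1 limit at s=0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, s_grid, seed):
        rng = np.random.default_rng(seed)
        geom = random_geometry(rng, int(rng.integers(2, 21)))
        sub = s_grid[::25]
        assert np.allclose(
            u.molecular_intensity(geom, sub).intensity,
            naive_debye(geom, sub),
            rtol=1e-10,
        )

    def test_low_s_limit_from_amplitude_sums(self, glycerol):
        # I_mol(0) = (sum f)^2 - sum f^2 when all phases vanish
        s = np.array([0.0, 0.01])
        f0 = np.array(
            [DEFAULT_TABLE.amplitude(a.element, np.zeros(1))[0] for a in glycerol.atoms]
        )
        expected = f0.sum() ** 2 - (f0**2).sum()
        got = u.molecular_intensity(glycerol, s).intensity[0]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_rigid_motion_invariance(self, glycerol, s_grid):
        rng = np.random.default_rng(1)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        moved = glycerol.transformed(rot, np.array([7.0, -3.0, 2.0]))
        a = u.molecular_intensity(glycerol, s_grid).intensity
        b = u.molecular_intensity(moved, s_grid).intensity
        assert np.allclose(a, b, rtol=1e-10)

    def test_histogram_path_tracks_exact_path(self, glycerol, s_grid):
        exact = u.molecular_intensity(glycerol, s_grid, method="exact").intensity
        hist = u.molecular_intensity(glycerol, s_grid, method="histogram").intensity
        scale = np.abs(exact).max()
        assert np.abs(hist - exact).max() / scale < 1e-3


class TestTotalAndModified:
    def test_total_decomposes(self, glycerol, s_grid, gas_curves):
        atomic, molecular, total = gas_curves
        assert np.allclose(
            total.intensity - atomic.intensity, molecular.intensity, rtol=1e-12
        )

    def test_single_molecule_liquid_matches_gas(self, glycerol, s_grid):
        configs = [u.pack_droplet(glycerol, 1, seed=k) for k in range(3)]
        ens = u.total_intensity(configs, s_grid)
        gas = u.total_intensity(glycerol, s_grid)
        assert np.allclose(ens.intensity, gas.intensity, rtol=1e-9)

    def test_modified_scattering_zero_cases(self, gas_curves, s_grid):
        atomic, molecular, total = gas_curves
        zero = DiffractionCurve(s_grid, np.zeros_like(s_grid), role="molecular")
        assert np.all(u.modified_scattering(zero, atomic).intensity == 0)
        sm = u.modified_scattering(total, atomic)
        assert sm.intensity[0] == 0.0  # s multiplication forces sM(0) = 0

    def test_diatomic_sm_zero_crossings(self, s_grid):
        r = 1.5
        geom = MolecularGeometry([Atom("O", (0, 0, 0)), Atom("O", (0, 0, r))])
        sm = u.modified_scattering(
            u.molecular_intensity(geom, s_grid), u.atomic_intensity(geom, s_grid)
        ).intensity
        # sM ∝ s sinc(s r): first sign change at s = pi / r
        crossing = s_grid[np.where(np.diff(np.sign(sm[1:])) != 0)[0][0] + 1]
        assert crossing == pytest.approx(np.pi / r, abs=0.03)

    def test_s2_weighting(self, gas_curves, s_grid):
        _, _, total = gas_curves
        w = u.s2_weighted(total)
        assert w.intensity[0] == 0.0
        const = DiffractionCurve(s_grid, np.ones_like(s_grid))
        assert np.allclose(u.s2_weighted(const).intensity, s_grid**2)

    def test_grid_mismatch_rejected(self, gas_curves):
        atomic, _, total = gas_curves
        other = DiffractionCurve(total.s[:-1], total.intensity[:-1], role="total")
        with pytest.raises(ValueError):
            u.modified_scattering(other, atomic)


class TestCurveIO:
    def test_round_trip(self, tmp_path, gas_curves):
        _, _, total = gas_curves
        total.meta["accel_voltage_kv"] = 100.0
        path = tmp_path / "curve.dat"
        u.write_curve(total, path)
        back = u.read_curve(path)
        assert back.role == "total"
        assert np.allclose(back.s, total.s)
        assert np.allclose(back.intensity, total.intensity, rtol=1e-9)
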