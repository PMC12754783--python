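"""Spectrum I/O, window integration, noise estimation and species tables."""

import numpy as np
import pytest

from g4screen import io, mzml
from g4screen.equilibria import BindingSample
from g4screen.masses import Ligand, Oligo, SpeciesKey
from g4screen.spectra import (
    MassSpectrum,
    SpeciesWindow,
    build_species_table,
    correct_intensity,
    estimate_noise,
    integrate_window,
    read_spectrum,
    write_table,
)
from g4screen.synthetic import SimConfig, simulate_spectrum


def _key(oligo, **kw):
    return SpeciesKey(target=oligo, **kw)


class TestReadSpectrum:
    def test_three_point_table(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("100 1.0\n101 2.0\n102 0.5\n")
        spec = read_spectrum(p, "table")
        assert spec.mz.size == 3
        assert spec.intensity[1] == 2.0

    def test_unsorted_table_rejected(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("101 1.0\n100 2.0\n")
        with pytest.raises(ValueError):
            read_spectrum(p, "table")

    def test_empty_rejected(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("")
        with pytest.raises(ValueError):
            read_spectrum(p, "table")

    def test_mzml_round_trip_bit_identical(self, tmp_path):
        mz = np.linspace(1000.0, 2000.0, 512) + 1e-9 * np.arange(512)
        inten = np.abs(np.sin(mz))
        path = tmp_path / "s.mzML"
        mzml.write_mzml(path, mz, inten)
        spec = read_spectrum(path, "mzml")
        assert np.array_equal(spec.mz, mz)
        assert np.array_equal(spec.intensity, inten)

    def test_table_round_trip(self, tmp_path):
        spec = MassSpectrum(mz=np.array([1.0, 2.0, 3.0]),
                            intensity=np.array([0.0, 5.0, 1.0]))
        p = tmp_path / "t.txt"
        write_table(p, spec)
        back = read_spectrum(p, "table")
        np.testing.assert_allclose(back.mz, spec.mz)
        np.testing.assert_allclose(back.intensity, spec.intensity)


class TestIntegrateWindow:
    def _flat(self):
        return MassSpectrum(mz=np.linspace(0, 10, 1001),
                            intensity=np.ones(1001))

    def test_flat_area(self):
        w = SpeciesWindow(_key(Oligo("x", "T")), center=5.0, half_width=1.0)
        assert integrate_window(self._flat(), w) == pytest.approx(2.0)

    def test_outside_range_returns_zero_with_warning(self):
        w = SpeciesWindow(_key(Oligo("x", "T")), center=50.0, half_width=1.0)
        with pytest.warns(UserWarning):
            assert integrate_window(self._flat(), w) == 0.0

    def test_gaussian_area_within_1pct(self):
        mz = np.linspace(90, 110, 4001)
        sigma, area = 0.3, 7.5
        inten = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((mz - 100.0) / sigma) ** 2
        )
        spec = MassSpectrum(mz=mz, intensity=inten)
        w = SpeciesWindow(_key(Oligo("x", "T")), center=100.0, half_width=5.0)
        assert integrate_window(spec, w) == pytest.approx(area, rel=0.01)

    def test_additive_over_disjoint_windows(self):
        spec = self._flat()
        k = _key(Oligo("x", "T"))
        whole = SpeciesWindow(k, center=5.0, half_width=2.0)
        left = SpeciesWindow(k, center=4.0, half_width=1.0)
        right = SpeciesWindow(k, center=6.0, half_width=1.0)
        assert integrate_window(spec, whole) == pytest.approx(
            integrate_window(spec, left) + integrate_window(spec, right)
        )


class TestNoise:
    def test_constant_region_zero(self):
        spec = MassSpectrum(mz=np.linspace(0, 10, 100),
                            intensity=np.full(100, 3.0))
        assert estimate_noise(spec, (0, 10)) == 0.0

    def test_known_sigma_recovered(self, rng):
        spec = MassSpectrum(
            mz=np.linspace(0, 10, 1000),
            intensity=np.abs(rng.normal(10.0, 2.0, 1000)),
        )
        assert estimate_noise(spec, (0, 10)) == pytest.approx(2.0, rel=0.2)

    def test_overlap_with_species_window_rejected(self):
        spec = MassSpectrum(mz=np.linspace(0, 10, 100),
                            intensity=np.ones(100))
        w = SpeciesWindow(_key(Oligo("x", "T")), center=5.0, half_width=1.0)
        with pytest.raises(ValueError):
            estimate_noise(spec, (4, 8), species_windows=[w])

    def test_too_few_points_rejected(self):
        spec = MassSpectrum(mz=np.linspace(0, 10, 100),
                            intensity=np.ones(100))
        with pytest.raises(ValueError):
            estimate_noise(spec, (0.0, 0.5))

    @pytest.mark.parametrize(
        "raw,sigma,n,expected",
        [(100.0, 0.0, 5, 100.0), (5.0, 10.0, 1, 0.0), (100.0, 10.0 / 3, 1, 90.0)],
    )
    def test_correct_intensity(self, raw, sigma, n, expected):
        assert correct_intensity(raw, sigma, n) == pytest.approx(expected)

    def test_correct_intensity_monotone(self):
        assert correct_intensity(10, 1) <= correct_intensity(20, 1)
        assert correct_intensity(10, 2) <= correct_intensity(10, 1)


class TestBuildSpeciesTable:
    def test_only_m_species_present(self, qqpq):
        oligo = Oligo("x", "TGGGTTGGGTTGGGTTGGGT")
        cfg = SimConfig(adduct_lambda=0.3)
        spec, _ = simulate_spectrum(
            BindingSample(M0=10, L0=0), 1.0, 10.0, cfg, oligo, qqpq
        )
        keys = [
            _key(oligo, ligand_count=lc, k_count=n, charge_magnitude=z)
            for lc in (0, 1, 2) for n in range(4) for z in (4, 5)
        ]
        table = build_species_table(spec, keys, qqpq)
        i_m, i_ml, i_ml2 = table.intensity_triplet()
        assert i_m > 0
        # complexes absent up to far Gaussian tails of the M envelope
        assert i_ml <= 1e-9 * i_m and i_ml2 <= 1e-9 * i_m

    def test_recovers_generator_ledger_within_1pct(self, qqpq):
        oligo = Oligo("x", "TGGGTTGGGTTGGGTTGGGT")
        cfg = SimConfig(adduct_lambda=0.4, peak_sigma=0.25)
        spec, ledger = simulate_spectrum(
            BindingSample(M0=10, L0=20), 1.5, 22.0, cfg, oligo, qqpq
        )
        keys = [k for k in ledger["areas"] if ledger["areas"][k] > 1.0]
        table = build_species_table(spec, keys, qqpq, half_width=0.9)
        for key in keys:
            assert table.entries[key] == pytest.approx(
                ledger["areas"][key], rel=0.02
            )

    def test_relative_abundance_recovery_at_high_snr(self, qqpq):
        oligo = Oligo("x", "TGGGTTGGGTTGGGTTGGGT")
        cfg = SimConfig(adduct_lambda=0.4, peak_sigma=0.25, noise_sigma=1.0,
                        intensity_scale=1e5, seed=3)
        spec, ledger = simulate_spectrum(
            BindingSample(M0=10, L0=20), 1.5, 22.0, cfg, oligo, qqpq
        )
        keys = list(ledger["areas"])
        table = build_species_table(spec, keys, qqpq, half_width=0.9,
                                    noise_sigma=1.0)
        got = np.array(table.intensity_triplet())
        truth = np.array(
            [ledger["stoichiometry_totals"][i] for i in range(3)]
        )
        np.testing.assert_allclose(got / got.sum(), truth / truth.sum(),
                                   atol=0.02)

    def test_colliding_windows_flagged(self, qqpq):
        oligo = Oligo("x", "TGGGT")
        k1 = _key(oligo, ligand_count=0, charge_magnitude=1)
        k2 = _key(oligo, ligand_count=1, charge_magnitude=1)
        tight = Ligand("tiny", 0.5)  # ML lands almost on M
        spec = MassSpectrum(mz=np.linspace(1000, 3000, 2000),
                            intensity=np.ones(2000))
        with pytest.warns(UserWarning, match="ambiguous"):
            table = build_species_table(spec, [k1, k2], tight, tolerance=1.0)
        assert set(table.ambiguous) == {k1, k2}
        assert table.entries == {}


class TestSpeciesTableIO:
    def test_csv_round_trip(self, tmp_path, qqpq):
        oligo = Oligo("x", "TGGGT")
        from g4screen.spectra import SpeciesTable

        t = SpeciesTable(noise_sigma=1.5, internal_standard_intensity=42.0)
        t.entries[_key(oligo, ligand_count=1, k_count=2, charge_magnitude=5)] = 7.25
        p = tmp_path / "table.csv"
        io.write_species_table(p, t)
        back = io.read_species_table(p, target=oligo)
        assert back.noise_sigma == 1.5
        assert back.internal_standard_intensity == 42.0
        assert list(back.entries.values()) == [7.25]
        key = next(iter(back.entries))
        assert (key.ligand_count, key.k_count, key.charge_magnitude) == (1, 2, 5)
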