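"""Spectral types, peak extraction, shift calls, quench ratios, CD conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind import (
    AxisKind,
    CDRecord,
    Spectrum,
    TitrationSeries,
    classify_shift,
    find_peak,
    molar_ellipticity,
    quench_ratios,
    read_spectra_csv,
    write_spectra_csv,
)
from quenchbind.spectra import PeakInfo, PeakMethod, ShiftDirection


def gaussian_spectrum(center, width=10.0, f0=1000.0, temperature=298.0,
                      lo=300.0, hi=500.0, step=1.0):
    axis = np.arange(lo, hi + step / 2, step)
    signal = f0 * np.exp(-((axis - center) ** 2) / (2 * width**2))
    return Spectrum(AxisKind.WAVELENGTH_NM, axis, signal, temperature)


class TestSpectrumInvariants:
    def test_rejects_decreasing_axis(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(AxisKind.WAVELENGTH_NM, [3, 2, 1], [1, 1, 1], 298.0)

    def test_rejects_length_mismatch_and_short(self):
        with pytest.raises(ValueError, match="equal length"):
            Spectrum(AxisKind.WAVELENGTH_NM, [1, 2, 3], [1, 2], 298.0)
        with pytest.raises(ValueError, match="at least 3"):
            Spectrum(AxisKind.WAVELENGTH_NM, [1, 2], [1, 2], 298.0)

    def test_rejects_negative_fluorescence_but_not_cd(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum(AxisKind.WAVELENGTH_NM, [1, 2, 3], [1, -1, 1], 298.0)
        cd = Spectrum(AxisKind.WAVELENGTH_NM, [1, 2, 3], [1, -1, 1], 298.0,
                      signal_kind="cd_degrees")
        assert cd.signal[1] == -1

    def test_series_requires_single_zero_reference(self):
        s = gaussian_spectrum(338.0)
        with pytest.raises(ValueError, match="no F0 reference"):
            TitrationSeries((s, s), np.array([1e-6, 2e-6]))


class TestFindPeak:
    def test_on_grid_center_found_exactly(self):
        peak = find_peak(gaussian_spectrum(338.0), window=1)
        assert peak.position == pytest.approx(338.0, abs=1e-9)
        assert peak.method is PeakMethod.PARABOLIC

    def test_off_grid_center_within_tenth_nm(self):
        # oracle: dense-grid argmax of the generating Gaussian is its center
        peak = find_peak(gaussian_spectrum(337.4), window=1)
        assert peak.position == pytest.approx(337.4, abs=0.1)

    def test_monotone_ramp_flags_boundary(self):
        axis = np.arange(300.0, 320.0)
        spec = Spectrum(AxisKind.WAVELENGTH_NM, axis, axis - 299.0, 298.0)
        with pytest.warns(UserWarning, match="boundary"):
            peak = find_peak(spec, window=1)
        assert peak.boundary and peak.method is PeakMethod.ARGMAX
        assert peak.position == axis[-1]

    def test_flat_spectrum_has_no_peak(self):
        spec = Spectrum(AxisKind.WAVELENGTH_NM, [1.0, 2.0, 3.0], [5.0, 5.0, 5.0], 298.0)
        with pytest.raises(ValueError, match="no peak"):
            find_peak(spec, window=1)

    def test_even_or_oversized_window_rejected(self):
        spec = gaussian_spectrum(338.0)
        with pytest.raises(ValueError, match="odd"):
            find_peak(spec, window=4)
        with pytest.raises(ValueError, match="exceeds"):
            find_peak(spec, window=len(spec) + 2)

    def test_smoothing_requires_uniform_grid(self):
        axis = np.array([300.0, 301.0, 303.0, 304.0, 305.0])
        spec = Spectrum(AxisKind.WAVELENGTH_NM, axis, [1, 2, 5, 2, 1], 298.0)
        with pytest.raises(ValueError, match="uniform"):
            find_peak(spec, window=3)
        find_peak(spec, window=1)  # no smoothing is fine

    @given(delta=st.floats(-5.0, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_translation_equivariance(self, delta):
        """Shifting the band center by delta shifts the parabolic estimate
        by delta within 0.05 grid steps."""
        base = find_peak(gaussian_spectrum(380.0), window=5)
        moved = find_peak(gaussian_spectrum(380.0 + delta), window=5)
        assert moved.position - base.position == pytest.approx(delta, abs=0.05)


class TestClassifyShift:
    def _peak(self, pos, kind=AxisKind.WAVELENGTH_NM):
        return PeakInfo(position=pos, height=1.0, method=PeakMethod.ARGMAX, axis_kind=kind)

    def test_tryptophan_band_blue_shift(self):
        call = classify_shift(self._peak(338.0), self._peak(335.5), tolerance=0.5)
        assert call.direction is ShiftDirection.DOWNSHIFT
        assert call.delta == pytest.approx(-2.5)
        assert "blue shift" in call.describe()

    def test_identical_positions_no_shift(self):
        call = classify_shift(self._peak(338.0), self._peak(338.0), tolerance=0.5)
        assert call.direction is ShiftDirection.NONE and call.delta == 0.0

    def test_amide_band_upshift_on_wavenumber_axis(self):
        call = classify_shift(
            self._peak(1651.0, AxisKind.WAVENUMBER_CM),
            self._peak(1655.0, AxisKind.WAVENUMBER_CM),
            tolerance=1.0,
        )
        assert call.direction is ShiftDirection.UPSHIFT
        assert call.delta == pytest.approx(4.0)
        assert "blue" not in call.describe()

    def test_mismatched_axis_kinds_rejected(self):
        with pytest.raises(ValueError, match="axis kind"):
            classify_shift(self._peak(338.0), self._peak(1651.0, AxisKind.WAVENUMBER_CM), 0.5)


def static_series(ka=1e5, concs=(0.0, 2e-6, 4e-6, 6e-6, 8e-6, 10e-6), noise=None, seed=0):
    axis = np.arange(300.0, 501.0)
    rng = np.random.default_rng(seed)
    spectra, qs = [], []
    for q in concs:
        f = 1000.0 / (1 + ka * q)
        signal = f * np.exp(-((axis - 338.0) ** 2) / (2 * 100.0))
        if noise:
            signal = signal * (1 + rng.normal(0, noise, signal.shape))
            signal = np.clip(signal, 0, None)
        spectra.append(Spectrum(AxisKind.WAVELENGTH_NM, axis, signal, 298.0))
        qs.append(q)
    return TitrationSeries(tuple(spectra), np.array(qs))


class TestQuenchRatios:
    def test_closed_form_static_model_exact(self):
        table = quench_ratios(static_series())
        expected = [1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
        assert table["F0_over_F"].to_numpy() == pytest.approx(expected, rel=1e-12)
        assert table["F0_minus_F_over_F"].to_numpy() == pytest.approx(
            [e - 1 for e in expected], abs=1e-12
        )

    def test_reference_only_series(self):
        table = quench_ratios(static_series(concs=(0.0,)))
        assert len(table) == 1
        assert table.iloc[0]["F0_over_F"] == 1.0
        assert table.iloc[0]["F0_minus_F_over_F"] == 0.0

    def test_noisy_ratios_near_noiseless_oracle(self):
        # oracle: regenerate the identical series without noise
        noisy = quench_ratios(static_series(noise=0.01, seed=7))
        clean = quench_ratios(static_series())
        assert noisy["F0_over_F"].to_numpy() == pytest.approx(
            clean["F0_over_F"].to_numpy(), rel=0.03
        )

    def test_enhancement_rows_flagged(self):
        series = static_series()
        brighter = Spectrum(
            series.spectra[0].axis_kind,
            series.spectra[0].axis,
            series.spectra[0].signal * 1.5,
            298.0,
        )
        spectra = (*series.spectra[:-1], brighter)
        bumped = TitrationSeries(spectra, series.quencher_conc)
        table = quench_ratios(bumped)
        assert bool(table.iloc[-1]["enhancement"])
        assert not table.iloc[:-1]["enhancement"].any()

    def test_per_spectrum_peak_mode(self):
        table = quench_ratios(static_series(), at="per_spectrum_peak")
        assert table["F0_over_F"].to_numpy() == pytest.approx(
            [1.0, 1.2, 1.4, 1.6, 1.8, 2.0], rel=1e-9
        )


class TestMolarEllipticity:
    def _record(self, theta, residues=1, conc=1.0, path=1.0):
        axis = np.array([200.0, 210.0, 220.0])
        spec = Spectrum(AxisKind.WAVELENGTH_NM, axis, np.full(3, theta), 298.0,
                        signal_kind="cd_degrees")
        return CDRecord(spec, protein_conc=conc, path_length=path, residue_count=residues)

    def test_unit_inputs_reduce_to_theta_over_ten(self):
        out = molar_ellipticity(self._record(0.5))
        assert out.signal == pytest.approx([0.05] * 3)

    def test_hand_calculator_case(self):
        # 0.01 / (400 * 6e-6 * 0.1 * 10) computed independently = 4.1666...
        out = molar_ellipticity(self._record(0.01, residues=400, conc=6e-6, path=0.1))
        assert out.signal == pytest.approx([4.166666666666666] * 3)

    def test_zero_signal_stays_zero(self):
        out = molar_ellipticity(self._record(0.0, residues=400, conc=6e-6, path=0.1))
        assert np.all(out.signal == 0.0)

    def test_invalid_metadata_rejected(self):
        with pytest.raises(ValueError):
            self._record(0.5, conc=0.0)
        with pytest.raises(ValueError):
            self._record(0.5, residues=0)

    def test_millidegree_convenience(self):
        spec = self._record(500.0).spectrum  # pretend mdeg
        rec = CDRecord.from_millidegrees(spec, 1.0, 1.0, 1)
        assert molar_ellipticity(rec).signal == pytest.approx([0.05] * 3)

    @given(scale=st.floats(0.1, 10.0), residues=st.integers(1, 500))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_theta_inverse_in_residues(self, scale, residues):
        base = molar_ellipticity(self._record(0.2)).signal
        scaled = molar_ellipticity(self._record(0.2 * scale)).signal
        divided = molar_ellipticity(self._record(0.2, residues=residues)).signal
        assert scaled == pytest.approx(base * scale, rel=1e-12)
        assert divided == pytest.approx(base / residues, rel=1e-12)


class TestSpectraCSV:
    def test_round_trip_lossless(self, tmp_path):
        series = [static_series(), static_series(ka=5e4)]
        # distinct temperature so the two series group separately
        series[1] = TitrationSeries(
            tuple(
                Spectrum(s.axis_kind, s.axis, s.signal, 318.0, s.sample_id)
                for s in series[1].spectra
            ),
            series[1].quencher_conc,
        )
        path = tmp_path / "spectra.csv"
        write_spectra_csv(path, series)
        back = read_spectra_csv(path)
        assert len(back) == 2
        for orig, rt in zip(series, back):
            assert rt.temperature == orig.temperature
            assert rt.quencher_conc == pytest.approx(orig.quencher_conc, rel=1e-12)
            for s0, s1 in zip(orig.spectra, rt.spectra):
                assert s1.signal == pytest.approx(s0.signal, rel=1e-11)

    def test_missing_column_and_missing_reference(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,temperature_K\nA,298\n")
        with pytest.raises(ValueError, match="missing column"):
            read_spectra_csv(path)
        write_spectra_csv(path, [static_series()])
        frame = pd.read_csv(path)
        frame = frame[frame["quencher_conc_M"] > 0]
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="no F0 reference"):
            read_spectra_csv(path)

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_spectra_csv(path, [static_series()])
        lines = path.read_text().splitlines()
        lines[3] = lines[3].replace(lines[3].split(",")[-1], "oops")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 4"):
            read_spectra_csv(path)

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        write_spectra_csv(path, [static_series()])
        lines = path.read_text().splitlines()
        lines.append(lines[1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_csv(path)
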