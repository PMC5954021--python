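"""Peptide mass/m-z arithmetic, XIC extraction, normalization, occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from glycoemt import (
    PeptideIon,
    apply_deamidation,
    compute_site_occupancy,
    extract_xic,
    integrate_trace,
    ion_mz,
    monoisotopic_mass,
    mz_window,
    normalize_to_reference,
)
from glycoemt.constants import DEAMIDATION_DELTA, RESIDUE_MONO_MASS, WATER_MONO_MASS
from glycoemt.errors import (
    InvalidInputError,
    MissingReferenceError,
    ZeroReferenceError,
)
from glycoemt.glyco import (
    PeakMeasurement,
    RunCondition,
    Scan,
    SpectrumSet,
    Variant,
    XICTrace,
)

AA = sorted(RESIDUE_MONO_MASS)
sequences = st.text(alphabet=AA, min_size=0, max_size=30)


class TestMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("", 18.010565),  # water only
            ("G", 75.032028),  # glycine residue + water
            ("DQLSLGNAALQITDVK", 1684.8995),
        ],
    )
    def test_known_masses(self, seq, expected):
        assert monoisotopic_mass(seq) == pytest.approx(expected, abs=1e-4)

    def test_unknown_residue_names_character_and_position(self):
        with pytest.raises(InvalidInputError, match=r"'B' at position 3"):
            monoisotopic_mass("GABG")

    @given(sequences)
    def test_agrees_with_pyteomics(self, seq):
        assert monoisotopic_mass(seq) == pytest.approx(
            pyteomics_mass.fast_mass(seq), abs=1e-3
        )

    @given(sequences, sequences)
    def test_mass_additivity(self, a, b):
        """Concatenation adds residue masses and removes one water."""
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b) - WATER_MONO_MASS,
            abs=1e-9,
        )


class TestIonMz:
    @pytest.mark.parametrize(
        "mass,charge,expected",
        [
            (1684.8995, 2, 843.4570),  # DQLSLGNAALQITDVK 2+
            (1755.8791, 3, 586.3003),  # AEVIWTSSDHQVLSGK 3+
        ],
    )
    def test_published_reference_mz(self, mass, charge, expected):
        assert ion_mz(mass, charge) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(min_value=0.01, max_value=1e5))
    def test_singly_protonated(self, m):
        assert ion_mz(m, 1) == pytest.approx(m + 1.00727646, abs=1e-12)

    @given(st.floats(min_value=1.1, max_value=1e5), st.integers(1, 9))
    def test_strictly_decreasing_in_charge(self, m, z):
        assert ion_mz(m, z) > ion_mz(m, z + 1)

    def test_round_trip_from_sequences(self):
        """Printed reference m/z reproduced from sequence + charge alone."""
        assert round(ion_mz(monoisotopic_mass("DQLSLGNAALQITDVK"), 2), 4) == 843.4570
        assert round(ion_mz(monoisotopic_mass("AEVIWTSSDHQVLSGK"), 3), 4) == 586.3003

    def test_invalid_charge(self):
        with pytest.raises(InvalidInputError):
            ion_mz(100.0, 0)


class TestDeamidation:
    def test_single_site_shift(self):
        ion = PeptideIon("LFNVTSTLR", 2)
        shifted = apply_deamidation(ion, 3)
        assert shifted.mass == pytest.approx(ion.mass + 0.984016, abs=1e-6)
        assert shifted.variant is Variant.DEAMIDATED

    def test_double_application_errors(self):
        ion = apply_deamidation(PeptideIon("LFNVTSTLR", 2), 3)
        with pytest.raises(InvalidInputError):
            apply_deamidation(ion, 3)

    def test_non_asn_position_errors(self):
        with pytest.raises(InvalidInputError):
            apply_deamidation(PeptideIon("LFNVTSTLR", 2), 1)

    def test_k_sites_additive(self):
        ion = PeptideIon("NGNGNGK", 1)
        base = ion.mass
        for k, pos in enumerate([1, 3, 5], start=1):
            ion = apply_deamidation(ion, pos)
            assert ion.mass == pytest.approx(base + k * DEAMIDATION_DELTA, abs=1e-9)


class TestMzWindow:
    @pytest.mark.parametrize(
        "mz,ppm,lo,hi",
        [
            (100.0, 10, 99.9990, 100.0010),
            (843.4570, 10, 843.448565, 843.465435),
        ],
    )
    def test_window_bounds(self, mz, ppm, lo, hi):
        got = mz_window(mz, ppm)
        assert got[0] == pytest.approx(lo, abs=1e-6)
        assert got[1] == pytest.approx(hi, abs=1e-6)

    @given(st.floats(min_value=1, max_value=5000))
    def test_zero_tolerance_degenerates(self, mz):
        assert mz_window(mz, 0) == (mz, mz)


def _spectra(scans):
    return SpectrumSet(
        scans=tuple(
            Scan(retention_time=rt, mz_values=np.array(mz), intensities=np.array(ii))
            for rt, mz, ii in scans
        )
    )


class TestXIC:
    def test_exact_match_and_summation(self):
        spectra = _spectra(
            [
                (1.0, [500.0], [5.0]),
                (2.0, [499.9999, 500.0001, 600.0], [3.0, 4.0, 9.0]),
            ]
        )
        trace = extract_xic(spectra, 500.0, 10)
        assert trace.points == ((1.0, 5.0), (2.0, 7.0))

    def test_out_of_window_centroid_excluded(self):
        spectra = _spectra([(1.0, [500.0 * (1 + 2e-5)], [5.0])])
        trace = extract_xic(spectra, 500.0, 10)  # centroid is 20 ppm away
        assert trace.points == ((1.0, 0.0),)

    def test_boundary_inclusive(self):
        lo, hi = mz_window(500.0, 10)
        spectra = _spectra([(1.0, [lo, hi], [1.0, 2.0])])
        assert extract_xic(spectra, 500.0, 10).points == ((1.0, 3.0),)

    def test_empty_spectrum_set(self):
        assert extract_xic(SpectrumSet(scans=()), 500.0, 10).points == ()

    @given(st.floats(min_value=0, max_value=50), st.floats(min_value=0, max_value=50))
    def test_widening_tolerance_is_monotone(self, ppm_a, ppm_b):
        spectra = _spectra(
            [(1.0, [499.99, 500.0, 500.004], [1.0, 2.0, 3.0]),
             (2.0, [500.002], [7.0])]
        )
        narrow, wide = sorted([ppm_a, ppm_b])
        pts_narrow = extract_xic(spectra, 500.0, narrow).points
        pts_wide = extract_xic(spectra, 500.0, wide).points
        assert all(w >= n for (_, n), (_, w) in zip(pts_narrow, pts_wide))
        assert sum(p for _, p in pts_wide) <= spectra.total_intensity()


class TestIntegrateTrace:
    def test_rectangle(self):
        trace = XICTrace(500.0, 10, tuple((t, 1.0) for t in np.linspace(0, 10, 11)))
        assert integrate_trace(trace) == pytest.approx(10.0)

    def test_triangle(self):
        trace = XICTrace(500.0, 10, ((0.0, 0.0), (2.0, 6.0), (4.0, 0.0)))
        assert integrate_trace(trace) == pytest.approx(6.0 * 4.0 / 2.0)

    def test_degenerate_conventions(self):
        assert integrate_trace(XICTrace(500.0, 10, ())) == 0.0
        assert integrate_trace(XICTrace(500.0, 10, ((3.0, 8.5),))) == 8.5


def _ref_ion(seq, z):
    return PeptideIon(seq, z, Variant.REFERENCE)


def _peak(sample, run, ion, intensity, site=""):
    return PeakMeasurement(
        sample_id=sample, run_condition=run, ion=ion, intensity=intensity,
        site_id=site,
    )


def _sample_rows(sample, ref_level, raw):
    native = PeptideIon("LFNVTSTLR", 2)
    r1 = _ref_ion("DQLSLGNAALQITDVK", 2)
    r2 = _ref_ion("AEVIWTSSDHQVLSGK", 3)
    return [
        _peak(sample, RunCondition.PNGASEF, r1, ref_level),
        _peak(sample, RunCondition.PNGASEF, r2, ref_level),
        _peak(sample, RunCondition.PNGASEF, native, raw, site="s1"),
    ]


class TestNormalization:
    def test_scale_factor_from_reference_means(self):
        rows = _sample_rows("base", 10.0, 7.0) + _sample_rows("s", 5.0, 3.0)
        norm = normalize_to_reference(rows)
        by_sample = {
            (m.sample_id, m.ion.variant): m.normalized_intensity
            for m in norm.measurements
        }
        assert by_sample[("base", Variant.NATIVE)] == pytest.approx(7.0)
        assert by_sample[("s", Variant.NATIVE)] == pytest.approx(6.0)  # factor 2

    def test_identical_references_leave_values_unchanged(self):
        rows = _sample_rows("a", 4.0, 1.5) + _sample_rows("b", 4.0, 2.5)
        norm = normalize_to_reference(rows)
        for m in norm.measurements:
            assert m.normalized_intensity == pytest.approx(m.intensity)

    def test_zero_reference_errors(self):
        rows = _sample_rows("a", 1.0, 1.0) + _sample_rows("b", 0.0, 1.0)
        with pytest.raises(ZeroReferenceError, match="'b'"):
            normalize_to_reference(rows)

    def test_missing_reference_errors(self):
        rows = _sample_rows("a", 1.0, 1.0)
        with pytest.raises(MissingReferenceError):
            normalize_to_reference(rows[1:])  # first reference peptide dropped


class TestOccupancyFormula:
    def test_full_occupancy_boundary(self):
        """IN = 0 with no spontaneous deamidation means exactly 100%."""
        res = compute_site_occupancy(IN=0.0, INF=1.0, IND=0.0)
        assert res.occupancy_percent == 100.0
        assert res.flags == frozenset()

    def test_vanishing_numerator(self):
        assert compute_site_occupancy(2.0, 0.3, 0.3).occupancy_percent == 0.0

    def test_generative_intensities_recover_half(self):
        res = compute_site_occupancy(0.45, 0.55, 0.05)
        assert res.occupancy_percent == pytest.approx(50.0, abs=1e-9)

    @pytest.mark.parametrize("theta", np.round(np.arange(0, 1.01, 0.1), 2))
    @pytest.mark.parametrize("d", [0.0, 0.05, 0.1, 0.2])
    @pytest.mark.parametrize("A", [1.0, 17.3])
    def test_noise_free_identity_over_grid(self, theta, d, A):
        """Model-generated intensities return 100·theta for any A and d."""
        IN = A * (1 - theta) * (1 - d)
        INF = A * (theta + (1 - theta) * d)
        IND = A * (1 - theta) * d
        res = compute_site_occupancy(IN, INF, IND)
        assert res.raw_percent == pytest.approx(100 * theta, abs=1e-9)

    def test_negative_raw_clamped_and_flagged(self):
        res = compute_site_occupancy(IN=1.0, INF=0.1, IND=0.5)
        assert res.raw_percent < 0
        assert res.occupancy_percent == 0.0
        assert "negative_raw" in res.flags

    def test_zero_denominator_flagged_unset(self):
        res = compute_site_occupancy(0.0, 0.0, 0.3)
        assert res.occupancy_percent is None
        assert res.flags == {"zero_denominator"}
        assert math.isnan(res.raw_percent)

    def test_low_signal_flag(self):
        res = compute_site_occupancy(1e-9, 1e-9, 0.0, low_signal_floor=1e-6)
        assert "low_signal" in res.flags

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_site_occupancy(-0.1, 1.0, 0.0)
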