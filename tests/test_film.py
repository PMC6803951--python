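"""Current-sheet film optics: algebra, energy bookkeeping, spectra analytics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoweld.constants import HC_EV_NM, Z0
from nanoweld.film import (FilmModel, absorption_from_arrays, bin_peaks,
                           find_absorption_maxima, max_absorption_real_sheet,
                           reflection_transmission, wavelengths_at_level)


def test_transparent_limit():
    R, T = reflection_transmission(np.zeros(3))
    assert np.allclose(R, 0.0) and np.allclose(T, 1.0)


def test_sigma_z0_equals_two():
    """σZ₀ = 2 (real): R = −1/2, T = 1/2, A = 1/2 — the absolute maximum."""
    R, T = reflection_transmission(np.array([2.0 / Z0]))
    assert R[0] == pytest.approx(-0.5)
    assert T[0] == pytest.approx(0.5)
    assert 1 - abs(R[0]) ** 2 - abs(T[0]) ** 2 == pytest.approx(0.5)


def test_lossless_sheet_absorbs_nothing():
    """Purely imaginary σ: |R|² + |T|² = 1 identically."""
    y = np.linspace(-30, 30, 301)
    R, T = reflection_transmission(1j * y / Z0)
    assert np.abs(np.abs(R) ** 2 + np.abs(T) ** 2 - 1).max() < 1e-12


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.complex_numbers(max_magnitude=50.0, allow_nan=False, allow_infinity=False)
       .filter(lambda s: s.real >= 0))
def test_energy_bookkeeping_identity(sigma_z0):
    """A + |R|² + |T|² = 1 to machine precision for any passive sheet."""
    spec = absorption_from_arrays(np.array([1.0]), np.array([sigma_z0 / Z0]))
    assert spec.A[0] + spec.R2[0] + spec.T2[0] == pytest.approx(1.0, abs=1e-14)
    assert -1e-14 <= spec.A[0] <= 1.0


def test_max_absorption_is_half_at_sigma_z0_two():
    A_max, x_opt = max_absorption_real_sheet()
    assert A_max == pytest.approx(0.5, abs=1e-9)
    assert x_opt == pytest.approx(2.0, abs=1e-4)


def test_absorption_monotone_in_real_sigma():
    """A = 4x/(2+x)² rises on [0, 2] and falls on [2, ∞)."""
    x = np.linspace(0.0, 2.0, 200)
    A = 4 * x / (2 + x) ** 2
    assert np.all(np.diff(A) > 0)
    x = np.linspace(2.0, 50.0, 200)
    A = 4 * x / (2 + x) ** 2
    assert np.all(np.diff(A) < 0)


def test_singular_sheet_rejected():
    with pytest.raises(ZeroDivisionError):
        reflection_transmission(np.array([-2.0 / Z0]))


# ------------------------------------------------------------------ analytics

def _toy_spectrum(centers, widths, amps, n=3000):
    omega = np.linspace(HC_EV_NM / 3000, HC_EV_NM / 150, n)
    lam = HC_EV_NM / omega
    A = sum(a / (1 + ((lam - c) / w) ** 2) for c, w, a in zip(centers, widths, amps))
    # realize A through a real conductivity (branch x < 2)
    x = ((4 - 4 * A) - np.sqrt((4 * A - 4) ** 2 - 16 * A ** 2)) / (2 * A)
    return absorption_from_arrays(omega, x / Z0)


def test_single_peak_found():
    spec = _toy_spectrum([700], [25], [0.3])
    peaks = find_absorption_maxima(spec, 0.01)
    assert len(peaks) == 1
    assert peaks[0][0] == pytest.approx(700, abs=2)


def test_well_separated_peaks_counted():
    spec = _toy_spectrum([300, 1000], [15, 30], [0.25, 0.2])
    assert len(find_absorption_maxima(spec, 0.01)) == 2


def test_bin_peaks_windows_and_boundary():
    peaks = [(300.0, 0.3), (700.0, 0.2), (1000.0, 0.2)]
    counts = bin_peaks(peaks)
    assert (counts["200-400"], counts["650-800"], counts["900-1150"],
            counts["1800-2400"], counts["outside"]) == (1, 1, 1, 0, 0)
    # a peak exactly at 400 nm falls in the window starting at 400 ([lo, hi))
    counts = bin_peaks([(400.0, 0.1)], ranges=[(200, 400), (400, 600)])
    assert counts["200-400"] == 0 and counts["400-600"] == 1
    assert bin_peaks([])["outside"] == 0


def test_overlapping_ranges_rejected():
    with pytest.raises(ValueError, match="overlap"):
        bin_peaks([], ranges=[(200, 500), (400, 600)])


def test_level_intervals():
    spec = _toy_spectrum([700], [40], [0.4])
    assert wavelengths_at_level(spec, 0.45) == []
    iv = wavelengths_at_level(spec, 0.2)
    assert len(iv) == 1
    lo, hi = iv[0]
    # Lorentzian half-height points at c ± w
    assert lo == pytest.approx(660, abs=3) and hi == pytest.approx(740, abs=3)
    # A ≡ 0 -> no intervals
    flat = absorption_from_arrays(np.linspace(1, 2, 50), np.zeros(50, complex))
    assert wavelengths_at_level(flat, 0.5) == []


def test_film_scell_geometries():
    side = FilmModel()
    end = FilmModel(geometry="end_illuminated_open_ends")
    d = 0.542   # (4,4) diameter
    assert side.scell((4, 4), period=0.246) == pytest.approx(0.246 * (d + 0.5), rel=1e-3)
    assert end.scell((4, 4)) == pytest.approx(np.sqrt(3) / 2 * (d + 0.5) ** 2, rel=1e-3)
    with pytest.raises(ValueError):
        side.scell((4, 4))          # needs the axial cell length


def test_thin_film_validity_warning():
    film = FilmModel(thickness=40.0)
    with pytest.warns(UserWarning, match="thickness"):
        film.check_validity(wavelength_min=100.0)
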