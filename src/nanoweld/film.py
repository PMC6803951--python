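"""Thin-film reflection, transmission and absorption from sheet conductivity.

A film whose thickness is much smaller than the wavelength acts as a
current sheet between two vacuum half-spaces.  At normal incidence the
complex amplitude coefficients are

    R = -σZ₀ / (2 + σZ₀),      T = 2 / (2 + σZ₀),

with Z₀ = 120π Ω the free-space impedance, and the absorbed fraction is

    A = 1 - |R|² - |T|².

For real σ, A = 4x/(2+x)² with x = σZ₀, maximized at x = 2 where A = 1/2:
a single current sheet can never absorb more than 50% of a normally
incident wave.  Purely imaginary (lossless) σ gives A = 0 identically.

The film geometry fixes the area per tube S_cell that normalizes the sheet
conductivity:

* side-illuminated parallel-tube film: S_cell = period × (d + gap),
  with the ~0.5 nm wall-to-wall gap of a close-packed parallel raft;
* end-illuminated open-end film (wave along the tube axes):
  S_cell = (√3/2)(d + gap)², the hexagonal-packing cross-section per tube.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .chirality import ChiralIndices, _as_chirality
from .constants import FILM_GAP, HC_EV_NM, Z0
from .kubo import ConductivitySpectrum

#: the four wavelength windows where absorption maxima of defected tubes
#: cluster (UV, visible, near-IR, far-IR), nm
DEFAULT_PEAK_RANGES: tuple[tuple[float, float], ...] = (
    (200.0, 400.0), (650.0, 800.0), (900.0, 1150.0), (1800.0, 2400.0),
)


@dataclass(frozen=True)
class FilmModel:
    """Geometry of the SWCNT thin film."""

    geometry: str = "side_illuminated_parallel_tubes"
    pitch_gap: float = FILM_GAP     # nm wall-to-wall spacing between tubes
    thickness: Optional[float] = None  # nm, for the thin-film validity check
    polarization: str = "axial"     # E relative to the tube axis

    _GEOMETRIES = ("side_illuminated_parallel_tubes", "end_illuminated_open_ends")

    def __post_init__(self):
        if self.geometry not in self._GEOMETRIES:
            raise ValueError(f"geometry must be one of {self._GEOMETRIES}")

    def scell(self, chirality, period: Optional[float] = None) -> float:
        """Area per tube in nm² for the conductivity normalization."""
        ch = _as_chirality(chirality)
        pitch = ch.diameter + self.pitch_gap
        if self.geometry == "side_illuminated_parallel_tubes":
            if period is None:
                raise ValueError("side-illuminated film needs the axial cell length")
            return period * pitch
        return (math.sqrt(3.0) / 2.0) * pitch * pitch

    def check_validity(self, wavelength_min: float) -> None:
        if self.thickness is not None and self.thickness >= wavelength_min / 10.0:
            warnings.warn(
                f"film thickness {self.thickness} nm is not << shortest "
                f"wavelength {wavelength_min} nm; the current-sheet formula "
                "degrades there"
            )


@dataclass
class AbsorptionSpectrum:
    """A, |R|², |T|² versus wavelength; A+|R|²+|T|²=1 by construction."""

    omega: np.ndarray                # eV
    R: np.ndarray                    # complex amplitude reflection
    T: np.ndarray                    # complex amplitude transmission
    polarization: str = "axial"
    provenance: dict = field(default_factory=dict)

    @property
    def wavelength(self) -> np.ndarray:
        return HC_EV_NM / self.omega

    @property
    def R2(self) -> np.ndarray:
        return np.abs(self.R) ** 2

    @property
    def T2(self) -> np.ndarray:
        return np.abs(self.T) ** 2

    @property
    def A(self) -> np.ndarray:
        return 1.0 - self.R2 - self.T2


def reflection_transmission(sigma: np.ndarray, z0: float = Z0):
    """Complex R, T of the current sheet, elementwise over the grid."""
    x = np.asarray(sigma) * z0
    denom = 2.0 + x
    if np.any(np.abs(denom) < 1e-15):
        raise ZeroDivisionError(
            "2 + σZ₀ vanished; nonphysical for a passive sheet (Re σ ≥ 0)"
        )
    return -x / denom, 2.0 / denom


def absorption(
    spec: ConductivitySpectrum,
    film: Optional[FilmModel] = None,
    provenance: Optional[dict] = None,
) -> AbsorptionSpectrum:
    """Absorption spectrum of the film with the given sheet conductivity."""
    film = film or FilmModel()
    R, T = reflection_transmission(spec.sigma)
    film.check_validity(float(np.min(HC_EV_NM / spec.omega)))
    pol = "axial" if spec.polarization == "z" else "perpendicular"
    return AbsorptionSpectrum(
        omega=spec.omega, R=R, T=T, polarization=pol,
        provenance=dict(provenance or {}, scell=spec.scell, **spec.meta),
    )


def absorption_from_arrays(omega: np.ndarray, sigma: np.ndarray) -> AbsorptionSpectrum:
    """Absorption directly from (Ω, σ) arrays (used for toy/closed-form inputs)."""
    R, T = reflection_transmission(sigma)
    return AbsorptionSpectrum(omega=np.asarray(omega), R=R, T=T)


def max_absorption_real_sheet(
    x_max: float = 1e3, n_scan: int = 2001
) -> tuple[float, float]:
    """Numerically maximize A over real σ ≥ 0; returns (A_max, σZ₀ at max).

    Scans σZ₀ log-uniformly then refines with golden-section search; the
    analytic optimum is A = 1/2 at σZ₀ = 2.
    """
    from scipy.optimize import minimize_scalar

    def A_of_x(x):
        R, T = reflection_transmission(np.array([x / Z0]))
        return 1.0 - abs(R[0]) ** 2 - abs(T[0]) ** 2

    xs = np.logspace(-3, math.log10(x_max), n_scan)
    As = np.array([A_of_x(x) for x in xs])
    i = int(np.argmax(As))
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
    res = minimize_scalar(lambda x: -A_of_x(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return -res.fun, float(res.x)


# ------------------------------------------------------------------ analytics

def find_absorption_maxima(
    spectrum: AbsorptionSpectrum, prominence: float = 0.01
) -> list[tuple[float, float]]:
    """Local maxima of A(λ) with at least the given absolute prominence.

    Returns (wavelength nm, A) pairs sorted by wavelength.
    """
    if not (0 < prominence < 1):
        raise ValueError("prominence must lie in (0, 1)")
    A = spectrum.A
    lam = spectrum.wavelength
    if len(A) < 3:
        raise ValueError("spectrum must have at least 3 points")
    order = np.argsort(lam)
    lam_s, A_s = lam[order], A[order]
    idx, _ = find_peaks(A_s, prominence=prominence)
    return sorted(((float(lam_s[i]), float(A_s[i])) for i in idx))


def bin_peaks(
    peaks: Sequence[tuple[float, float]],
    ranges: Sequence[tuple[float, float]] = DEFAULT_PEAK_RANGES,
) -> dict:
    """Count peaks per wavelength window [lo, hi) plus an 'outside' bucket."""
    rs = sorted((float(lo), float(hi)) for lo, hi in ranges)
    for (lo, hi) in rs:
        if hi <= lo:
            raise ValueError(f"empty range [{lo}, {hi})")
    for (_, hi1), (lo2, _) in zip(rs, rs[1:]):
        if lo2 < hi1:
            raise ValueError("overlapping wavelength ranges")
    counts = {f"{lo:g}-{hi:g}": 0 for lo, hi in rs}
    outside = 0
    for lam, _ in peaks:
        for lo, hi in rs:
            if lo <= lam < hi:       # boundary inclusive on the left
                counts[f"{lo:g}-{hi:g}"] += 1
                break
        else:
            outside += 1
    counts["outside"] = outside
    return counts


def wavelengths_at_level(
    spectrum: AbsorptionSpectrum, level: float = 0.5
) -> list[tuple[float, float]]:
    """Maximal wavelength intervals where A ≥ level (linear interpolation)."""
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    lam = spectrum.wavelength
    A = spectrum.A
    order = np.argsort(lam)
    lam, A = lam[order], A[order]
    above = A >= level
    intervals = []
    i = 0
    n = len(lam)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        lo = lam[i]
        if i > 0:
            lo = _interp_crossing(lam[i - 1], A[i - 1], lam[i], A[i], level)
        hi = lam[j]
        if j + 1 < n:
            hi = _interp_crossing(lam[j], A[j], lam[j + 1], A[j + 1], level)
        intervals.append((float(lo), float(hi)))
        i = j + 1
    return intervals


def _interp_crossing(l0, a0, l1, a1, level):
    if a1 == a0:
        return l1
    t = (level - a0) / (a1 - a0)
    return l0 + t * (l1 - l0)
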