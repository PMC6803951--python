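"""Orthogonal nearest-neighbour π-orbital tight binding for SWCNTs.

One π orbital per carbon, on-site energy ε₀ and hopping −γ₀ (default
2.7 eV) between atoms closer than the bond cutoff.  For a tube periodic
along z the Bloch Hamiltonian uses the atom gauge,

    H_ij(k) = -γ₀ Σ_images exp(i k Δz_ij),   Δz_ij = z_j + L·P - z_i,

so the analytic axial momentum (m_e/ħ)∂H/∂k agrees element-wise with the
commutator form (m_e/iħ)[z, H].  This model replaces a self-consistent
DFTB Hamiltonian by design: it reproduces the metal/semiconductor
dichotomy, van Hove structure and selection rules that control the optics
qualitatively, but absolute transition energies are parametrization
dependent.

Half filling (one π electron per atom) defines the chemical potential.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .constants import BOND_CUTOFF, GAMMA0, KB_EV
from .structure import AtomicStructure


@dataclass(frozen=True)
class TBModel:
    """π-band tight-binding parametrization."""

    onsite: float = 0.0          # ε₀, eV
    gamma0: float = GAMMA0       # nearest-neighbour hopping, eV (> 0)
    cutoff: float = BOND_CUTOFF  # nm, bond cutoff
    scaling_exponent: float = 0.0  # hopping ∝ (r0/r)^q for strained bonds

    def __post_init__(self):
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if not (0 < self.cutoff < 0.246):
            raise ValueError("cutoff must lie below the second-neighbour shell")

    def hopping(self, r: np.ndarray) -> np.ndarray:
        if self.scaling_exponent == 0.0:
            return np.full_like(np.asarray(r, dtype=float), self.gamma0)
        from .constants import A_CC
        return self.gamma0 * (A_CC / np.asarray(r)) ** self.scaling_exponent


@dataclass
class BandStructure:
    """Eigenvalues (and optionally eigenvectors) over a 1D k-grid.

    ``energies[ik]`` is sorted ascending; eigenvector columns match that
    order.  ``period`` is the axial cell length (None for finite
    structures, where the grid is Γ only).  ``scell`` (nm²) is the film
    area per tube attached later by the film model.
    """

    k: np.ndarray                      # (Nk,) 1/nm
    energies: np.ndarray               # (Nk, N) eV
    eigenvectors: Optional[np.ndarray]  # (Nk, N, N) or None
    period: Optional[float]
    model: TBModel
    structure: AtomicStructure = None
    scell: Optional[float] = None      # nm²

    @property
    def n_k(self) -> int:
        return len(self.k)

    @property
    def n_bands(self) -> int:
        return self.energies.shape[1]


# ------------------------------------------------------------------ H(k)

def _bond_data(structure: AtomicStructure, model: TBModel):
    dz = structure.positions[structure.bond_j, 2] - structure.positions[structure.bond_i, 2]
    if structure.period is not None:
        dz = dz + structure.bond_image * structure.period
    r = structure.bond_lengths()
    t = model.hopping(r)
    return dz, t


def hamiltonian_at_k(
    structure: AtomicStructure, model: TBModel, k: float = 0.0, sparse: bool = False
):
    """Bloch Hamiltonian at axial wavevector k (1/nm); Hermitian.

    Finite structures only admit k = 0.
    """
    if structure.period is None and k != 0.0:
        raise ValueError("finite structure: only k = 0 is meaningful")
    n = structure.n_atoms
    dz, t = _bond_data(structure, model)
    val = -t * np.exp(1j * k * dz)
    rows = np.concatenate([structure.bond_i, structure.bond_j, np.arange(n)])
    cols = np.concatenate([structure.bond_j, structure.bond_i, np.arange(n)])
    vals = np.concatenate([val, np.conj(val), np.full(n, model.onsite, dtype=complex)])
    H = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    H.sum_duplicates()
    return H if sparse else H.toarray()


def dhamiltonian_dk(structure: AtomicStructure, model: TBModel, k: float) -> np.ndarray:
    """Analytic ∂H/∂k (eV·nm) for a periodic structure (atom gauge)."""
    if structure.period is None:
        raise ValueError("∂H/∂k requires a periodic structure")
    n = structure.n_atoms
    dz, t = _bond_data(structure, model)
    val = -t * (1j * dz) * np.exp(1j * k * dz)
    M = np.zeros((n, n), dtype=complex)
    np.add.at(M, (structure.bond_i, structure.bond_j), val)
    np.add.at(M, (structure.bond_j, structure.bond_i), np.conj(val))
    return M


def k_grid(period: float, nk: int) -> np.ndarray:
    """Uniform grid over the 1D Brillouin zone [-π/P, π/P)."""
    if nk < 1:
        raise ValueError("Nk must be >= 1")
    return (np.arange(nk) / nk - 0.5) * (2.0 * math.pi / period)


def band_structure(
    structure: AtomicStructure,
    model: TBModel = TBModel(),
    nk: int = 1,
    store_eigenvectors: bool = True,
) -> BandStructure:
    """Diagonalize H(k) on a uniform BZ grid (Γ only for finite tubes)."""
    if structure.period is None:
        ks = np.array([0.0])
    else:
        ks = k_grid(structure.period, nk)
    n = structure.n_atoms
    energies = np.empty((len(ks), n))
    vecs = np.empty((len(ks), n, n), dtype=complex) if store_eigenvectors else None
    for ik, k in enumerate(ks):
        H = hamiltonian_at_k(structure, model, k)
        if store_eigenvectors:
            w, v = np.linalg.eigh(H)
            vecs[ik] = v
        else:
            w = np.linalg.eigvalsh(H)
        energies[ik] = w
    return BandStructure(
        k=ks, energies=energies, eigenvectors=vecs,
        period=structure.period, model=model, structure=structure,
    )


# ------------------------------------------------------------------ filling

def fermi_dirac(E: np.ndarray, mu: float, temperature: float) -> np.ndarray:
    """Occupation f(E) at temperature (K); the T→0 limit is a step."""
    if temperature <= 0:
        return (np.asarray(E) < mu).astype(float) + 0.5 * (np.asarray(E) == mu)
    beta = 1.0 / (KB_EV * temperature)
    return expit(-beta * (np.asarray(E) - mu))


def fermi_derivative(E: np.ndarray, mu: float, temperature: float) -> np.ndarray:
    """∂f/∂E in 1/eV (negative)."""
    beta = 1.0 / (KB_EV * temperature)
    f = fermi_dirac(E, mu, temperature)
    return -beta * f * (1.0 - f)


def chemical_potential(
    bands: BandStructure,
    temperature: float = 300.0,
    n_electrons: Optional[float] = None,
    tol: float = 1e-9,
) -> float:
    """μ solving Σ_{k,n} 2 f(E−μ) = N_electrons · Nk by bisection.

    Default filling is one π electron per carbon atom.  For the
    particle-hole-symmetric pristine lattice this lands exactly at ε₀.
    """
    E = bands.energies
    nk, nb = E.shape
    if n_electrons is None:
        n_electrons = nb  # half filling: N orbitals, 2N states, N electrons
    target = n_electrons * nk

    def occupation(mu):
        return 2.0 * fermi_dirac(E, mu, temperature).sum()

    lo, hi = E.min() - 5.0, E.max() + 5.0
    f_lo, f_hi = occupation(lo) - target, occupation(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError(
            f"chemical potential not bracketed: occ({lo:.2f})={f_lo + target:.3f}, "
            f"occ({hi:.2f})={f_hi + target:.3f}, target={target}"
        )
    return brentq(lambda mu: occupation(mu) - target, lo, hi, xtol=tol)


# ------------------------------------------------------------------ gaps

def direct_gap_at_k(structure, model, k, n_occ: Optional[int] = None) -> float:
    """HOMO–LUMO separation of H(k) at half filling."""
    n = structure.n_atoms
    if n_occ is None:
        n_occ = n // 2
    if n <= 600:
        w = np.linalg.eigvalsh(hamiltonian_at_k(structure, model, k))
        return float(w[n_occ] - w[n_occ - 1])
    # large cells: a handful of eigenvalues around ε₀ via shift-invert
    H = hamiltonian_at_k(structure, model, k, sparse=True)
    sigma = model.onsite + 1.2345e-4  # off any exact eigenvalue
    w = spla.eigsh(H, k=6, sigma=sigma, which="LM", return_eigenvectors=False)
    w = np.sort(w)
    below = w[w <= model.onsite]
    above = w[w > model.onsite]
    if len(below) == 0 or len(above) == 0:  # pragma: no cover
        w = spla.eigsh(H, k=20, sigma=sigma, which="LM", return_eigenvectors=False)
        w = np.sort(w)
        below, above = w[w <= model.onsite], w[w > model.onsite]
    return float(above.min() - below.max())


def minimal_gap(
    structure: AtomicStructure,
    model: TBModel = TBModel(),
    coarse_nk: int = 16,
    refine: bool = True,
) -> float:
    """Minimal direct band gap over the 1D BZ.

    A fixed k-grid overestimates the gap of metallic tubes whose Dirac
    point falls between grid points, so the minimum is refined by bounded
    scalar minimization around the best coarse sample.
    """
    if structure.period is None:
        return direct_gap_at_k(structure, model, 0.0)
    kmax = math.pi / structure.period
    ks = np.linspace(0.0, kmax, coarse_nk)   # time reversal: k ≥ 0 suffices
    gaps = np.array([direct_gap_at_k(structure, model, k) for k in ks])
    best = float(gaps.min())
    if not refine:
        return best
    i = int(np.argmin(gaps))
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, len(ks) - 1)]
    if lo == hi:
        return best
    res = minimize_scalar(
        lambda k: direct_gap_at_k(structure, model, k),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * kmax},
    )
    return float(min(best, res.fun))


# ------------------------------------------------------------------ export

def export_bands_csv(bands: BandStructure, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k_invnm"] + [f"E{n}_eV" for n in range(bands.n_bands)])
        for ik in range(bands.n_k):
            w.writerow([f"{bands.k[ik]:.8g}"] + [f"{e:.8g}" for e in bands.energies[ik]])


def export_bands_hdf5(bands: BandStructure, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("k", data=bands.k)
        f.create_dataset("energies", data=bands.energies)
        if bands.eigenvectors is not None:
            f.create_dataset("eigenvectors", data=bands.eigenvectors)
        f.attrs["period"] = bands.period if bands.period is not None else np.nan
        f.attrs["gamma0"] = bands.model.gamma0
        f.attrs["onsite"] = bands.model.onsite
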