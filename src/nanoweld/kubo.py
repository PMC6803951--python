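"""Kubo–Greenwood complex optical conductivity from a band structure.

The sheet conductivity tensor versus photon energy Ω is

    σ_αβ(Ω) = 2e²ħ / (i m_e² S_cell) · (1/Nk) Σ_k Σ_{n,m}
              P^α_nm P^β_mn / (E_n − E_m + Ω + iη)
              · (f[E_n − μ] − f[E_m − μ]) / (E_n − E_m),

with the momentum operator from the Hamiltonian gradient,
P(k) = (m_e/ħ) ∇_k H(k).  The factor 2 is spin degeneracy; η is a
phenomenological broadening.  The intraband 0/0 ratio is replaced by its
analytic limit ∂f/∂E, which produces the Drude-like response of metallic
tubes and keeps Re σ ≥ 0 (passivity).

Directions: 'z' (axial) uses the analytic Bloch gradient for periodic
tubes; 'x'/'y' (perpendicular) — and every direction of a finite tube —
use the commutator form P = (m_e/iħ)[r, H].  The two constructions agree
element-wise for the axial direction of a periodic tube (atom gauge).

Since P carries the (m_e/ħ) prefactor, the full expression reduces to
2e²/(iħ S_cell) · Σ |∇_k H|²-type sums, which is what the kernel
evaluates, in SI units; the output is in siemens (a 2D sheet value, so
σ·Z₀ is dimensionless).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import E_CHARGE, EV_J, HBAR_SI, HC_EV_NM, M_ELECTRON, NM_M
from .structure import AtomicStructure
from .tb import (BandStructure, TBModel, chemical_potential, dhamiltonian_dk,
                 fermi_derivative, fermi_dirac, hamiltonian_at_k)

_DEGENERACY_TOL = 1e-9  # eV; |E_n - E_m| below this uses the intraband limit


@dataclass(frozen=True)
class KuboConfig:
    """Evaluation parameters for the conductivity kernel."""

    omega: np.ndarray = field(
        default_factory=lambda: np.linspace(0.05, 6.0, 600)
    )                            # photon energies Ω, eV (strictly increasing, > 0)
    eta: float = 0.05            # broadening η, eV
    temperature: float = 300.0   # electronic temperature, K
    polarization: str = "z"      # α (= β) direction: 'x', 'y' or 'z'

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        if om.ndim != 1 or len(om) < 1:
            raise ValueError("omega must be a 1D grid")
        if np.any(om <= 0) or np.any(np.diff(om) <= 0):
            raise ValueError("omega grid must be strictly increasing and positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive (the Ω=ΔE resonance diverges otherwise)")
        if self.polarization not in ("x", "y", "z"):
            raise ValueError("polarization must be 'x', 'y' or 'z'")
        object.__setattr__(self, "omega", om)


@dataclass
class ConductivitySpectrum:
    """Complex sheet conductivity per photon energy, in siemens."""

    omega: np.ndarray            # eV
    sigma: np.ndarray            # complex, S
    polarization: str
    scell: float                 # nm², area per tube used for normalization
    meta: dict = field(default_factory=dict)

    @property
    def wavelength(self) -> np.ndarray:
        """Vacuum wavelength grid in nm."""
        return HC_EV_NM / self.omega


# ------------------------------------------------------------------ momentum

def momentum_matrix(
    structure: AtomicStructure,
    model: TBModel,
    k: float,
    direction: str,
    eigenvectors: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Momentum operator in the eigenbasis at k, SI units (kg·m/s).

    ``direction`` in {'x','y','z'}.  Axial ('z') momentum of a periodic
    structure uses (m_e/ħ)∂H/∂k; perpendicular directions and finite
    structures use the commutator form.  Pass the eigenvector matrix to
    rotate into the eigenbasis (columns = eigenstates); otherwise the
    atom-basis matrix is returned.
    """
    if direction not in ("x", "y", "z"):
        raise ValueError(f"direction must be 'x', 'y' or 'z', got {direction!r}")
    if direction == "z" and structure.period is not None:
        M = dhamiltonian_dk(structure, model, k)       # eV·nm
    else:
        M = _commutator_gradient(structure, model, k, direction)
    if eigenvectors is not None:
        M = eigenvectors.conj().T @ M @ eigenvectors
    return M * (M_ELECTRON / HBAR_SI) * EV_J * NM_M     # -> kg·m/s


def _commutator_gradient(
    structure: AtomicStructure, model: TBModel, k: float, direction: str
) -> np.ndarray:
    """(ħ/m_e)·P from P = (m_e/iħ)[r, H], returned in eV·nm.

    Equals i(r_j − r_i)_d H_ij including periodic images, i.e. the same
    quantity as ∂H/∂k for the axial direction (atom gauge).
    """
    axis = "xyz".index(direction)
    n = structure.n_atoms
    dr = structure.positions[structure.bond_j] - structure.positions[structure.bond_i]
    if structure.period is not None:
        dr = dr + np.outer(structure.bond_image, [0.0, 0.0, structure.period])
    dz = dr[:, 2]
    r = np.linalg.norm(dr, axis=1)
    t = model.hopping(r)
    val = -t * np.exp(1j * k * dz) * (1j * dr[:, axis])
    M = np.zeros((n, n), dtype=complex)
    np.add.at(M, (structure.bond_i, structure.bond_j), val)
    np.add.at(M, (structure.bond_j, structure.bond_i), np.conj(val))
    return M


# ------------------------------------------------------------------ kernel

def kubo_conductivity(
    bands: BandStructure,
    config: KuboConfig = KuboConfig(),
    scell: Optional[float] = None,
    mu: Optional[float] = None,
) -> ConductivitySpectrum:
    """Evaluate the conductivity formula over the photon-energy grid.

    ``scell`` (nm², area per tube) must be set here or on the band
    structure.  μ defaults to the half-filling chemical potential at the
    configured temperature.
    """
    if bands.eigenvectors is None:
        raise ValueError("band structure must carry eigenvectors")
    scell = scell if scell is not None else bands.scell
    if scell is None or scell <= 0:
        raise ValueError("positive Scell (nm² per tube) required")
    if mu is None:
        mu = chemical_potential(bands, config.temperature)

    st, model = bands.structure, bands.model
    om = config.omega
    sigma = np.zeros(len(om), dtype=complex)
    for ik, k in enumerate(bands.k):
        E = bands.energies[ik]
        V = bands.eigenvectors[ik]
        P = momentum_matrix(st, model, k, config.polarization, V)
        sigma += _k_term(E, P, mu, config)
    # prefactor: 2 e² ħ / (i m_e² S Nk); the (m_e/ħ)² inside |P|² is explicit
    pref = 2.0 * E_CHARGE**2 * HBAR_SI / (1j * M_ELECTRON**2 * (scell * NM_M**2) * bands.n_k)
    return ConductivitySpectrum(
        omega=om, sigma=pref * sigma, polarization=config.polarization,
        scell=scell,
        meta={"eta": config.eta, "temperature": config.temperature,
              "mu": mu, "nk": bands.n_k},
    )


def _k_term(E: np.ndarray, P: np.ndarray, mu: float, config: KuboConfig) -> np.ndarray:
    """Σ_{n,m} |P_nm|²·F_nm/(D_nm+Ω+iη) for one k, SI inner units."""
    f = fermi_dirac(E, mu, config.temperature)
    D = E[:, None] - E[None, :]                     # eV
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (f[:, None] - f[None, :]) / D           # 1/eV
    degenerate = np.abs(D) < _DEGENERACY_TOL
    Ebar = 0.5 * (E[:, None] + E[None, :])
    F = np.where(degenerate, fermi_derivative(Ebar, mu, config.temperature), F)
    W = (np.abs(P) ** 2) * (F / EV_J)               # SI: P² / J
    w = W.ravel()
    d = (D * EV_J).ravel()
    keep = w != 0.0
    w, d = w[keep], d[keep]
    om_J = config.omega * EV_J
    eta_J = config.eta * EV_J
    # Σ_pairs w / (d + Ω + iη), vectorized over Ω in chunks
    out = np.empty(len(om_J), dtype=complex)
    chunk = max(1, int(4e6 // max(len(w), 1)))
    for s in range(0, len(om_J), chunk):
        block = om_J[s:s + chunk]
        denom = d[None, :] + block[:, None] + 1j * eta_J
        out[s:s + chunk] = (w[None, :] / denom).sum(axis=1)
    return out


# ------------------------------------------------------------------ export

def export_sigma_csv(spec: ConductivitySpectrum, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["omega_eV", "lambda_nm", "re_sigma_S", "im_sigma_S", "pol"])
        lam = spec.wavelength
        for i in range(len(spec.omega)):
            w.writerow([f"{spec.omega[i]:.8g}", f"{lam[i]:.8g}",
                        f"{spec.sigma[i].real:.8g}", f"{spec.sigma[i].imag:.8g}",
                        spec.polarization])


def export_sigma_hdf5(spec: ConductivitySpectrum, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("omega", data=spec.omega)
        f.create_dataset("sigma", data=spec.sigma)
        f.attrs["polarization"] = spec.polarization
        f.attrs["scell_nm2"] = spec.scell
        for key, val in spec.meta.items():
            f.attrs[key] = val
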