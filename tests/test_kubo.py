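"""Optical conductivity kernel: closed forms, brute-force oracle, sum rules."""

import numpy as np
import pytest

from nanoweld.constants import EV_J, HBAR_SI, M_ELECTRON, NM_M, E_CHARGE
from nanoweld.kubo import (KuboConfig, kubo_conductivity, momentum_matrix,
                           _commutator_gradient)
from nanoweld.structure import build_finite_tube, build_periodic_tube
from nanoweld.tb import TBModel, band_structure, chemical_potential, dhamiltonian_dk

from oracles import brute_force_kubo

MODEL = TBModel()


def test_axial_gradient_equals_commutator(tube130):
    """(m/ħ)∂H/∂k and (m/iħ)[z,H] agree element-wise (atom gauge)."""
    for k in (0.0, 0.8, -2.1):
        A = dhamiltonian_dk(tube130, MODEL, k)
        B = _commutator_gradient(tube130, MODEL, k, "z")
        assert np.abs(A - B).max() < 1e-13


def test_momentum_hermitian(tube44):
    b = band_structure(tube44, MODEL, nk=4)
    for d in ("x", "y", "z"):
        P = momentum_matrix(tube44, MODEL, b.k[1], d, b.eigenvectors[1])
        assert np.abs(P - P.conj().T).max() < 1e-30   # SI scale ~1e-24


def test_dimer_momentum_closed_form(dimer):
    """|P12| of the 2-atom fixture equals m_e·a_cc·γ0/ħ·(1/2)·(…): the
    commutator form gives |P12| = (m_e/ħ)·γ0·d12 with d12 = 0.142 nm."""
    w, V = np.linalg.eigh(np.array([[0, -2.7], [-2.7, 0.0]]))
    P = momentum_matrix(dimer, MODEL, 0.0, "z", V)
    expected = (M_ELECTRON / HBAR_SI) * 2.7 * EV_J * 0.142 * NM_M
    assert abs(P[0, 1]) == pytest.approx(expected, rel=1e-12)
    assert abs(P[0, 0]) < 1e-40   # diagonal vanishes for a finite system


def test_direction_validation(tube44):
    with pytest.raises(ValueError):
        momentum_matrix(tube44, MODEL, 0.0, "q")


# ------------------------------------------------------------------ kernel

def _sigma_inputs(structure, nk, pol="z"):
    b = band_structure(structure, MODEL, nk=nk)
    mu = chemical_potential(b, 300.0)
    P = [momentum_matrix(structure, MODEL, b.k[ik], pol, b.eigenvectors[ik])
         for ik in range(b.n_k)]
    return b, mu, P


def test_kernel_matches_brute_force_pair_sum(tube44):
    """Production kernel ≡ independent pure-python pair sum to 1e-10
    relative, on the 16-atom fixture."""
    omega = np.linspace(0.2, 8.0, 25)
    cfg = KuboConfig(omega=omega, eta=0.05, temperature=300.0, polarization="z")
    b, mu, P = _sigma_inputs(tube44, nk=4)
    spec = kubo_conductivity(b, cfg, scell=1.0, mu=mu)
    ref = brute_force_kubo([b.energies[i] for i in range(4)], P, mu,
                           omega, 0.05, 300.0, 1.0, 4)
    scale = np.abs(ref).max()
    assert np.abs(spec.sigma - ref).max() / scale < 1e-10


def test_two_level_lorentzian():
    """A single occupied→empty transition gives a Lorentzian of width η
    centred at Ω = ΔE, with the closed-form peak height of the pair sum."""
    from nanoweld.structure import AtomicStructure

    st = AtomicStructure(positions=np.array([[0, 0, 0], [0, 0, 0.142]]),
                         elements=["C", "C"])
    st.rebuild_bonds()
    delta = 2 * 2.7                      # E2 - E1
    eta = 0.05
    omega = np.linspace(0.5, 9.0, 851)
    cfg = KuboConfig(omega=omega, eta=eta, temperature=50.0, polarization="z")
    b = band_structure(st, MODEL, nk=1)
    spec = kubo_conductivity(b, cfg, scell=1.0, mu=0.0)
    re = spec.sigma.real
    peak_idx = int(np.argmax(re))
    assert omega[peak_idx] == pytest.approx(delta, abs=0.02)
    # closed form at resonance: both (1,2) and (2,1) pairs contribute
    p12 = (M_ELECTRON / HBAR_SI) * 2.7 * EV_J * 0.142 * NM_M
    occ = 1.0 / (delta * EV_J)           # (f1-f2)/(E1-E2) at T→0
    s_cell = 1.0 * NM_M**2
    pref = 2 * E_CHARGE**2 * HBAR_SI / (M_ELECTRON**2 * s_cell)
    # Im part of 1/(iη) -> 1/η; the antiresonant pair adds η/(4Δ²+η²)
    expected = pref * p12**2 * occ * (1.0 / (eta * EV_J)
                                      + (eta * EV_J) / ((2 * delta * EV_J)**2 + (eta * EV_J)**2))
    assert re[peak_idx] == pytest.approx(expected, rel=1e-3)
    # half width at half maximum ≈ η
    half = re >= expected / 2
    width = omega[half][-1] - omega[half][0]
    assert width == pytest.approx(2 * eta, rel=0.1)


def test_empty_band_gives_zero_sigma(tube44):
    b, _, _ = _sigma_inputs(tube44, nk=2)
    cfg = KuboConfig(omega=np.linspace(0.5, 5, 20), eta=0.05)
    spec = kubo_conductivity(b, cfg, scell=1.0, mu=-100.0)
    assert np.abs(spec.sigma).max() < 1e-30


def test_passivity_and_high_frequency_decay(tube130):
    b, mu, _ = _sigma_inputs(tube130, nk=8)
    omega = np.linspace(0.1, 20.0, 300)
    cfg = KuboConfig(omega=omega, eta=0.05)
    spec = kubo_conductivity(b, cfg, scell=1.0, mu=mu)
    re = spec.sigma.real
    assert re.min() > -1e-6 * re.max()          # Re σ ≥ 0
    # σ → 0 beyond the bandwidth faster than 1/Ω
    tail = omega > 3 * 2.7 * 2 + 5 * 0.05
    assert np.all(np.abs(spec.sigma[tail]) * omega[tail]
                  < np.abs(spec.sigma).max())


def test_degenerate_subspace_unitary_invariance(tube44):
    """Remixing eigenvectors inside degenerate subspaces leaves σ unchanged:
    conductivity only sees Σ|P|² over the subspace."""
    rng = np.random.default_rng(5)
    b = band_structure(tube44, MODEL, nk=3)
    mu = chemical_potential(b, 300.0)
    cfg = KuboConfig(omega=np.linspace(0.3, 7, 40), eta=0.05)
    base = kubo_conductivity(b, cfg, scell=1.0, mu=mu).sigma
    # randomly remix each degenerate block at every k
    for ik in range(b.n_k):
        E = b.energies[ik]
        start = 0
        while start < len(E):
            stop = start
            while stop + 1 < len(E) and E[stop + 1] - E[start] < 1e-9:
                stop += 1
            if stop > start:
                dim = stop - start + 1
                X = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
                Q, _ = np.linalg.qr(X)
                b.eigenvectors[ik][:, start:stop + 1] = \
                    b.eigenvectors[ik][:, start:stop + 1] @ Q
            start = stop + 1
    remixed = kubo_conductivity(b, cfg, scell=1.0, mu=mu).sigma
    assert np.abs(remixed - base).max() < 1e-10 * np.abs(base).max()


def test_supercell_doubling_leaves_sheet_sigma_invariant():
    """Two periods at Nk/2 sample the same states as one period at Nk;
    σ per area must agree to ~machine precision."""
    st1 = build_periodic_tube((4, 4), 1)
    st2 = build_periodic_tube((4, 4), 2)
    cfg = KuboConfig(omega=np.linspace(0.3, 7, 50), eta=0.05)
    b1 = band_structure(st1, MODEL, nk=16)
    b2 = band_structure(st2, MODEL, nk=8)
    s1 = kubo_conductivity(b1, cfg, scell=st1.period * 1.0)
    s2 = kubo_conductivity(b2, cfg, scell=st2.period * 1.0)
    assert np.abs(s1.sigma - s2.sigma).max() < 1e-6 * np.abs(s1.sigma).max()


def test_semiconductor_transparent_below_gap(tube130):
    """At 50 K the (13,0) tube shows no absorption deep in its gap; the
    residual at gap−4η is the Lorentzian tail of the band edge (~1/16)."""
    from nanoweld.tb import minimal_gap

    gap = minimal_gap(tube130)
    eta = 0.05
    omega = np.linspace(0.05, 3.0, 400)
    cfg = KuboConfig(omega=omega, eta=eta, temperature=50.0)
    b = band_structure(tube130, MODEL, nk=32)
    spec = kubo_conductivity(b, cfg, scell=1.0)
    re = spec.sigma.real
    peak = re.max()
    assert re[omega < gap - 4 * eta].max() < 0.1 * peak
    assert re[omega < 0.3].max() < 0.05 * peak


def test_config_validation():
    with pytest.raises(ValueError):
        KuboConfig(eta=0.0)
    with pytest.raises(ValueError):
        KuboConfig(omega=np.array([1.0, 0.5]))
    with pytest.raises(ValueError):
        KuboConfig(polarization="axial-ish")
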