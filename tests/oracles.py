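"""Independent oracles used by the test suite.

Everything here is deliberately written against the analytic theory (folded
graphene dispersion, direct pair sums) rather than against the package's
production code paths, so agreement is a real cross-check.
"""

from __future__ import annotations

import math

import numpy as np

A = 0.246          # nm graphene lattice constant
KB = 8.617333262e-5


def graphene_vectors():
    a1 = np.array([math.sqrt(3) / 2, 0.5]) * A
    a2 = np.array([math.sqrt(3) / 2, -0.5]) * A
    delta1 = (a1 + a2) / 3.0
    deltas = np.stack([delta1, delta1 - a1, delta1 - a2])
    return a1, a2, deltas


def folded_bands(n, m, k, gamma0=2.7, onsite=0.0):
    """All tube eigenvalues at axial wavevector k from zone folding.

    E_{μ,±}(k) = ε₀ ± γ₀|Σ_δ e^{i k_2D·δ}| on the allowed lines
    k_2D = μ·(2π/|Ch|)·ĉ + k·t̂ of the graphene BZ.
    """
    a1, a2, deltas = graphene_vectors()
    d_R = math.gcd(2 * n + m, 2 * m + n)
    Ch = n * a1 + m * a2
    T = ((2 * m + n) // d_R) * a1 - ((2 * n + m) // d_R) * a2
    c_hat = Ch / np.linalg.norm(Ch)
    t_hat = T / np.linalg.norm(T)
    n_hex = 2 * (n * n + m * m + n * m) // d_R
    mus = np.arange(n_hex)
    kc = mus * 2.0 * math.pi / np.linalg.norm(Ch)
    k2d = kc[:, None] * c_hat[None, :] + k * t_hat[None, :]      # (n_hex, 2)
    g = np.exp(1j * (k2d @ deltas.T)).sum(axis=1)                # Σ_δ e^{ik·δ}
    mag = gamma0 * np.abs(g)
    return np.sort(np.concatenate([onsite - mag, onsite + mag]))


def folded_eigenpairs(n, m, k, surface_coords, sublattice, gamma0=2.7, onsite=0.0):
    """Analytic Bloch eigenpairs of the tube Hamiltonian (atom gauge).

    Returns (energies (2*n_hex,), eigenvector matrix (N, 2*n_hex)) with
    ψ_j = e^{i k_c c_j} w_{s_j}: the circumferential phase stays in the
    vector, the axial phase is carried by H(k) itself.
    """
    a1, a2, deltas = graphene_vectors()
    d_R = math.gcd(2 * n + m, 2 * m + n)
    Ch = n * a1 + m * a2
    T = ((2 * m + n) // d_R) * a1 - ((2 * n + m) // d_R) * a2
    c_hat = Ch / np.linalg.norm(Ch)
    t_hat = T / np.linalg.norm(T)
    n_hex = 2 * (n * n + m * m + n * m) // d_R
    L_c = np.linalg.norm(Ch)
    mus = np.arange(n_hex)
    kc = mus * 2.0 * math.pi / L_c
    k2d = kc[:, None] * c_hat[None, :] + k * t_hat[None, :]
    g = -gamma0 * np.exp(1j * (k2d @ deltas.T)).sum(axis=1)      # (n_hex,)
    mag = np.abs(g)
    # sublattice amplitudes for E = ε₀ ± |g|: w = (1, ±g*/|g|)/√2;
    # at |g| = 0 the 2x2 block vanishes and any w is an eigenvector
    phase = np.where(mag > 1e-12, np.conj(g) / np.where(mag > 1e-12, mag, 1.0), 1.0)
    bloch = np.exp(1j * np.outer(surface_coords, kc))            # (N, n_hex)
    isA = (sublattice == 0)[:, None]
    energies = np.concatenate([onsite - mag, onsite + mag])
    minus = bloch * np.where(isA, 1.0, -phase[None, :]) / math.sqrt(2)
    plus = bloch * np.where(isA, 1.0, +phase[None, :]) / math.sqrt(2)
    return energies, np.concatenate([minus, plus], axis=1)


def brute_force_kubo(energies, P, mu, omega, eta, temperature, scell_nm2, nk):
    """Direct pair-sum evaluation of the conductivity formula.

    ``energies``: list over k of (N,) eV arrays; ``P``: list over k of
    (N, N) SI momentum matrices.  Pure python loops; SI output in siemens.
    """
    e = 1.602176634e-19
    hbar = 1.054571817e-34
    me = 9.1093837015e-31
    ev = e
    S = scell_nm2 * 1e-18
    total = np.zeros(len(omega), dtype=complex)
    beta = 1.0 / (KB * temperature)

    def f(E):
        x = beta * (E - mu)
        if x > 500:
            return 0.0
        if x < -500:
            return 1.0
        return 1.0 / (1.0 + math.exp(x))

    def fprime(E):
        ff = f(E)
        return -beta * ff * (1.0 - ff)

    for E, Pk in zip(energies, P):
        N = len(E)
        for n_ in range(N):
            for m_ in range(N):
                d = E[n_] - E[m_]
                if abs(d) < 1e-9:
                    occ = fprime(0.5 * (E[n_] + E[m_])) / ev
                else:
                    occ = (f(E[n_]) - f(E[m_])) / (d * ev)
                w = abs(Pk[n_, m_]) ** 2 * occ
                if w == 0.0:
                    continue
                for io, om in enumerate(omega):
                    total[io] += w / ((d + om + 1j * eta) * ev)
    pref = 2.0 * e * e * hbar / (1j * me * me * S * nk)
    return pref * total
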