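"""Atomistic SWCNT models: rolled-graphene geometry and bond topology.

The builder places carbon atoms on the ideal cylinder obtained by rolling a
graphene sheet along the chiral vector; no geometry optimization is applied
by default (see `relax_bonds` for the optional harmonic pass).  The bond
graph is recomputed from a global distance cutoff whenever the geometry
changes, which keeps defect handling simple and testable.

Conventions: lengths in nm, tube axis along +z, 0-based atom indexing.
Periodic tubes carry a scalar axial period; bonds that cross the periodic
boundary store an integer image offset (the neighbour sits at
``r_j + image * period * ez``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .chirality import ChiralIndices, _as_chirality
from .constants import A_LATTICE, A_CC, BOND_CUTOFF


@dataclass
class AtomicStructure:
    """Coordinates + bond graph + cell + defect bookkeeping.

    ``surface_coords`` (arc-length coordinate along the circumference) and
    ``sublattice`` (0=A, 1=B) are retained from the rolled-graphene
    construction while the topology is pristine; they become ``None`` after
    topology-changing edits.
    """

    positions: np.ndarray                 # (N, 3) nm
    elements: list[str]
    bond_i: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    bond_j: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    bond_image: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    period: Optional[float] = None        # axial (z) period, nm; None = finite
    box: Optional[np.ndarray] = None      # (3,) nm, for network exports
    defect_sites: list[dict] = field(default_factory=list)
    open_end_atoms: list[int] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    surface_coords: Optional[np.ndarray] = None   # (N,) arc coordinate, nm
    sublattice: Optional[np.ndarray] = None       # (N,) 0/1

    # ------------------------------------------------------------------ util
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_i)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=int)
        np.add.at(deg, self.bond_i, 1)
        np.add.at(deg, self.bond_j, 1)
        return deg

    def neighbor_lists(self) -> list[list[tuple[int, int]]]:
        """Per-atom list of (neighbour index, image offset)."""
        nbrs: list[list[tuple[int, int]]] = [[] for _ in range(self.n_atoms)]
        for i, j, im in zip(self.bond_i, self.bond_j, self.bond_image):
            nbrs[i].append((int(j), int(im)))
            nbrs[j].append((int(i), -int(im)))
        return nbrs

    def bond_lengths(self) -> np.ndarray:
        delta = self.positions[self.bond_j] - self.positions[self.bond_i]
        if self.period is not None:
            delta = delta + np.outer(self.bond_image, [0.0, 0.0, self.period])
        return np.linalg.norm(delta, axis=1)

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            positions=self.positions.copy(),
            elements=list(self.elements),
            bond_i=self.bond_i.copy(),
            bond_j=self.bond_j.copy(),
            bond_image=self.bond_image.copy(),
            period=self.period,
            box=None if self.box is None else np.asarray(self.box).copy(),
            defect_sites=[dict(d, atoms=list(d.get("atoms", []))) for d in self.defect_sites],
            open_end_atoms=list(self.open_end_atoms),
            provenance=dict(self.provenance),
            surface_coords=None if self.surface_coords is None else self.surface_coords.copy(),
            sublattice=None if self.sublattice is None else self.sublattice.copy(),
        )

    def rebuild_bonds(self, cutoff: float = BOND_CUTOFF) -> None:
        bi, bj, im = compute_bonds(self.positions, self.period, cutoff)
        self.bond_i, self.bond_j, self.bond_image = bi, bj, im


def compute_bonds(
    positions: np.ndarray, period: Optional[float], cutoff: float = BOND_CUTOFF
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance-cutoff bond detection, with axial periodic images if needed.

    Returns each bond once: (i, j, image) with i < j for image 0, and all
    (i, j) pairs for image +1 (neighbour at r_j + period*ez).
    """
    n = len(positions)
    if n == 0:
        return (np.zeros(0, int),) * 3
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    bi = [pairs[:, 0]] if len(pairs) else []
    bj = [pairs[:, 1]] if len(pairs) else []
    im = [np.zeros(len(pairs), dtype=int)] if len(pairs) else []
    if period is not None:
        shifted = positions + np.array([0.0, 0.0, period])
        stree = cKDTree(shifted)
        hits = tree.query_ball_tree(stree, cutoff)
        ii = [i for i, js in enumerate(hits) for _ in js]
        jj = [j for js in hits for j in js]
        if ii:
            bi.append(np.asarray(ii, int))
            bj.append(np.asarray(jj, int))
            im.append(np.ones(len(ii), dtype=int))
    if not bi:
        return (np.zeros(0, int),) * 3
    return np.concatenate(bi), np.concatenate(bj), np.concatenate(im)


# --------------------------------------------------------------------------
# rolled-graphene construction
# --------------------------------------------------------------------------

def _unrolled_cell(ch: ChiralIndices) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Atoms of one translational cell in unrolled sheet coordinates.

    Returns (arc coordinate c in [0, |Ch|), axial coordinate z in [0, T),
    sublattice 0/1), sorted deterministically.
    """
    n, m = ch.n, ch.m
    a = A_LATTICE
    a1 = np.array([math.sqrt(3) / 2, 0.5]) * a
    a2 = np.array([math.sqrt(3) / 2, -0.5]) * a
    delta = (a1 + a2) / 3.0  # B-atom basis offset
    Ch = n * a1 + m * a2
    t1 = (2 * m + n) // ch.d_R
    t2 = -(2 * n + m) // ch.d_R
    T = t1 * a1 + t2 * a2
    L_c = float(np.linalg.norm(Ch))
    L_t = float(np.linalg.norm(T))
    # index ranges covering the (Ch, T) parallelogram
    corners = np.array([[0, 0], [n, m], [t1, t2], [n + t1, m + t2]])
    i_lo, j_lo = corners.min(axis=0) - 2
    i_hi, j_hi = corners.max(axis=0) + 2
    ii, jj = np.meshgrid(
        np.arange(i_lo, i_hi + 1), np.arange(j_lo, j_hi + 1), indexing="ij"
    )
    cells = np.stack([ii.ravel(), jj.ravel()], axis=1)
    base = cells @ np.stack([a1, a2])        # (M, 2)
    pts = np.concatenate([base, base + delta])
    subl = np.concatenate(
        [np.zeros(len(base), dtype=int), np.ones(len(base), dtype=int)]
    )
    u = pts @ Ch / (L_c * L_c)
    v = pts @ T / (L_t * L_t)
    eps = 1e-9
    u = u - np.floor(u + eps)
    v = v - np.floor(v + eps)
    # dedupe atoms that map to the same point of the cell
    key = np.round(np.stack([u * L_c, v * L_t], axis=1) / 1e-4).astype(np.int64)
    _, keep = np.unique(key, axis=0, return_index=True)
    u, v, subl = u[keep], v[keep], subl[keep]
    if len(u) != ch.atoms_per_cell:  # pragma: no cover - construction guard
        raise RuntimeError(
            f"cell construction for {ch} produced {len(u)} atoms, "
            f"expected {ch.atoms_per_cell}"
        )
    c, z = u * L_c, v * L_t
    order = np.lexsort((np.round(c / 1e-6), np.round(z / 1e-6)))
    return c[order], z[order], subl[order]


def build_periodic_tube(
    chirality, n_periods: int = 1, cutoff: float = BOND_CUTOFF
) -> AtomicStructure:
    """Pristine SWCNT supercell, periodic along z.

    Atom count is ``n_periods * 4(n^2+m^2+nm)/d_R``; the bond graph is
    3-regular under periodic wrapping.
    """
    ch = _as_chirality(chirality)
    if int(n_periods) < 1:
        raise ValueError(f"n_periods must be >= 1, got {n_periods}")
    n_periods = int(n_periods)
    c1, z1, s1 = _unrolled_cell(ch)
    T = ch.translation_period
    c = np.tile(c1, n_periods)
    z = np.concatenate([z1 + p * T for p in range(n_periods)])
    subl = np.tile(s1, n_periods)
    radius = ch.diameter / 2.0
    theta = 2.0 * math.pi * c / ch.circumference
    pos = np.stack([radius * np.cos(theta), radius * np.sin(theta), z], axis=1)
    st = AtomicStructure(
        positions=pos,
        elements=["C"] * len(pos),
        period=n_periods * T,
        provenance={
            "kind": "periodic_tube",
            "n": ch.n,
            "m": ch.m,
            "n_periods": n_periods,
        },
        surface_coords=c,
        sublattice=subl,
    )
    st.rebuild_bonds(cutoff)
    return st


def build_finite_tube(
    chirality, length: float, cutoff: float = BOND_CUTOFF
) -> AtomicStructure:
    """Open-ended tube of the requested length, rounded DOWN to whole periods.

    Rim atoms (coordination 2) are left unterminated and tagged as
    ``open_end`` sites.  The axial cut is phased so that it severs only one
    bond per rim atom — the clean open edge — rather than stranding
    singly-coordinated atoms.
    """
    ch = _as_chirality(chirality)
    T = ch.translation_period
    n_periods = int(math.floor(length / T + 1e-9))
    if n_periods < 1:
        raise ValueError(
            f"requested length {length} nm is below one period ({T:.4f} nm)"
        )
    st = build_periodic_tube(ch, n_periods, cutoff)
    L = st.period
    st.period = None
    # scan cut phases (cyclic z-shifts of the same infinite tube) for one
    # that leaves every rim atom 2-coordinated
    for frac in range(12):
        shift = frac * T / 12.0 + 1e-4
        z = np.mod(st.positions[:, 2] + shift, L)
        trial = st.positions.copy()
        trial[:, 2] = z
        bi, bj, im = compute_bonds(trial, None, cutoff)
        deg = np.zeros(st.n_atoms, dtype=int)
        np.add.at(deg, bi, 1)
        np.add.at(deg, bj, 1)
        if deg.min() >= 2:
            order = np.lexsort((np.round(trial[:, 0] / 1e-6),
                                np.round(trial[:, 1] / 1e-6),
                                np.round(trial[:, 2] / 1e-6)))
            st.positions = trial[order]
            st.surface_coords = st.surface_coords[order]
            st.sublattice = st.sublattice[order]
            break
    else:  # pragma: no cover - honeycomb always admits a clean cut
        raise RuntimeError(f"no clean open-end cut found for {ch}")
    st.rebuild_bonds(cutoff)
    st.provenance = {
        "kind": "finite_tube",
        "n": ch.n,
        "m": ch.m,
        "n_periods": n_periods,
        "requested_length": float(length),
        "length": n_periods * T,
    }
    deg = st.degrees()
    rim = np.nonzero(deg < 3)[0]
    st.open_end_atoms = [int(i) for i in rim]
    return st


def cylinder_radius(structure: AtomicStructure) -> float:
    """Mean radial distance of atoms from the z axis (canonical frame)."""
    return float(np.mean(np.hypot(structure.positions[:, 0], structure.positions[:, 1])))


def relax_bonds(
    structure: AtomicStructure,
    k_spring: float = 30.0,
    r0: float = A_CC,
    step: float = 2e-3,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AtomicStructure:
    """Optional harmonic nearest-neighbour relaxation (steepest descent).

    OFF by default everywhere: the ideal rolled cylinder already has the
    correct topology, which is what the tight-binding model consumes.  The
    pass is provided for users who want bond lengths equalized after defect
    surgery.  Convergence: max force component < ``tol`` (eV/nm with the
    default spring constant in eV/nm^2).
    """
    st = structure.copy()
    pos = st.positions
    for _ in range(max_iter):
        delta = pos[st.bond_j] - pos[st.bond_i]
        if st.period is not None:
            delta = delta + np.outer(st.bond_image, [0.0, 0.0, st.period])
        d = np.linalg.norm(delta, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        fmag = k_spring * (d - r0)          # attractive when stretched
        fvec = (fmag / d)[:, None] * delta
        force = np.zeros_like(pos)
        np.add.at(force, st.bond_i, fvec)
        np.add.at(force, st.bond_j, -fvec)
        if np.abs(force).max() < tol:
            break
        pos = pos + step * force
    st.positions = pos
    st.rebuild_bonds()
    return st


def _check_pristine(structure: AtomicStructure) -> None:
    """Raise if the structure is not a valid pristine periodic tube."""
    deg = structure.degrees()
    if not np.all(deg == 3):
        raise ValueError("bond graph is not 3-regular")
    bl = structure.bond_lengths()
    if np.any(np.abs(bl - A_CC) > 0.05 * A_CC):
        warnings.warn("bond lengths deviate >5% from 0.142 nm")
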