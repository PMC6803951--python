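"""Random SWCNT networks in a periodic box: packing, contacts, hot spots.

Tubes are placed as rigid straight cylinders (their 5–20 nm lengths are far
below typical persistence lengths) by random sequential insertion: uniform
base point in the box, uniform orientation on the sphere, uniform length in
the configured range, rejected whenever any surface–surface distance to an
already placed tube falls below the van der Waals exclusion gap (0.34 nm
default).  Distances are closest-approach distances between axis segments
minus the two radii, under the minimum-image convention in all three
directions.

Close contacts (surface gap within 0.2–0.4 nm by default) are where
nanowelding initiates: point defects are seeded on both partner tubes at
the contact, and the hot-spot temperature map raises defect-site and
open-end atoms 16–20% above the base temperature, reflecting the locally
enhanced absorption and depressed thermal conductivity of defective
regions.  The welding dynamics itself is a hand-off to external reactive
MD codes and is not modelled here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chirality import ChiralIndices, _as_chirality
from .constants import M_CARBON_KG, VDW_GAP
from .defects import DefectSpec, apply_defect
from .structure import AtomicStructure, build_finite_tube


@dataclass
class TubeSegment:
    """One straight tube: geometry plus (lazily built) atomistic model."""

    chirality: ChiralIndices
    length: float                  # nm (rounded down to whole periods)
    base: np.ndarray               # (3,) nm, segment start
    axis: np.ndarray               # (3,) unit vector
    structure: Optional[AtomicStructure] = None

    @property
    def radius(self) -> float:
        return self.chirality.diameter / 2.0

    @property
    def end(self) -> np.ndarray:
        return self.base + self.length * self.axis

    @property
    def n_periods(self) -> int:
        return int(math.floor(self.length / self.chirality.translation_period + 1e-9))

    @property
    def n_atoms(self) -> int:
        return self.n_periods * self.chirality.atoms_per_cell

    def atomize(self) -> AtomicStructure:
        """Build (once) the atomistic model in the network frame."""
        if self.structure is None:
            st = build_finite_tube(self.chirality, self.length)
            R = _rotation_z_to(self.axis)
            st.positions = st.positions @ R.T + self.base
            st.provenance["network_axis"] = self.axis.tolist()
            st.provenance["network_base"] = self.base.tolist()
            self.structure = st
        return self.structure


@dataclass
class Contact:
    tube_i: int
    tube_j: int
    gap: float                       # nm, surface-surface
    point_i: np.ndarray              # closest point on axis i
    point_j: np.ndarray              # closest point on axis j (image frame)
    image_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    atom_pair: Optional[tuple[int, int]] = None  # nearest atoms (set on demand)


@dataclass
class NetworkModel:
    box: np.ndarray                  # (3,) nm, periodic in all directions
    tubes: list[TubeSegment]
    rng_seed: int
    exclusion_gap: float
    contacts: list[Contact] = field(default_factory=list)
    defect_assignments: list[dict] = field(default_factory=list)

    @property
    def n_tubes(self) -> int:
        return len(self.tubes)

    @property
    def n_atoms(self) -> int:
        return sum(t.n_atoms for t in self.tubes)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


class PlacementError(RuntimeError):
    """Packing failed; carries the number of tubes successfully placed."""

    def __init__(self, placed: int, requested: int, max_attempts: int):
        super().__init__(
            f"placed only {placed}/{requested} tubes after {max_attempts} "
            "attempts for one tube; box too dense for the exclusion gap"
        )
        self.placed = placed


# ------------------------------------------------------------------ geometry

def _rotation_z_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ez to the given unit axis."""
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(ez, axis)
    c = float(ez @ axis)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def segment_distance_batch(
    p: np.ndarray, u: np.ndarray, L: float,
    bases: np.ndarray, axes: np.ndarray, lengths: np.ndarray,
) -> np.ndarray:
    """Closest-approach distances from segment (p, u, L) to many segments.

    Standard closed-form segment–segment clamping (Ericson), vectorized
    over the second operand.  All arrays in nm.  Returns (distances, s, t)
    with s, t the normalized closest-point parameters in [0, 1].
    """
    d1 = u * L                                # (3,)
    d2 = axes * lengths[:, None]              # (M, 3)
    r = p[None, :] - bases                    # p1 - p2
    a = float(L * L)                          # d1·d1 (> 0: tubes have length)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = r @ d1
    b = d2 @ d1
    denom = a * e - b * b
    safe = np.where(denom > 1e-12, denom, 1.0)
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / safe, 0.0, 1.0), 0.0)
    e_safe = np.where(e > 1e-12, e, 1.0)
    t = (b * s + f) / e_safe
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.where(t == t_cl, s, np.clip((b * t_cl - c) / a, 0.0, 1.0))
    closest1 = p[None, :] + s[:, None] * d1[None, :]
    closest2 = bases + t_cl[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1), s, t_cl


_IMAGE_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def min_image_segment_gap(
    t1: TubeSegment, t2: TubeSegment, box: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum surface gap between two tubes over all periodic images.

    Returns (gap, closest point on tube1 axis, closest point on tube2 axis,
    image shift of tube2); the closest points live in the frame where tube2
    is shifted to its realizing image.
    """
    shifts = _IMAGE_SHIFTS * box[None, :]
    bases = t2.base[None, :] + shifts
    axes = np.repeat(t2.axis[None, :], len(shifts), axis=0)
    lengths = np.full(len(shifts), t2.length)
    d, s, t = segment_distance_batch(t1.base, t1.axis, t1.length, bases, axes, lengths)
    i = int(np.argmin(d))
    p1 = t1.base + s[i] * t1.axis * t1.length
    p2 = bases[i] + t[i] * t2.axis * t2.length
    return float(d[i]) - t1.radius - t2.radius, p1, p2, shifts[i]


def _gaps_to_placed(
    seg: TubeSegment, tubes: Sequence[TubeSegment], box: np.ndarray
) -> np.ndarray:
    """Surface gaps from one segment to all placed segments (min image)."""
    if not tubes:
        return np.zeros(0)
    shifts = _IMAGE_SHIFTS * box[None, :]
    bases = np.concatenate([t.base[None, :] + shifts for t in tubes])
    axes = np.concatenate([np.repeat(t.axis[None, :], len(shifts), axis=0) for t in tubes])
    lengths = np.concatenate([np.full(len(shifts), t.length) for t in tubes])
    radii = np.concatenate([np.full(len(shifts), t.radius) for t in tubes])
    d, _, _ = segment_distance_batch(seg.base, seg.axis, seg.length, bases, axes, lengths)
    gaps = (d - radii - seg.radius).reshape(len(tubes), len(shifts))
    return gaps.min(axis=1)


# ------------------------------------------------------------------ packing

def generate_network(
    box: Sequence[float],
    n_tubes: int,
    length_range: tuple[float, float] = (5.0, 20.0),
    chirality=(4, 4),
    exclusion_gap: float = VDW_GAP,
    seed: int = 0,
    max_attempts: int = 20000,
) -> NetworkModel:
    """Random sequential insertion of rigid tubes into a periodic box."""
    box = np.asarray(box, dtype=float)
    ch = _as_chirality(chirality)
    lo, hi = length_range
    if hi >= box.max():
        raise ValueError("longest tube must be shorter than the longest box edge")
    rng = np.random.default_rng(seed)
    tubes: list[TubeSegment] = []
    for _ in range(n_tubes):
        placed = False
        for _attempt in range(max_attempts):
            length = float(rng.uniform(lo, hi))
            # snap to whole periods so geometry and atomistics agree
            length = math.floor(length / ch.translation_period) * ch.translation_period
            if length < ch.translation_period:
                continue
            base = rng.uniform(0.0, 1.0, 3) * box
            axis = _random_unit_vector(rng)
            seg = TubeSegment(ch, length, base, axis)
            gaps = _gaps_to_placed(seg, tubes, box)
            if len(gaps) == 0 or gaps.min() >= exclusion_gap:
                tubes.append(seg)
                placed = True
                break
        if not placed:
            raise PlacementError(len(tubes), n_tubes, max_attempts)
    return NetworkModel(box=box, tubes=tubes, rng_seed=seed, exclusion_gap=exclusion_gap)


def _random_unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def place_tubes(
    box, specs: Sequence[tuple], exclusion_gap: float = VDW_GAP
) -> NetworkModel:
    """Explicit placement API (no exclusion rejection): specs are
    (chirality, length, base, axis) tuples."""
    tubes = [
        TubeSegment(_as_chirality(c), float(l), np.asarray(b, float),
                    np.asarray(a, float) / np.linalg.norm(a))
        for c, l, b, a in specs
    ]
    return NetworkModel(box=np.asarray(box, float), tubes=tubes, rng_seed=-1,
                        exclusion_gap=exclusion_gap)


# ------------------------------------------------------------------ contacts

def detect_contacts(
    network: NetworkModel,
    d_min: float = 0.2,
    d_max: float = 0.4,
    method: str = "hash",
) -> list[Contact]:
    """Tube pairs whose minimal surface gap lies in [d_min, d_max].

    ``method='hash'`` prunes pairs with a spatial grid before the exact
    segment-distance check; ``method='brute'`` scans all pairs.  Both give
    identical results (the grid is conservative).
    """
    if d_min >= d_max:
        raise ValueError("d_min must be below d_max")
    pairs = (_candidate_pairs_hash(network, d_max) if method == "hash"
             else itertools.combinations(range(network.n_tubes), 2))
    contacts = []
    for i, j in pairs:
        gap, p1, p2, shift = min_image_segment_gap(
            network.tubes[i], network.tubes[j], network.box
        )
        if d_min <= gap <= d_max:
            contacts.append(Contact(i, j, gap, p1, p2, image_shift=shift))
    contacts.sort(key=lambda c: (c.tube_i, c.tube_j))
    network.contacts = contacts
    return contacts


def _candidate_pairs_hash(network: NetworkModel, d_max: float):
    """Conservative candidate pairs from a periodic spatial grid.

    Segments are sampled along their axes at half-cell steps; two tubes
    whose capsules approach within d_max always land within two grid cells
    of each other, so scanning the ±2 neighbourhood never loses a pair.
    """
    box = network.box
    r_max = max(t.radius for t in network.tubes)
    h = max(2.0, d_max + 2 * r_max + 0.5)
    ncell = np.maximum(1, np.floor(box / h).astype(int))
    cell_of: dict[tuple, set] = {}
    for idx, t in enumerate(network.tubes):
        n_samp = max(2, int(math.ceil(t.length / (h / 2.0))) + 1)
        pts = t.base[None, :] + np.linspace(0, 1, n_samp)[:, None] * (t.length * t.axis)[None, :]
        pts = np.mod(pts, box)
        cells = np.floor(pts / (box / ncell)).astype(int)
        cells = np.minimum(cells, ncell - 1)
        for c in {tuple(c) for c in cells}:
            cell_of.setdefault(c, set()).add(idx)
    pairs = set()
    offsets = list(itertools.product(range(-2, 3), repeat=3))
    for c, ids in cell_of.items():
        for off in offsets:
            nb = tuple((np.array(c) + off) % ncell)
            for a in ids:
                for b in cell_of.get(nb, ()):
                    if a < b:
                        pairs.add((a, b))
    return sorted(pairs)


def nearest_atom_pair(
    network: NetworkModel, contact: Contact, window: float = 1.5
) -> tuple[int, int]:
    """Nearest atoms of the two partner tubes around a contact point.

    Only atoms within ``window`` nm (along the axis) of the closest-approach
    points are examined, which keeps the search local.
    """
    ti = network.tubes[contact.tube_i]
    tj = network.tubes[contact.tube_j]
    si, sj = ti.atomize(), tj.atomize()
    pi = si.positions
    # tube j may realize the contact through a periodic image; shift to it
    pj = sj.positions + contact.image_shift
    ai = np.nonzero(np.abs((pi - contact.point_i) @ ti.axis) < window)[0]
    aj = np.nonzero(np.abs((pj - contact.point_j) @ tj.axis) < window)[0]
    if len(ai) == 0 or len(aj) == 0:  # pragma: no cover - degenerate window
        ai, aj = np.arange(len(pi)), np.arange(len(pj))
    d = np.linalg.norm(pi[ai][:, None, :] - pj[aj][None, :, :], axis=2)
    r, c = np.unravel_index(np.argmin(d), d.shape)
    contact.atom_pair = (int(ai[r]), int(aj[c]))
    return contact.atom_pair


# ------------------------------------------------------------------ defects / hot spots

def seed_defects_at_contacts(
    network: NetworkModel,
    defect_kinds: Sequence[str] = ("SV", "DV", "SW"),
    seed: int = 0,
) -> NetworkModel:
    """One defect per contact on each partner tube, at the nearest atoms.

    The defect kind is drawn uniformly from ``defect_kinds``.  A contact
    atom already consumed by an earlier defect is skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    consumed: set[tuple[int, int]] = set()
    network.defect_assignments = []
    for contact in network.contacts:
        kind = str(rng.choice(list(defect_kinds)))
        ai, aj = nearest_atom_pair(network, contact)
        entry = {"contact": (contact.tube_i, contact.tube_j), "kind": kind, "atoms": []}
        for tube_idx, atom in ((contact.tube_i, ai), (contact.tube_j, aj)):
            if (tube_idx, atom) in consumed:
                warnings.warn(
                    f"atom {atom} of tube {tube_idx} already consumed by a "
                    "previous defect; skipping"
                )
                continue
            consumed.add((tube_idx, atom))
            st = network.tubes[tube_idx].atomize()
            try:
                spec = (DefectSpec(kind, site=atom) if kind != "SW"
                        else DefectSpec("SW", site=_bond_near_atom(st, atom)))
                network.tubes[tube_idx].structure = apply_defect(st, spec, allow_close=True)
                entry["atoms"].append((tube_idx, atom))
            except ValueError as err:
                warnings.warn(f"defect on tube {tube_idx} atom {atom} skipped: {err}")
        network.defect_assignments.append(entry)
    return network


def _bond_near_atom(st: AtomicStructure, atom: int) -> int:
    deg = st.degrees()
    for b in range(st.n_bonds):
        i, j = int(st.bond_i[b]), int(st.bond_j[b])
        if atom in (i, j) and deg[i] == 3 and deg[j] == 3 and st.bond_image[b] == 0:
            return b
    raise ValueError(f"no interior bond at atom {atom}")


@dataclass
class TemperatureMap:
    """Per-atom temperature multipliers, one array per tube."""

    factors: list[np.ndarray]

    def all_factors(self) -> np.ndarray:
        return np.concatenate(self.factors) if self.factors else np.zeros(0)


def hot_spot_map(
    network: NetworkModel,
    overheat_range: tuple[float, float] = (0.16, 0.20),
    seed: int = 0,
) -> TemperatureMap:
    """Temperature factors: 1 everywhere, 1+U(overheat) at defect sites
    and open-end rims — the regions that absorb more and conduct less."""
    rng = np.random.default_rng(seed)
    lo, hi = overheat_range
    factors = []
    for tube in network.tubes:
        st = tube.atomize()
        f = np.ones(st.n_atoms)
        hot = sorted({a for d in st.defect_sites for a in d["atoms"]}
                     | set(st.open_end_atoms))
        if hot:
            f[hot] = 1.0 + rng.uniform(lo, hi, size=len(hot))
        factors.append(f)
    return TemperatureMap(factors=factors)


# ------------------------------------------------------------------ density / export

def network_density(network: NetworkModel) -> float:
    """Mass density in kg/m³ from the carbon atom count and box volume."""
    if network.volume <= 0:
        raise ValueError("box volume must be positive")
    mass = network.n_atoms * M_CARBON_KG
    return mass / (network.volume * 1e-27)


def export_network(
    network: NetworkModel, path, fmt: str = "xyz",
    temperature_map: Optional[TemperatureMap] = None,
) -> None:
    """Write all atoms (wrapped into the box) as one XYZ or PDB file."""
    from .io import write_structure

    positions = []
    elements = []
    for tube in network.tubes:
        st = tube.atomize()
        positions.append(np.mod(st.positions, network.box))
        elements.extend(st.elements)
    merged = AtomicStructure(
        positions=np.concatenate(positions),
        elements=elements,
        box=network.box,
        provenance={"kind": "network", "n_tubes": network.n_tubes,
                    "rng_seed": network.rng_seed},
    )
    tfac = temperature_map.all_factors() if temperature_map is not None else None
    write_structure(merged, path, fmt=fmt.upper(), temperature_factors=tfac)
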