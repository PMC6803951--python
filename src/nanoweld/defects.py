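"""Point-defect surgery on SWCNT structures.

Supported defects, following the standard nomenclature:

* ``SV`` — single vacancy (1V): one atom removed, leaving three
  2-coordinated neighbours.  Left unreconstructed.
* ``DV`` — double vacancy (2V): two bonded atoms removed.
* ``SW`` — Stone–Wales: one C–C bond rotated 90° about its midpoint in the
  local surface tangent plane and the graph rebonded, converting four
  hexagons into the 5-7-7-5 pentagon/heptagon pattern.
* ``MIXED`` — ordered list of the above applied sequentially (e.g. the
  SW+SW+1V combination used on armchair tubes).

Site indices refer to the structure *at the moment the component defect is
applied*; atom indices shift after removals, which `apply_defect` tracks
when updating the recorded defect sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import A_CC, BOND_CUTOFF
from .structure import AtomicStructure

_KINDS = ("SV", "DV", "SW", "MIXED")
OVERLAP_DISTANCE = 2.0 * A_CC   # defects closer than this are "overlapping"


@dataclass(frozen=True)
class DefectSpec:
    """Specification of one defect (or an ordered MIXED combination)."""

    kind: str
    site: Optional[int] = None          # atom index (SV/DV) or bond index (SW)
    components: tuple = ()              # DefectSpec list, MIXED only
    rng_seed: Optional[int] = None      # for random site selection

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "MIXED":
            if not self.components:
                raise ValueError("MIXED defect needs a non-empty component list")
            if any(c.kind == "MIXED" for c in self.components):
                raise ValueError("MIXED components must be non-MIXED specs")


def apply_defect(
    structure: AtomicStructure,
    spec: DefectSpec,
    allow_close: bool = False,
    cutoff: float = BOND_CUTOFF,
) -> AtomicStructure:
    """Return a new structure with the defect applied and tagged.

    ``allow_close=True`` overrides the guard against placing a defect within
    two bond lengths of an existing one (a warning is still emitted).
    """
    if spec.kind == "MIXED":
        st = structure
        rng = np.random.default_rng(spec.rng_seed)
        for comp in spec.components:
            if comp.site is None and comp.rng_seed is None:
                comp = DefectSpec(comp.kind, rng_seed=int(rng.integers(2**31)))
            st = apply_defect(st, comp, allow_close=allow_close, cutoff=cutoff)
        return st

    st = structure.copy()
    rng = np.random.default_rng(spec.rng_seed)

    if spec.kind in ("SV", "DV"):
        site = spec.site
        if site is None:
            site = int(rng.integers(st.n_atoms))
        if not (0 <= site < st.n_atoms):
            raise IndexError(f"atom index {site} out of range (n_atoms={st.n_atoms})")
        _guard_overlap(st, st.positions[site], allow_close)
        remove = [site]
        nbrs = st.neighbor_lists()[site]
        if spec.kind == "DV":
            if not nbrs:
                raise ValueError(f"atom {site} has no bonded neighbour for a DV")
            partner = min(j for j, _ in nbrs)   # deterministic choice
            remove.append(partner)
        affected = sorted({j for r in remove for j, _ in st.neighbor_lists()[r]} - set(remove))
        new_st, index_map = _remove_atoms(st, remove, cutoff)
        new_st.defect_sites.append({
            "kind": "1V" if spec.kind == "SV" else "2V",
            "atoms": [int(index_map[a]) for a in affected if index_map[a] >= 0],
            "removed": len(remove),
        })
        return new_st

    # --- Stone-Wales ---
    bond = spec.site
    if bond is None:
        interior = _interior_bonds(st)
        if not len(interior):
            raise ValueError("no interior bond available for a SW defect")
        bond = int(rng.choice(interior))
    if not (0 <= bond < st.n_bonds):
        raise IndexError(f"bond index {bond} out of range (n_bonds={st.n_bonds})")
    u, v = int(st.bond_i[bond]), int(st.bond_j[bond])
    if st.bond_image[bond] != 0:
        raise ValueError("SW rotation across the periodic boundary is not supported; "
                         "pick an interior (image-0) bond")
    deg = st.degrees()
    if deg[u] != 3 or deg[v] != 3:
        raise ValueError(
            f"SW bond ({u},{v}) is not interior: both atoms must be 3-coordinated "
            f"(got degrees {deg[u]}, {deg[v]}; edge bonds of finite tubes are rejected)"
        )
    mid = 0.5 * (st.positions[u] + st.positions[v])
    _guard_overlap(st, mid, allow_close)
    axis = _surface_normal(mid)
    R = _rotation_matrix(axis, math.pi / 2.0)
    for a in (u, v):
        st.positions[a] = mid + R @ (st.positions[a] - mid)
    st.rebuild_bonds(cutoff)
    st.surface_coords = None
    st.sublattice = None
    st.defect_sites.append({"kind": "SW", "atoms": [u, v], "removed": 0})
    return st


# ------------------------------------------------------------------ helpers

def _interior_bonds(st: AtomicStructure) -> np.ndarray:
    deg = st.degrees()
    ok = (st.bond_image == 0) & (deg[st.bond_i] == 3) & (deg[st.bond_j] == 3)
    return np.nonzero(ok)[0]


def _guard_overlap(st: AtomicStructure, point: np.ndarray, allow_close: bool) -> None:
    tagged = sorted({a for d in st.defect_sites for a in d["atoms"]})
    if not tagged:
        return
    dists = np.linalg.norm(st.positions[tagged] - point, axis=1)
    if dists.min() < OVERLAP_DISTANCE:
        msg = (f"new defect within {OVERLAP_DISTANCE:.3f} nm of an existing one "
               f"(min distance {dists.min():.3f} nm)")
        if allow_close:
            warnings.warn(msg + "; proceeding (allow_close=True)")
        else:
            raise ValueError(msg + "; pass allow_close=True to override")


def _surface_normal(point: np.ndarray) -> np.ndarray:
    """Outward radial direction of the canonical (axis=z) cylinder."""
    n = np.array([point[0], point[1], 0.0])
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("point lies on the tube axis; cannot define a tangent plane")
    return n / norm


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    ux, uy, uz = axis
    c, s = math.cos(angle), math.sin(angle)
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _remove_atoms(
    st: AtomicStructure, remove: Sequence[int], cutoff: float
) -> tuple[AtomicStructure, np.ndarray]:
    keep = np.setdiff1d(np.arange(st.n_atoms), np.asarray(remove, dtype=int))
    index_map = -np.ones(st.n_atoms, dtype=int)
    index_map[keep] = np.arange(len(keep))
    new = AtomicStructure(
        positions=st.positions[keep].copy(),
        elements=[st.elements[i] for i in keep],
        period=st.period,
        box=st.box,
        provenance=dict(st.provenance),
        surface_coords=None,
        sublattice=None,
    )
    new.rebuild_bonds(cutoff)
    # remap previously recorded defect sites and open ends
    for d in st.defect_sites:
        new.defect_sites.append(
            dict(d, atoms=[int(index_map[a]) for a in d["atoms"] if index_map[a] >= 0])
        )
    new.open_end_atoms = [int(index_map[a]) for a in st.open_end_atoms if index_map[a] >= 0]
    return new, index_map
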