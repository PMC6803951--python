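"""Defect surgery semantics and the pentagon/heptagon ring census."""

import collections

import numpy as np
import pytest

from nanoweld.defects import DefectSpec, apply_defect
from nanoweld.rings import ring_census, trace_faces
from nanoweld.structure import build_finite_tube, build_periodic_tube


def rdkit_ring_sizes(st, max_size=10):
    """Independent ring perception via RDKit's SSSR (test oracle)."""
    from rdkit import Chem

    mol = Chem.RWMol()
    for _ in range(st.n_atoms):
        a = Chem.Atom(6)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    for i, j in zip(st.bond_i, st.bond_j):
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    m = mol.GetMol()
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return collections.Counter(
        s for s in (len(r) for r in m.GetRingInfo().AtomRings()) if s <= max_size
    )


# ------------------------------------------------------------------ census

def test_pristine_census_hexagons_only():
    """One (20,0) period is 40 faces on the torus — all hexagons."""
    st = build_periodic_tube((20, 0))
    assert dict(ring_census(st)) == {6: 40}


def test_sw_census_two_pentagons_two_heptagons():
    st = build_periodic_tube((20, 0))
    sw = apply_defect(st, DefectSpec("SW", site=0))
    assert sw.n_atoms == 80                      # SW removes no atoms
    census = ring_census(sw)
    assert census[5] == 2 and census[7] == 2 and census[6] == 36
    assert np.all(sw.degrees() == 3)             # rebonding keeps 3-regularity


def test_census_agrees_with_rdkit_sssr():
    """Face tracing and RDKit's independent SSSR perception agree on a
    finite tube before and after a Stone–Wales rotation."""
    ft = build_finite_tube((13, 0), 2.0)
    assert ring_census(ft) == rdkit_ring_sizes(ft)
    sw = apply_defect(ft, DefectSpec("SW", site=ft.n_bonds // 2))
    ours, theirs = ring_census(sw), rdkit_ring_sizes(sw)
    assert ours == theirs
    assert ours[5] == 2 and ours[7] == 2


def test_face_count_conserved_by_sw():
    """SW preserves V and E, hence the total face count (Euler)."""
    st = build_periodic_tube((20, 0), 2)
    sw = apply_defect(st, DefectSpec("SW", site=0))
    assert len(trace_faces(sw)) == len(trace_faces(st))


# ------------------------------------------------------------------ vacancies

def test_single_vacancy_atom_count():
    """One (15,15) period: 60 atoms pristine, 59 after a single vacancy."""
    st = build_periodic_tube((15, 15))
    assert st.n_atoms == 60
    assert apply_defect(st, DefectSpec("SV", site=5)).n_atoms == 59


def test_single_vacancy_semantics():
    st = build_periodic_tube((15, 15), 3)   # long enough for distinct neighbours
    sv = apply_defect(st, DefectSpec("SV", site=5))
    assert sv.n_atoms == st.n_atoms - 1
    assert int(np.sum(sv.degrees() == 2)) == 3   # three dangling atoms
    assert sv.defect_sites[0]["kind"] == "1V"
    assert len(sv.defect_sites[0]["atoms"]) == 3


def test_double_vacancy_removes_bonded_pair():
    st = build_periodic_tube((15, 15))
    dv = apply_defect(st, DefectSpec("DV", site=5))
    assert dv.n_atoms == st.n_atoms - 2
    assert dv.defect_sites[0]["kind"] == "2V"


def test_mixed_two_sw_plus_vacancy():
    """The SW+SW+1V combination: net atom change −1, two disjoint
    5-7-7-5 patterns (4 pentagons + 4 heptagons) in the census."""
    st = build_periodic_tube((15, 15), 4)
    spec = DefectSpec("MIXED", components=(
        DefectSpec("SW", site=0),
        DefectSpec("SW", rng_seed=11),
        DefectSpec("SV", rng_seed=12),
    ))
    out = apply_defect(st, spec, allow_close=True)
    assert out.n_atoms == st.n_atoms - 1
    census = ring_census(out)
    assert census[5] == 4 and census[7] == 4
    kinds = [d["kind"] for d in out.defect_sites]
    assert sorted(kinds) == ["1V", "SW", "SW"]


# ------------------------------------------------------------------ guards

def test_sw_on_rim_bond_rejected():
    ft = build_finite_tube((4, 4), 1.0)
    rim = set(ft.open_end_atoms)
    edge_bonds = [b for b in range(ft.n_bonds)
                  if ft.bond_i[b] in rim or ft.bond_j[b] in rim]
    with pytest.raises(ValueError, match="interior"):
        apply_defect(ft, DefectSpec("SW", site=edge_bonds[0]))


def test_overlapping_defects_need_override():
    st = build_periodic_tube((15, 15), 2)
    one = apply_defect(st, DefectSpec("SV", site=10))
    neighbour = one.defect_sites[0]["atoms"][0]
    with pytest.raises(ValueError, match="allow_close"):
        apply_defect(one, DefectSpec("SV", site=neighbour))
    with pytest.warns(UserWarning, match="proceeding"):
        two = apply_defect(one, DefectSpec("SV", site=neighbour), allow_close=True)
    assert two.n_atoms == st.n_atoms - 2


def test_seeded_defect_choice_is_deterministic():
    st = build_periodic_tube((13, 0), 2)
    a = apply_defect(st, DefectSpec("SV", rng_seed=42))
    b = apply_defect(st, DefectSpec("SV", rng_seed=42))
    assert np.array_equal(a.positions, b.positions)
    c = apply_defect(st, DefectSpec("SV", rng_seed=43))
    assert a.positions.shape == c.positions.shape
    assert not np.array_equal(a.positions, c.positions)


def test_unknown_kind_rejected():
    with pytest.raises(ValueError):
        DefectSpec("XX")
    with pytest.raises(ValueError):
        DefectSpec("MIXED", components=())
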