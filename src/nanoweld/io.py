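"""Structure I/O: XYZ (with metadata comment) and PDB (visualization).

The XYZ comment line carries a JSON payload (cell, defect tags, open ends,
provenance) so that write→read round-trips are lossless for everything the
pipeline cares about; coordinates are written in nm at 1e-6 nm precision.

PDB files are written in Å with the per-atom temperature factor in the
B-factor column (used by the network hot-spot map) and metadata in REMARK
records.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .structure import AtomicStructure

_META_PREFIX = "nanoweld_meta="


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class StructureParseError(ValueError):
    """Malformed structure file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _meta_dict(st: AtomicStructure) -> dict:
    return {
        "period": st.period,
        "box": None if st.box is None else list(map(float, st.box)),
        "defect_sites": st.defect_sites,
        "open_end_atoms": st.open_end_atoms,
        "provenance": st.provenance,
    }


def _apply_meta(st: AtomicStructure, meta: dict) -> None:
    st.period = meta.get("period")
    box = meta.get("box")
    st.box = None if box is None else np.asarray(box, dtype=float)
    st.defect_sites = meta.get("defect_sites", [])
    st.open_end_atoms = meta.get("open_end_atoms", [])
    st.provenance = meta.get("provenance", {})


def write_structure(
    structure: AtomicStructure,
    path,
    fmt: Optional[str] = None,
    temperature_factors: Optional[np.ndarray] = None,
) -> None:
    """Write XYZ or PDB; the format defaults to the file extension."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write a structure with 0 atoms")
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "XYZ":
        _write_xyz(structure, path)
    elif fmt == "PDB":
        _write_pdb(structure, path, temperature_factors)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use XYZ or PDB")


def read_structure(path, fmt: Optional[str] = None) -> AtomicStructure:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "XYZ":
        return _read_xyz(path)
    if fmt == "PDB":
        return _read_pdb(path)
    raise ValueError(f"unsupported format {fmt!r}; use XYZ or PDB")


# ------------------------------------------------------------------ XYZ

def _write_xyz(st: AtomicStructure, path: Path) -> None:
    lines = [str(st.n_atoms), _META_PREFIX + json.dumps(_meta_dict(st), default=_json_default)]
    for el, (x, y, z) in zip(st.elements, st.positions):
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _read_xyz(path: Path) -> AtomicStructure:
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureParseError(path, 1, "empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise StructureParseError(path, 1, f"expected atom count, got {lines[0]!r}")
    if len(lines) < n + 2:
        raise StructureParseError(path, len(lines), f"expected {n} atom lines")
    meta = {}
    comment = lines[1].strip()
    if comment.startswith(_META_PREFIX):
        try:
            meta = json.loads(comment[len(_META_PREFIX):])
        except json.JSONDecodeError:
            raise StructureParseError(path, 2, "malformed metadata JSON")
    elements, coords = [], []
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise StructureParseError(path, 3 + k, f"malformed atom line {lines[2+k]!r}")
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise StructureParseError(path, 3 + k, "non-numeric coordinate")
        elements.append(parts[0])
    _warn_non_carbon(elements)
    st = AtomicStructure(positions=np.asarray(coords), elements=elements)
    _apply_meta(st, meta)
    st.rebuild_bonds()
    return st


# ------------------------------------------------------------------ PDB

def _write_pdb(st: AtomicStructure, path: Path, tfac: Optional[np.ndarray]) -> None:
    if tfac is None:
        tfac = np.ones(st.n_atoms)
    lines = ["REMARK 250 " + _META_PREFIX + json.dumps(_meta_dict(st), default=_json_default)]
    if st.box is not None:
        bx, by, bz = (10.0 * np.asarray(st.box)).tolist()
        lines.append(
            f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}  90.00  90.00  90.00 P 1           1"
        )
    for k, (el, (x, y, z)) in enumerate(zip(st.elements, st.positions)):
        serial = (k % 99999) + 1
        lines.append(
            f"ATOM  {serial:5d} {el:<4s}MOL A   1    "
            f"{10*x:8.3f}{10*y:8.3f}{10*z:8.3f}{1.0:6.2f}{tfac[k]:6.2f}"
            f"          {el:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_pdb(path: Path) -> AtomicStructure:
    meta = {}
    elements, coords, tfac = [], [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("REMARK 250 " + _META_PREFIX):
            try:
                meta = json.loads(line.split(_META_PREFIX, 1)[1])
            except json.JSONDecodeError:
                raise StructureParseError(path, ln, "malformed metadata JSON")
        elif line.startswith(("ATOM", "HETATM")):
            try:
                coords.append([float(line[30:38]) / 10.0,
                               float(line[38:46]) / 10.0,
                               float(line[46:54]) / 10.0])
                tfac.append(float(line[60:66]) if line[60:66].strip() else 1.0)
            except ValueError:
                raise StructureParseError(path, ln, "malformed ATOM record")
            el = line[76:78].strip() or line[12:16].strip()
            elements.append(el or "C")
    if not coords:
        raise StructureParseError(path, 1, "no ATOM records found")
    _warn_non_carbon(elements)
    st = AtomicStructure(positions=np.asarray(coords), elements=elements)
    _apply_meta(st, meta)
    st.provenance.setdefault("temperature_factors", tfac)
    st.rebuild_bonds()
    return st


def _warn_non_carbon(elements) -> None:
    other = sorted({e for e in elements if e != "C"})
    if other:
        warnings.warn(
            f"non-carbon elements {other} read; accepted for forward compatibility"
        )
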