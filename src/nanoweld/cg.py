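"""Coarse-grained composition bookkeeping for matrix and membrane boxes.

The protein–polymer matrices (SWCNT framework + albumin / collagen /
chitosan filler in water) and the DPPC membrane are simulated with external
coarse-grained engines; what this module owns is the exact composition
arithmetic: per-component bead counts, grand totals, box metadata, and
consistency checks against declared totals.  Bead-type breakdowns within a
grain are opaque (counts only).

Presets reproduce the studied boxes: the 30 nm albumin box
(19,827 SWCNT + 25,970 albumin + 200,000 water = 245,797 grains), the
collagen and chitosan boxes with the same SWCNT framework, and the
50×50×4 nm membrane of 8,450 DPPC lipids at 12 beads each (101,400 beads —
the standard coarse-grained DPPC mapping: 2 head + 2 glycerol + 2×4 tail
beads).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

DPPC_BEADS = 12   # standard coarse-grained DPPC topology


@dataclass(frozen=True)
class Component:
    name: str
    beads_per_molecule: int
    n_molecules: int

    def __post_init__(self):
        if self.beads_per_molecule <= 0 or self.n_molecules <= 0:
            raise ValueError(
                f"component {self.name!r}: counts must be positive integers"
            )
        if (int(self.beads_per_molecule) != self.beads_per_molecule
                or int(self.n_molecules) != self.n_molecules):
            raise ValueError(f"component {self.name!r}: counts must be integers")

    @property
    def total_beads(self) -> int:
        return self.beads_per_molecule * self.n_molecules


@dataclass
class CGSystemManifest:
    components: list[Component]
    box: Optional[tuple[float, float, float]] = None   # nm
    temperature: float = 310.0                         # K, thermostat
    name: str = ""

    @property
    def totals(self) -> dict[str, int]:
        return {c.name: c.total_beads for c in self.components}

    @property
    def total_beads(self) -> int:
        return sum(c.total_beads for c in self.components)

    def check_total(self, expected: int) -> None:
        """Raise if the grand total disagrees with a declared count."""
        if self.total_beads != expected:
            raise ValueError(
                f"manifest total {self.total_beads} != declared {expected} "
                f"(difference {self.total_beads - expected})"
            )

    # ---------------------------------------------------------- JSON round trip
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "box_nm": list(self.box) if self.box else None,
            "temperature_K": self.temperature,
            "components": [
                {"name": c.name, "beads_per_molecule": c.beads_per_molecule,
                 "n_molecules": c.n_molecules, "total_beads": c.total_beads}
                for c in self.components
            ],
            "total_beads": self.total_beads,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CGSystemManifest":
        comps = [Component(c["name"], c["beads_per_molecule"], c["n_molecules"])
                 for c in d["components"]]
        manifest = cls(
            components=comps,
            box=tuple(d["box_nm"]) if d.get("box_nm") else None,
            temperature=d.get("temperature_K", 310.0),
            name=d.get("name", ""),
        )
        if "total_beads" in d:
            manifest.check_total(d["total_beads"])
        return manifest

    @classmethod
    def from_json(cls, path) -> "CGSystemManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compose_system(
    components: Sequence[tuple[str, int, int]],
    box=None,
    temperature: float = 310.0,
    name: str = "",
    allow_empty: bool = False,
) -> CGSystemManifest:
    """Manifest from (name, beads_per_molecule, n_molecules) triples."""
    if not components and not allow_empty:
        raise ValueError("empty component list (pass allow_empty=True to permit)")
    if not components:
        warnings.warn("composing an empty system (total 0 beads)")
    comps = [Component(n, int(b), int(m)) for n, b, m in components]
    return CGSystemManifest(components=comps, box=box, temperature=temperature,
                            name=name)


def membrane_manifest(
    n_lipids: int = 8450, beads_per_lipid: int = DPPC_BEADS
) -> CGSystemManifest:
    """DPPC membrane layer: total beads = n_lipids × beads_per_lipid."""
    return compose_system(
        [("DPPC", beads_per_lipid, n_lipids)],
        box=(50.0, 50.0, 4.0), temperature=310.0, name="membrane",
    )


# the SWCNT framework common to all three matrix boxes
_SWCNT = ("SWCNT", 19827, 1)

PRESETS: dict[str, dict] = {
    "albumin-box": {
        "components": [_SWCNT, ("albumin", 5194, 5), ("water", 1, 200000)],
        "box": (30.0, 30.0, 30.0),
        "expected_total": 245797,
    },
    "collagen-box": {
        "components": [_SWCNT, ("collagen", 56498, 1), ("water", 1, 160000)],
        "box": (30.0, 30.0, 30.0),
        "expected_total": 236325,
    },
    "chitosan-box": {
        "components": [_SWCNT, ("chitosan", 9237, 1), ("water", 1, 200000)],
        "box": (30.0, 30.0, 30.0),
        "expected_total": 229064,
    },
}


def preset_manifest(name: str) -> CGSystemManifest:
    """One of the studied boxes by name ('membrane' or a matrix preset)."""
    if name == "membrane":
        m = membrane_manifest()
        m.check_total(101400)
        return m
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{sorted(PRESETS) + ['membrane']}")
    p = PRESETS[name]
    m = compose_system(p["components"], box=p["box"], name=name)
    m.check_total(p["expected_total"])
    return m
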