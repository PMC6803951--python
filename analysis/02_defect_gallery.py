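#!/usr/bin/env python
"""Gallery of point-defected SWCNT supercells with ring censuses.

Reproduces the showcase defect set — an armchair (15,15) cell with the
mixed 2×SW + 1V defect, a zigzag (20,0) cell with two double vacancies,
a (20,0) cell with a single SW rotation, and a (15,15) cell with one 2V —
then verifies the topology signatures (pentagon/heptagon counts, dangling
atoms) and exports XYZ models to results/structures/.
"""

import warnings
from pathlib import Path

import pandas as pd

from nanoweld.defects import DefectSpec, apply_defect
from nanoweld.io import write_structure
from nanoweld.rings import ring_census
from nanoweld.structure import build_periodic_tube

RESULTS = Path(__file__).resolve().parents[1] / "results"

GALLERY = [
    ("15-15_mixed_2sw_1v", (15, 15), 4, DefectSpec("MIXED", components=(
        DefectSpec("SW", site=0), DefectSpec("SW", rng_seed=11),
        DefectSpec("SV", rng_seed=12)))),
    ("20-0_two_2v", (20, 0), 3, DefectSpec("MIXED", components=(
        DefectSpec("DV", site=0), DefectSpec("DV", rng_seed=21)))),
    ("20-0_single_sw", (20, 0), 2, DefectSpec("SW", site=0)),
    ("15-15_single_2v", (15, 15), 3, DefectSpec("DV", site=0)),
]


def main():
    outdir = RESULTS / "structures"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, nm, periods, spec in GALLERY:
        pristine = build_periodic_tube(nm, periods)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            defected = apply_defect(pristine, spec, allow_close=True)
        census = ring_census(defected)
        n_dangling = int((defected.degrees() == 2).sum())
        write_structure(defected, outdir / f"{name}.xyz")
        rows.append({
            "model": name, "chirality": f"({nm[0]},{nm[1]})",
            "atoms_pristine": pristine.n_atoms, "atoms": defected.n_atoms,
            "pentagons": census.get(5, 0), "hexagons": census.get(6, 0),
            "heptagons": census.get(7, 0), "dangling_atoms": n_dangling,
        })
        print(f"{name:20s} {pristine.n_atoms:4d} -> {defected.n_atoms:4d} atoms, "
              f"rings 5/6/7 = {census.get(5,0)}/{census.get(6,0)}/{census.get(7,0)}, "
              f"{n_dangling} dangling atoms")

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "defect_gallery.csv", index=False)
    print("\nEach SW contributes the 5-7-7-5 signature (+2 pentagons, "
          "+2 heptagons); vacancies leave 2-coordinated atoms that later "
          "act as welding hot spots.")
    print(f"models -> {outdir}, table -> {RESULTS/'defect_gallery.csv'}")


if __name__ == "__main__":
    main()
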