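#!/usr/bin/env python
"""Coarse-grained composition manifests for the matrix and membrane boxes.

Writes the four preset manifests (SWCNT+albumin, SWCNT+collagen,
SWCNT+chitosan matrices and the DPPC membrane) as JSON under
results/cg_manifests/ and prints the bead totals, including the exact
245,797-grain albumin box and the 101,400-bead membrane (8,450 DPPC × 12).
"""

from pathlib import Path

from nanoweld.cg import preset_manifest

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    outdir = RESULTS / "cg_manifests"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("albumin-box", "collagen-box", "chitosan-box", "membrane"):
        m = preset_manifest(name)
        m.to_json(outdir / f"{name}.json")
        parts = ", ".join(f"{k}={v:,}" for k, v in m.totals.items())
        print(f"{name:13s}: {parts}  ->  total {m.total_beads:,} beads "
              f"(thermostat {m.temperature:g} K)")
    print(f"\nmanifests -> {outdir}")


if __name__ == "__main__":
    main()
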