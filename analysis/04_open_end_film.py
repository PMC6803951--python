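#!/usr/bin/env python
"""End-illuminated film of finite open-ended tubes.

Here the wave vector runs along the tube axes, so the electric field is
perpendicular to them and the film cross-section per tube is the
hexagonal-packing area (d + 0.5 nm pitch).  Finite tubes have no k-grid:
the Γ-point spectrum of the open-ended (4,4) tube feeds the conductivity,
and the open-end rim states contribute transitions that the infinite tube
does not have.  The wavelength range starts at 100 nm because the film is
as thick as the tubes are long.

Writes the A(λ) spectrum and a peak report under results/.

Note: perpendicular response is computed from bare matrix elements; the
depolarization correction that suppresses it in real tubes is not applied,
so magnitudes are upper bounds.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nanoweld.chirality import ChiralIndices
from nanoweld.constants import HC_EV_NM
from nanoweld.film import (FilmModel, absorption, bin_peaks,
                           find_absorption_maxima)
from nanoweld.kubo import KuboConfig, kubo_conductivity
from nanoweld.structure import build_finite_tube
from nanoweld.tb import TBModel, band_structure

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--length", type=float, default=10.0,
                        help="tube length in nm (40 for the full-size film)")
    parser.add_argument("--eta", type=float, default=0.05)
    parser.add_argument("--n-omega", type=int, default=600)
    args = parser.parse_args()

    ch = ChiralIndices(4, 4)
    tube = build_finite_tube(ch, args.length)
    print(f"open-ended (4,4) tube, {args.length} nm -> {tube.n_atoms} atoms, "
          f"{len(tube.open_end_atoms)} rim atoms")

    bands = band_structure(tube, TBModel(), nk=1)   # Γ only: finite system
    omega = np.linspace(HC_EV_NM / 3000.0, HC_EV_NM / 100.0, args.n_omega)
    film = FilmModel(geometry="end_illuminated_open_ends",
                     thickness=args.length)
    cfg = KuboConfig(omega=omega, eta=args.eta, temperature=300.0,
                     polarization="x")
    sigma = kubo_conductivity(bands, cfg, scell=film.scell(ch))
    spec = absorption(sigma, film)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame({"lambda_nm": spec.wavelength, "A": spec.A,
                  "R2": spec.R2, "T2": spec.T2}).to_csv(
        RESULTS / "absorption_open_end_4-4.csv", index=False,
        float_format="%.5g")
    peaks = find_absorption_maxima(spec, 0.01)
    counts = bin_peaks(peaks)
    print(f"{len(peaks)} absorption maxima, A_max={spec.A.max():.3f} at "
          f"{spec.wavelength[spec.A.argmax()]:.0f} nm")
    print(f"peaks per window: {counts}")
    pd.DataFrame(peaks, columns=["lambda_nm", "A"]).to_csv(
        RESULTS / "open_end_peaks.csv", index=False)
    print(f"spectrum -> {RESULTS/'absorption_open_end_4-4.csv'}")


if __name__ == "__main__":
    main()
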