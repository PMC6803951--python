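"""Physical constants and lattice parameters used throughout the package.

Lengths are nanometres and energies electron-volts unless a name says
otherwise; conversions to SI happen only inside the conductivity kernel.
"""

import math

# --- graphene / nanotube lattice ---
A_LATTICE = 0.246          # nm, graphene lattice constant a = sqrt(3) * a_cc
A_CC = A_LATTICE / math.sqrt(3.0)   # nm, C-C bond length (0.142 nm)
BOND_CUTOFF = 0.17         # nm, bond-detection cutoff: between 1st (0.142)
                           # and 2nd (0.246) neighbour shells

# --- tight-binding defaults ---
GAMMA0 = 2.7               # eV, nearest-neighbour pi-orbital hopping

# --- electromagnetic / thermodynamic ---
Z0 = 120.0 * math.pi       # ohm, free-space wave impedance
HC_EV_NM = 1239.842        # eV*nm, photon-energy <-> wavelength conversion
KB_EV = 8.617333262e-5     # eV/K, Boltzmann constant

# --- SI values (conductivity kernel only) ---
E_CHARGE = 1.602176634e-19     # C (also J per eV)
HBAR_SI = 1.054571817e-34      # J*s
M_ELECTRON = 9.1093837015e-31  # kg
EV_J = E_CHARGE                # J per eV
NM_M = 1e-9                    # m per nm

# --- masses ---
M_CARBON_KG = 12.011 * 1.66054e-27  # kg, atomic carbon mass

# --- van der Waals / packing defaults ---
VDW_GAP = 0.34             # nm, graphitic wall-to-wall exclusion distance
FILM_GAP = 0.5             # nm, inter-tube gap in the parallel-tube film
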