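"""Independent oracles shared by the unit and acceptance suites.

The flux-accounting oracle assembles the derivative of each species
reaction by reaction from a stoichiometry table and the mass-action flux
of that single reaction; it never calls the packaged right-hand side.
"""

import numpy as np

from wntclock.model import SPECIES_INDEX


def flux_oracle_rhs(y, p, k_mod=1.0, s_b_mod=1.0):
    C, GA, G, B, L, Dm, D, LD, A, LGA = y
    dy = np.zeros(10)

    def add(stoich, flux):
        for name, coeff in stoich.items():
            dy[SPECIES_INDEX[name]] += coeff * flux

    add({"G": -1, "A": -1, "GA": +1}, (p.kminus_GA / p.K_GA) * G * A)
    add({"G": +1, "A": +1, "GA": -1}, p.kminus_GA * GA)
    add({"L": -1, "GA": -1, "LGA": +1}, (p.kminus_LGA / p.K_LGA) * k_mod * L * GA)
    add({"L": +1, "GA": +1, "LGA": -1}, p.kminus_LGA * LGA)
    add({"LGA": -1, "L": +1, "G": +1}, p.v * LGA)          # Axin degraded at the receptor
    add({"B": -1, "GA": -1, "C": +1}, (p.kminus_C / p.K_C) * B * GA)
    add({"B": +1, "GA": +1, "C": -1}, p.kminus_C * C)
    add({"C": -1, "GA": +1}, p.alpha * C)                  # beta-catenin degraded in C
    add({"B": +1}, p.S_B * s_b_mod)
    add({"A": +1}, p.S_A)
    add({"Dm": +1}, p.k_tx * B ** p.h)
    add({"Dm": -1}, Dm / p.tau_Dm)
    add({"D": +1}, p.k_tl * Dm)
    add({"D": -1}, D / p.tau_D)
    add({"L": -1, "D": -1, "LD": +1}, (p.kminus_LD / p.K_LD) * L * D)
    add({"L": +1, "D": +1, "LD": -1}, p.kminus_LD * LD)
    return dy


def random_states(n, seed, scale=50.0):
    """Random strictly-positive state vectors for oracle comparisons."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.01, scale, size=(n, len(SPECIES_INDEX)))
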