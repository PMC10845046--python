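"""Shared fixtures: an independent fixed-step integrator and tiny CRN rigs."""

import numpy as np
import pytest

from domaincode.compiler import Reaction, crn_from_reactions
from domaincode.strands import complex_species, single_species


@pytest.fixture(scope="session")
def rk4_integrate():
    """Brute-force fixed-step RK4 oracle, independent of the solver path.

    Rates are evaluated straight off the reaction list, not through the
    package's vectorised RHS builder.
    """

    def integrate(crn, t_end, dt):
        idx = {sp.structure: i for i, sp in enumerate(crn.species)}
        y = np.array([sp.init_conc for sp in crn.species], dtype=float)

        def deriv(state):
            dy = np.zeros_like(state)
            for rxn in crn.reactions:
                v = rxn.rate
                for sp in rxn.reactants:
                    v *= state[idx[sp.structure]]
                for sp in rxn.reactants:
                    dy[idx[sp.structure]] -= v
                for sp in rxn.products:
                    dy[idx[sp.structure]] += v
            return dy

        steps = int(round(t_end / dt))
        times = [0.0]
        states = [y.copy()]
        for i in range(steps):
            k1 = deriv(y)
            k2 = deriv(y + dt / 2 * k1)
            k3 = deriv(y + dt / 2 * k2)
            k4 = deriv(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            times.append((i + 1) * dt)
            states.append(y.copy())
        return np.array(times), np.array(states), [sp.name for sp in crn.species]

    return integrate


def displacement_rig(a0=1.0, g0=1.0e7, rate=1e-9):
    """A + G -> O + W single-displacement CRN with strand conservation."""
    A = single_species(("sig", "A", 0, 0), "A", "input", a0)
    G = complex_species([("fuel", "G", 0), ("sig", "O", 0, 0)], "G", "gate", g0)
    O = single_species(("sig", "O", 0, 0), "O", "output")
    W = complex_species([("fuel", "G", 0), ("sig", "A", 0, 0)], "W", "waste")
    return crn_from_reactions([Reaction((A, G), (O, W), rate, label="disp")])


def catalytic_rig(a0=100.0, g0=100.0, h0=200.0, rate=3.0e-4):
    """A + G -> O + I; I + H -> A + W catalytic loop (6 species)."""
    A = single_species(("sig", "A", 0, 0), "A", "input", a0)
    G = complex_species([("ft", "g", 0, 0), ("sig", "O", 0, 0)], "G", "gate", g0)
    O = single_species(("sig", "O", 0, 0), "O", "output")
    I = complex_species([("ft", "g", 0, 0), ("sig", "A", 0, 0)], "I",
                        "intermediate")
    H = single_species(("fuel", "g", 0), "H", "fuel", h0)
    W = complex_species([("ft", "g", 0, 0), ("fuel", "g", 0)], "W", "waste")
    return crn_from_reactions([
        Reaction((A, G), (O, I), rate, label="release"),
        Reaction((I, H), (A, W), rate, label="recover"),
    ])
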