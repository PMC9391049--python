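"""In-situ Gibbs free energies of acetogenic and methanogenic reactions.

Standard free energies at the incubation temperature come from the
Gibbs-Helmholtz / van't Hoff relation

    dG0(T) = dH0 - T * (dH0 - dG0_298) / 298.15

(assuming a temperature-independent reaction enthalpy over the narrow window
considered), and the in-situ value adds the Nernst reaction-quotient term

    dG = dG0(T) + R * T * ln Q.

Q is built from molar concentrations of the dissolved species (dilute-solution
activities), proton activity 10^-pH, and unit water activity.  Dissolved-gas
concentrations — not partial pressures — enter Q; the aqueous-convention
formation constants in the shipped table match that choice.  When any
required reactant is censored (e.g. H2 below the detection limit) or
nonpositive, no dG is computed and the result is flagged undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .constants import DEFAULT_CONSTANTS, ConstantsError, PhysChemConstants

#: Organism-scale feasibility limit for acetogens (kJ per mol reaction): the
#: lowest energy yield at which cultured acetogens have been shown to operate.
ACETOGEN_LIMIT_KJ = -5.0


class Feasibility(str, Enum):
    EXERGONIC_BEYOND_THRESHOLD = "exergonic_beyond_threshold"
    EXERGONIC = "exergonic"
    ENDERGONIC = "endergonic"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class ReactionSpec:
    """A balanced reaction with standard-state constants (298.15 K, aqueous)."""

    name: str
    stoichiometry: dict[str, int]       # products positive
    delta_g0_298: float                 # kJ mol-1
    delta_h0_298: float                 # kJ mol-1
    species_states: dict[str, str]      # aqueous | water | proton


@dataclass(frozen=True)
class DeltaGResult:
    reaction: str
    delta_g: float | None               # kJ mol-1
    defined: bool
    reason: str = ""


def reaction_from_constants(
    name: str, constants: PhysChemConstants = DEFAULT_CONSTANTS
) -> ReactionSpec:
    """Build a :class:`ReactionSpec` from the shipped (balance-checked) tables."""
    try:
        stoich = constants.reactions[name]
    except KeyError:
        raise ConstantsError(
            f"unknown reaction {name!r}; shipped: {sorted(constants.reactions)}"
        ) from None
    dg0 = sum(nu * constants.species[sp].dgf for sp, nu in stoich.items())
    dh0 = sum(nu * constants.species[sp].dhf for sp, nu in stoich.items())
    states = {sp: constants.species[sp].state for sp in stoich}
    return ReactionSpec(name, dict(stoich), dg0, dh0, states)


def shipped_reactions(
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> dict[str, ReactionSpec]:
    return {name: reaction_from_constants(name, constants) for name in constants.reactions}


def standard_delta_g_at_t(reaction: ReactionSpec, temperature_k: float) -> float:
    """dG0 at *temperature_k* via the van't Hoff / Gibbs-Helmholtz correction."""
    if not (250.0 < temperature_k < 350.0):
        import warnings

        warnings.warn(
            f"temperature {temperature_k} K outside the plausible incubation "
            "window (250, 350) K",
            stacklevel=2,
        )
    t_ref = 298.15
    return reaction.delta_h0_298 - temperature_k * (
        (reaction.delta_h0_298 - reaction.delta_g0_298) / t_ref
    )


def in_situ_delta_g(
    reaction: ReactionSpec,
    concentrations: dict[str, float | None],
    ph: float,
    temperature_k: float,
    constants: PhysChemConstants = DEFAULT_CONSTANTS,
) -> DeltaGResult:
    """dG (kJ per mol reaction) at the given molar concentrations, pH and T.

    *concentrations* maps species names to mol l-1; ``None`` marks a censored
    measurement and yields an undefined result rather than a number.
    """
    ln_q = 0.0
    for species, nu in reaction.stoichiometry.items():
        state = reaction.species_states.get(species)
        if state is None:
            raise ConstantsError(f"species {species!r} missing a state")
        if state == "water":
            continue
        if state == "proton":
            ln_q += nu * math.log(10.0 ** (-ph))
            continue
        if species not in concentrations:
            raise ConstantsError(
                f"no concentration supplied for species {species!r}"
            )
        c = concentrations[species]
        if c is None:
            return DeltaGResult(reaction.name, None, False,
                                f"{species} censored (below detection)")
        if c <= 0:
            return DeltaGResult(reaction.name, None, False,
                                f"{species} concentration {c} not positive")
        ln_q += nu * math.log(c)
    dg0_t = standard_delta_g_at_t(reaction, temperature_k)
    nernst = constants.gas_constant * temperature_k * ln_q / 1000.0  # kJ
    return DeltaGResult(reaction.name, dg0_t + nernst, True)


def feasibility_classification(
    result: DeltaGResult, threshold_kj: float = ACETOGEN_LIMIT_KJ
) -> Feasibility:
    """Classify a dG against 0 and an organism-specific energetic limit."""
    if not result.defined or result.delta_g is None:
        return Feasibility.UNDEFINED
    if result.delta_g <= threshold_kj:
        return Feasibility.EXERGONIC_BEYOND_THRESHOLD
    if result.delta_g < 0:
        return Feasibility.EXERGONIC
    return Feasibility.ENDERGONIC
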