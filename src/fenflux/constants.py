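"""Physico-chemical constants shared by the chemistry and thermodynamics layers.

The package ships one commented YAML file with Henry solubilities, the first
carbonic-acid dissociation constant, the gas constant, and an aqueous-convention
table of standard formation energies; :func:`load_constants` parses it into a
frozen :class:`PhysChemConstants`.  Users may point the loader at their own file
to swap constant sets without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import math

import yaml


class ConstantsError(ValueError):
    """Raised when a constants file is malformed or internally inconsistent."""


@dataclass(frozen=True)
class HenryConstant:
    """Solubility K_H (mol l-1 atm-1) at 298.15 K with van't Hoff slope B (K)."""

    kh_298: float
    vant_hoff_b: float

    def at(self, temperature_k: float) -> float:
        """Temperature-corrected K_H; colder water dissolves more gas (B > 0)."""
        return self.kh_298 * math.exp(
            self.vant_hoff_b * (1.0 / temperature_k - 1.0 / 298.15)
        )


@dataclass(frozen=True)
class SpeciesThermo:
    state: str                      # aqueous | water | proton
    formula: dict[str, int]
    charge: int
    dgf: float                      # kJ mol-1, 298.15 K
    dhf: float                      # kJ mol-1, 298.15 K


@dataclass(frozen=True)
class PhysChemConstants:
    gas_constant: float             # J mol-1 K-1
    reference_temperature: float    # K
    atm_pa: float
    henry: dict[str, HenryConstant]
    carbonate_pk1_coeffs: tuple[float, float, float]
    species: dict[str, SpeciesThermo] = field(default_factory=dict)
    reactions: dict[str, dict[str, int]] = field(default_factory=dict)

    def henry_for(self, gas: str) -> HenryConstant:
        try:
            return self.henry[gas]
        except KeyError:
            raise ConstantsError(
                f"no Henry constant for gas {gas!r}; supported gases: "
                f"{sorted(self.henry)}"
            ) from None

    def carbonate_pk1(self, temperature_k: float) -> float:
        """Harned & Davis fit of pK1 for CO2(aq) <-> HCO3- + H+ (6.352 at 25 C)."""
        a1, a2, a3 = self.carbonate_pk1_coeffs
        return a1 / temperature_k + a2 * temperature_k + a3


def _check_balance(name: str, stoich: dict[str, int],
                   species: dict[str, SpeciesThermo]) -> None:
    """Element and charge balance of a reaction, verified at load time."""
    elements: dict[str, float] = {}
    charge = 0.0
    for sp, nu in stoich.items():
        if sp not in species:
            raise ConstantsError(f"reaction {name!r} uses unknown species {sp!r}")
        info = species[sp]
        charge += nu * info.charge
        for el, count in info.formula.items():
            elements[el] = elements.get(el, 0.0) + nu * count
    bad = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    if bad or abs(charge) > 1e-9:
        raise ConstantsError(
            f"reaction {name!r} is not balanced (elements {bad}, charge {charge})"
        )


def load_constants(path: str | Path | None = None) -> PhysChemConstants:
    """Load constants from *path*, defaulting to the YAML file shipped in-package."""
    if path is None:
        text = resources.files("fenflux.data").joinpath("constants.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    henry = {
        gas: HenryConstant(float(v["kh_298"]), float(v["vant_hoff_b"]))
        for gas, v in raw["henry"].items()
    }
    for gas, hc in henry.items():
        if hc.kh_298 <= 0:
            raise ConstantsError(f"Henry constant for {gas} must be positive")

    pk1 = raw["carbonate_pk1"]
    species = {
        name: SpeciesThermo(
            state=str(v["state"]),
            formula={k: int(n) for k, n in v.get("formula", {}).items()},
            charge=int(v.get("charge", 0)),
            dgf=float(v["dgf"]),
            dhf=float(v["dhf"]),
        )
        for name, v in raw.get("species", {}).items()
    }
    reactions = {
        name: {sp: int(nu) for sp, nu in v["stoichiometry"].items()}
        for name, v in raw.get("reactions", {}).items()
    }
    for name, stoich in reactions.items():
        _check_balance(name, stoich, species)

    return PhysChemConstants(
        gas_constant=float(raw["gas_constant"]),
        reference_temperature=float(raw["reference_temperature"]),
        atm_pa=float(raw["atm_pa"]),
        henry=henry,
        carbonate_pk1_coeffs=(
            float(pk1["a_over_t"]), float(pk1["a_times_t"]), float(pk1["a_const"])
        ),
        species=species,
        reactions=reactions,
    )


DEFAULT_CONSTANTS = load_constants()
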