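# Physico-chemical and thermodynamic constants used throughout fenflux.
#
# Henry solubilities are K_H in mol l-1 atm-1 at 298.15 K with a van't Hoff
# temperature dependence K_H(T) = K_H(298.15) * exp(B * (1/T - 1/298.15));
# values of K_H and B are from the standard solubility compilations
# (Sander-type tables). Colder water dissolves more gas (B > 0).
#
# The first dissociation of carbonic acid uses the Harned & Davis fit
# pK1(T) = A1/T + A2*T + A3 (T in kelvin), which gives 6.352 at 25 degC.
#
# Formation energies (kJ mol-1, 298.15 K) follow the aqueous-species
# convention for all solutes including dissolved gases, after the classic
# anaerobe-energetics compilations (Thauer-style tables). Water is liquid,
# the proton enters reaction quotients through pH only.

gas_constant: 8.314462618   # J mol-1 K-1
reference_temperature: 298.15
atm_pa: 101325.0

henry:
  H2:  {kh_298: 7.8e-4, vant_hoff_b: 500.0}
  CO2: {kh_298: 3.4e-2, vant_hoff_b: 2400.0}
  CH4: {kh_298: 1.4e-3, vant_hoff_b: 1700.0}

carbonate_pk1:
  a_over_t: 3404.71
  a_times_t: 0.032786
  a_const: -14.8435

species:
  H2:      {state: aqueous, formula: {H: 2},              charge: 0,  dgf: 17.57,   dhf: -4.2}
  CO2:     {state: aqueous, formula: {C: 1, O: 2},        charge: 0,  dgf: -386.02, dhf: -413.8}
  CH4:     {state: aqueous, formula: {C: 1, H: 4},        charge: 0,  dgf: -34.39,  dhf: -89.04}
  acetate: {state: aqueous, formula: {C: 2, H: 3, O: 2},  charge: -1, dgf: -369.41, dhf: -486.01}
  H2O:     {state: water,   formula: {H: 2, O: 1},        charge: 0,  dgf: -237.18, dhf: -285.83}
  "H+":    {state: proton,  formula: {H: 1},              charge: 1,  dgf: 0.0,     dhf: 0.0}

# Products carry positive coefficients, substrates negative.
reactions:
  hydrogenotrophic_acetogenesis:
    stoichiometry: {H2: -4, CO2: -2, acetate: 1, "H+": 1, H2O: 2}
  hydrogenotrophic_methanogenesis:
    stoichiometry: {H2: -4, CO2: -1, CH4: 1, H2O: 2}
  aceticlastic_methanogenesis:
    stoichiometry: {acetate: -1, "H+": -1, CH4: 1, CO2: 1}
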