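# Nutrient solution recipes used throughout the pipeline.
# Concentrations are µM of the salt; `ions` maps ion identifier to the
# stoichiometric count per formula unit (hydration water ignored).
# `trace: true` marks micronutrient salts excluded from focal-ion totals.
recipes:
  - label: growth
    ph: 6.0
    salts:
      - {name: KH2PO4, umol_per_l: 500, ions: {potassium: 1, phosphate: 1}}
      - {name: KNO3, umol_per_l: 5700, ions: {potassium: 1, nitrate: 1}}
      - {name: NH4NO3, umol_per_l: 300, ions: {ammonium: 1, nitrate: 1}}
      - {name: CaCl2, umol_per_l: 2000, ions: {calcium: 1, chloride: 2}}
      - {name: MgSO4, umol_per_l: 1000, ions: {magnesium: 1, sulfate: 1}}
      - {name: H3BO3, umol_per_l: 46, ions: {borate: 1}, trace: true}
      - {name: ZnSO4.7H2O, umol_per_l: 7, ions: {zinc: 1, sulfate: 1}, trace: true}
      - {name: MnCl2.4H2O, umol_per_l: 9, ions: {manganese: 1, chloride: 2}, trace: true}
      - {name: CuSO4.5H2O, umol_per_l: 0.32, ions: {copper: 1, sulfate: 1}, trace: true}
      - {name: (NH4)6Mo7O24.4H2O, umol_per_l: 0.114, ions: {ammonium: 6, molybdate: 7}, trace: true}
      - {name: Fe(III)-EDTA, umol_per_l: 150, ions: {iron: 1, edta: 1}, trace: true}
  - label: deprivation
    ph: 6.0
    salts:
      - {name: CaCl2, umol_per_l: 500, ions: {calcium: 1, chloride: 2}}
      - {name: H3BO3, umol_per_l: 46, ions: {borate: 1}, trace: true}
      - {name: ZnSO4.7H2O, umol_per_l: 7, ions: {zinc: 1, sulfate: 1}, trace: true}
      - {name: MnCl2.4H2O, umol_per_l: 9, ions: {manganese: 1, chloride: 2}, trace: true}
      - {name: CuSO4.5H2O, umol_per_l: 0.32, ions: {copper: 1, sulfate: 1}, trace: true}
      - {name: (NH4)6Mo7O24.4H2O, umol_per_l: 0.114, ions: {ammonium: 6, molybdate: 7}, trace: true}
      - {name: Fe(III)-EDTA, umol_per_l: 150, ions: {iron: 1, edta: 1}, trace: true}
  - label: high
    ph: 6.0
    buffer: {name: MES, umol_per_l: 1000, ions: {mes: 1}}
    salts:
      - {name: KNO3, umol_per_l: 1000, ions: {potassium: 1, nitrate: 1}}
      - {name: NH4Cl, umol_per_l: 1000, ions: {ammonium: 1, chloride: 1}}
      - {name: Ca(H2PO4)2.H2O, umol_per_l: 125, ions: {calcium: 1, phosphate: 2}}
      - {name: MgSO4, umol_per_l: 250, ions: {magnesium: 1, sulfate: 1}}
      - {name: CaCl2, umol_per_l: 375, ions: {calcium: 1, chloride: 2}}
  - label: low
    ph: 6.0
    buffer: {name: MES, umol_per_l: 1000, ions: {mes: 1}}
    salts:
      - {name: KNO3, umol_per_l: 100, ions: {potassium: 1, nitrate: 1}}
      - {name: NH4Cl, umol_per_l: 100, ions: {ammonium: 1, chloride: 1}}
      - {name: Ca(H2PO4)2.H2O, umol_per_l: 12.5, ions: {calcium: 1, phosphate: 2}}
      - {name: MgSO4, umol_per_l: 25, ions: {magnesium: 1, sulfate: 1}}
      - {name: CaCl2, umol_per_l: 487.5, ions: {calcium: 1, chloride: 2}}
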