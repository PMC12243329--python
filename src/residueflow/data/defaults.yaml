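# Default run configuration: screening thresholds, conversion chains and
# market/land constants for the three model bioprocesses.
#
# The bundled reference matrix is already filtered to residues above the
# 250,000 Mg DM a-1 relevance cutoff, so the default cutoff here is 0
# (applying it again must be the identity).
reference_year: 2025
cutoff_Mg_DM_a: 0.0
report_significant_figures: 3
national_gdp_share: 0.03

processes:
  polymer_bricks_from_lignin:
    fraction: lignin
    screening: {favorable: 0.23, possible: 0.20, comparison: geq}
    market: {product: adipic_acid, global_production_Mg_a: 4500000.0}
    land:
      crop: trunk_wood
      areal_yield_Mg_ha_a: 10.0
      content_factor: 1.0
      feedstock_fraction_content: 0.25   # average lignin share of displaced wood
    chains:
      adipic_acid:
        steps:
          - {name: biomass decomposition, input: lignin in residues, output: recovered lignin, factor: 0.59}
          - {name: lignin depolymerization, input: recovered lignin, output: phenolic monomers, factor: 0.35, idealized: 0.50}
          - {name: electrochemical hydrogenation, input: phenolic monomers, output: cyclohexanol (incl. derivatives), factor: 0.68, idealized: 0.85}
          - {name: microbial conversion, input: cyclohexanol (incl. derivatives), output: adipic acid, factor: 0.61, idealized: 0.99}

  carboxylic_acids_from_nfc:
    fraction: nfc
    screening: {favorable: 0.20, possible: 0.16, comparison: geq}
    market: {product: c6_c8_carboxylic_acids, global_production_Mg_a: 1800000.0}
    land:
      crop: corn_silage
      areal_yield_Mg_ha_a: 40.0
      content_factor: 0.35               # dry-matter share of fresh corn silage
      feedstock_fraction_content: 1.0
    chains:
      c6_c8_carboxylic_acids:
        steps:
          - {name: anaerobic mixed-culture fermentation, input: NFC in residues, output: C6/C8 carboxylic acids, factor: 0.093}

  citric_acid_from_wfo:
    fraction: fats_oils
    screening: {favorable: 0.90, possible: 0.90, comparison: gt}
    restrict_to: [oil_waste]
    market: {product: citric_acid, global_production_Mg_a: 2000000.0}
    land:
      crop: rapeseed_oil
      areal_yield_Mg_ha_a: 40.0          # used verbatim from the source constants; far above agronomic norms
      content_factor: 0.446              # oil content
      feedstock_fraction_content: 1.0
    chains:
      citric_acid:
        steps:
          - {name: microbial conversion, input: waste cooking fat and oil, output: citric acid, factor: 1.32}
      citric_acid_wastewater:
        steps:
          - {name: microbial conversion (wastewater as process water), input: waste cooking fat and oil, output: citric acid, factor: 1.03}

  kga_from_glycerol:
    fraction: fats_oils
    screening: {favorable: 0.90, possible: 0.90, comparison: gt}
    restrict_to: [glycerol_biodiesel]
    chains:
      kga:
        steps:
          - {name: microbial conversion, input: raw glycerol, output: alpha-ketoglutarate, factor: 0.44}
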