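# reference_year: 2025
# provenance: bundled reference matrix of 20 German biogenic residues; relevant-fraction means from a published cross-sector composition survey; per-residue technical potentials are SYNTHETIC, reconstructed so tier pool sums close on the published pool tonnages; quality metadata synthetic/plausible
id,name,sector,technical_potential_Mg_DM_a,usable_share,cellulose_min,cellulose_mean,cellulose_max,hemicellulose_min,hemicellulose_mean,hemicellulose_max,lignin_min,lignin_mean,lignin_max,nfc_min,nfc_mean,nfc_max,protein_min,protein_mean,protein_max,fats_oils_min,fats_oils_mean,fats_oils_max,ash_min,ash_mean,ash_max,n_sources,analysis_quality,newest_source_year
bark,Bark,forestry,1000000,1.0,,,,,,,0.26,0.34,0.42,,,,,,,,,,,,,4,detailed,2019
wood_processing_byproducts,By-products of wood processing industry,industry,2400000,1.0,,,,,,,0.24,0.28,0.33,,,,,,,,,,,,,4,detailed,2021
other_industrial_waste_wood,Other industrial waste wood,industry,1600000,1.0,,,,,,,0.24,0.28,0.33,,,,,,,,,,,,,5,detailed_with_series,2022
brewery_residues,Residues from breweries (brewer's spent grain),industry,1000000,1.0,,,,,,,0.21,0.28,0.34,,,,,,,,,,,,,1,method_stated,2016
logging_residues_deciduous,Logging residues (deciduous),forestry,6000000,1.0,,,,,,,0.20,0.25,0.31,,,,,,,,,,,,,6,detailed_with_series,2023
landscape_woody_biomass,Woody biomass from landscape management,other,3400000,1.0,,,,,,,0.20,0.24,0.29,,,,,,,,,,,,,11,detailed,2017
waste_wood,Waste wood,industry,11000000,1.0,,,,,,,0.20,0.24,0.29,,,,,,,,,,,,,12,detailed_with_series,2021
logging_residues_coniferous,Logging residues (coniferous),forestry,4800000,1.0,,,,,,,0.19,0.23,0.28,,,,,,,,,,,,,4,detailed,2012
green_waste,Green waste,municipal_waste_sewage,8500000,1.0,,,,,,,0.15,0.20,0.26,,,,,,,,,,,,,2,method_stated,2013
leaves,Leaves (mixed species),other,3000000,1.0,,,,,,,0.15,0.20,0.25,,,,,,,,,,,,,2,detailed,2001
bakery_residues,Residues from bread and bakeries production,industry,500000,1.0,,,,,,,,,,0.52,0.65,0.78,,,,,,,,,,2,detailed,2020
starch_residues,Residues from starch production (potato pulp),industry,1000000,0.8,,,,,,,,,,0.42,0.53,0.64,,,,,,,,,,2,detailed,2022
milk_processing_residues,Residues from milk processing (whey),industry,1000000,1.0,,,,,,,,,,0.42,0.52,0.62,,,,,,,,,,2,detailed_with_series,2019
sugar_residues,Residues from sugar production,industry,1400000,1.0,,,,,,,,,,0.30,0.40,0.50,,,,,,,,,,4,detailed_with_series,2024
kitchen_canteen_waste,Kitchen and canteen wastes,municipal_waste_sewage,900000,1.0,,,,,,,,,,0.28,0.38,0.49,,,,,,,,,,4,detailed,2018
bioethanol_residues,Residues from bioethanol production,industry,2300000,1.0,,,,,,,,,,0.16,0.23,0.31,,,,,,,,,,3,method_stated,2010
cattle_solid_manure,Cattle solid manure,agriculture,9000000,1.0,,,,,,,,,,0.11,0.16,0.22,,,,,,,,,,5,detailed_with_series,2021
roadside_stalks,Stalks from roadside,other,700000,1.0,,,,,,,,,,0.11,0.16,0.21,,,,,,,,,,5,detailed,2015
glycerol_biodiesel,Glycerol from biodiesel production,industry,277000,1.0,,,,,,,,,,,,,,,,0.90,0.95,0.99,,,,1,unclear,1992
oil_waste,Oil waste,industry,156000,1.0,,,,,,,,,,,,,,,,0.85,0.91,0.97,,,,1,method_stated,2020
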