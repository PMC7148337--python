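{
 "description": "Synthetic stand-in for the curated species-specific reaction additions: four reactions absent from the reference organism's pathway map (gulonolactone oxidase, threonine dehydrogenase and the two cytochrome-b5-dependent neuraminate hydroxylase steps), written against the synthetic toy-model namespace with stand-in stoichiometry. Four metabolites are new to the model; dead-ended ones receive auto-generated sinks on addition.",
 "additions": [
  {
   "id": "R10053",
   "name": "L-gulonolactone oxidase (synthetic stand-in)",
   "stoichiometry": {"glc_c": -1, "o2_c": -1, "lac_c": 1, "h2o_c": 1},
   "lower_bound": 0,
   "upper_bound": 1000,
   "gene_reaction_rule": "268756",
   "subsystem": "ascorbate synthesis",
   "metabolites": []
  },
  {
   "id": "R01465",
   "name": "L-threonine 3-dehydrogenase (synthetic stand-in)",
   "stoichiometry": {"pyr_c": -1, "nadh_c": -1, "co2_c": 1, "nad_c": 1, "h2o_c": 1},
   "lower_bound": 0,
   "upper_bound": 1000,
   "gene_reaction_rule": "58865",
   "subsystem": "threonine degradation",
   "metabolites": []
  },
  {
   "id": "R01803",
   "name": "N-acetylneuraminate hydroxylase (synthetic stand-in)",
   "stoichiometry": {"glc_c": -1, "focytb5_c": -1, "o2_c": -1, "hc01115_c": 1, "ficytb5_c": 1, "h2o_c": 1},
   "lower_bound": 0,
   "upper_bound": 1000,
   "gene_reaction_rule": "12763",
   "subsystem": "aminosugar metabolism",
   "metabolites": [
    {"id": "focytb5_c", "name": "ferrocytochrome b5", "compartment": "c", "formula": "C200H300FeN50O50S2"},
    {"id": "ficytb5_c", "name": "ferricytochrome b5", "compartment": "c", "formula": "C200H299FeN50O50S2"},
    {"id": "hc01115_c", "name": "N-glycoloylneuraminate", "compartment": "c", "formula": "C11H19NO10"}
   ]
  },
  {
   "id": "R01115",
   "name": "CMP-N-acetylneuraminate hydroxylase (synthetic stand-in)",
   "stoichiometry": {"glc_c": -1, "focytb5_c": -1, "o2_c": -1, "cmpglna_c": 1, "ficytb5_c": 1, "h2o_c": 1},
   "lower_bound": 0,
   "upper_bound": 1000,
   "gene_reaction_rule": "12763",
   "subsystem": "aminosugar metabolism",
   "metabolites": [
    {"id": "cmpglna_c", "name": "CMP-N-glycoloylneuraminate", "compartment": "c", "formula": "C20H31N4O19P"}
   ]
  }
 ]
}
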