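{
 "id": "toy22",
 "metabolites": [
  {
   "id": "a_e",
   "name": "met_a (extracellular)",
   "compartment": "e"
  },
  {
   "id": "a_c",
   "name": "met_a (cytosol)",
   "compartment": "c"
  },
  {
   "id": "o_e",
   "name": "met_o (extracellular)",
   "compartment": "e"
  },
  {
   "id": "o_c",
   "name": "met_o (cytosol)",
   "compartment": "c"
  },
  {
   "id": "n_e",
   "name": "met_n (extracellular)",
   "compartment": "e"
  },
  {
   "id": "n_c",
   "name": "met_n (cytosol)",
   "compartment": "c"
  },
  {
   "id": "r_e",
   "name": "met_r (extracellular)",
   "compartment": "e"
  },
  {
   "id": "r_c",
   "name": "met_r (cytosol)",
   "compartment": "c"
  },
  {
   "id": "p_e",
   "name": "met_p (extracellular)",
   "compartment": "e"
  },
  {
   "id": "p_c",
   "name": "met_p (cytosol)",
   "compartment": "c"
  },
  {
   "id": "q_e",
   "name": "met_q (extracellular)",
   "compartment": "e"
  },
  {
   "id": "q_c",
   "name": "met_q (cytosol)",
   "compartment": "c"
  },
  {
   "id": "s_e",
   "name": "met_s (extracellular)",
   "compartment": "e"
  },
  {
   "id": "s_c",
   "name": "met_s (cytosol)",
   "compartment": "c"
  },
  {
   "id": "de_e",
   "name": "met_de (extracellular)",
   "compartment": "e"
  },
  {
   "id": "de_c",
   "name": "met_de (cytosol)",
   "compartment": "c"
  },
  {
   "id": "b_c",
   "name": "precursor b",
   "compartment": "c"
  },
  {
   "id": "c_c",
   "name": "precursor c",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_a",
   "name": "a exchange",
   "metabolites": {
    "a_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_o",
   "name": "o exchange",
   "metabolites": {
    "o_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_n",
   "name": "n exchange",
   "metabolites": {
    "n_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_r",
   "name": "r exchange",
   "metabolites": {
    "r_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_p",
   "name": "p exchange",
   "metabolites": {
    "p_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_q",
   "name": "q exchange",
   "metabolites": {
    "q_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_s",
   "name": "s exchange",
   "metabolites": {
    "s_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "EX_de",
   "name": "de exchange",
   "metabolites": {
    "de_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_a",
   "name": "a transport",
   "metabolites": {
    "a_c": 1.0,
    "a_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 10.0,
   "gene_reaction_rule": "gta1 and gta2",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_o",
   "name": "o transport",
   "metabolites": {
    "o_c": 1.0,
    "o_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 10.0,
   "gene_reaction_rule": "gto1 or gto2",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_n",
   "name": "n transport",
   "metabolites": {
    "n_c": 1.0,
    "n_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 10.0,
   "gene_reaction_rule": "gtn",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_r",
   "name": "r transport",
   "metabolites": {
    "r_c": 1.0,
    "r_e": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 10.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_p",
   "name": "p transport",
   "metabolites": {
    "p_c": -1.0,
    "p_e": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_q",
   "name": "q transport",
   "metabolites": {
    "q_c": -1.0,
    "q_e": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_s",
   "name": "s transport",
   "metabolites": {
    "s_c": -1.0,
    "s_e": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "T_de",
   "name": "de transport",
   "metabolites": {
    "de_c": -1.0,
    "de_e": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "V1",
   "name": "backbone synthesis",
   "metabolites": {
    "a_c": -1.0,
    "b_c": 1.0,
    "o_c": -1.0,
    "p_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g1",
   "objective_coefficient": 0.0
  },
  {
   "id": "V2a",
   "name": "conversion route a",
   "metabolites": {
    "b_c": -1.0,
    "c_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g2a",
   "objective_coefficient": 0.0
  },
  {
   "id": "V2b",
   "name": "conversion route b",
   "metabolites": {
    "b_c": -1.0,
    "c_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "g2b",
   "objective_coefficient": 0.0
  },
  {
   "id": "V3",
   "name": "side route",
   "metabolites": {
    "q_c": 1.0,
    "r_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "V4",
   "name": "overflow",
   "metabolites": {
    "a_c": -1.0,
    "p_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 0.0
  },
  {
   "id": "BIOMASS",
   "name": "biomass",
   "metabolites": {
    "c_c": -1.0,
    "n_c": -1.0,
    "s_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "gene_reaction_rule": "",
   "objective_coefficient": 1.0
  }
 ],
 "genes": []
}
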