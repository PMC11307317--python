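{
 "id": "bt_like",
 "version": "1",
 "metabolites": [
  {
   "id": "asp_e",
   "compartment": "e"
  },
  {
   "id": "nag_e",
   "compartment": "e"
  },
  {
   "id": "glc_e",
   "compartment": "e"
  },
  {
   "id": "gal_e",
   "compartment": "e"
  },
  {
   "id": "fuc_e",
   "compartment": "e"
  },
  {
   "id": "p_c",
   "compartment": "c"
  },
  {
   "id": "x_c",
   "compartment": "c"
  },
  {
   "id": "bio",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_asp",
   "name": "EX_asp",
   "metabolites": {
    "asp_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_nag",
   "name": "EX_nag",
   "metabolites": {
    "nag_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_glc",
   "name": "EX_glc",
   "metabolites": {
    "glc_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_gal",
   "name": "EX_gal",
   "metabolites": {
    "gal_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_fuc",
   "name": "EX_fuc",
   "metabolites": {
    "fuc_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_asp",
   "name": "T_asp",
   "metabolites": {
    "asp_e": -1.0,
    "p_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_nag",
   "name": "T_nag",
   "metabolites": {
    "nag_e": -1.0,
    "p_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_glc",
   "name": "T_glc",
   "metabolites": {
    "glc_e": -1.0,
    "x_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_gal",
   "name": "T_gal",
   "metabolites": {
    "gal_e": -1.0,
    "x_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_fuc",
   "name": "T_fuc",
   "metabolites": {
    "fuc_e": -1.0,
    "x_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "GROWTH",
   "name": "GROWTH",
   "metabolites": {
    "p_c": -1.0,
    "x_c": -0.3,
    "bio": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 1.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_bio",
   "name": "EX_bio",
   "metabolites": {
    "bio": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  }
 ],
 "genes": [],
 "compartments": {
  "c": "cytosol",
  "e": "extracellular"
 }
}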