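{
 "id": "fp_like",
 "version": "1",
 "metabolites": [
  {
   "id": "ser_e",
   "compartment": "e"
  },
  {
   "id": "thr_e",
   "compartment": "e"
  },
  {
   "id": "ura_e",
   "compartment": "e"
  },
  {
   "id": "ac_e",
   "compartment": "e"
  },
  {
   "id": "pep_e",
   "compartment": "e"
  },
  {
   "id": "ser_c",
   "compartment": "c"
  },
  {
   "id": "thr_c",
   "compartment": "c"
  },
  {
   "id": "ura_c",
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
   "id": "EX_ser",
   "name": "EX_ser",
   "metabolites": {
    "ser_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_thr",
   "name": "EX_thr",
   "metabolites": {
    "thr_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_ura",
   "name": "EX_ura",
   "metabolites": {
    "ura_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_ac",
   "name": "EX_ac",
   "metabolites": {
    "ac_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_pep",
   "name": "EX_pep",
   "metabolites": {
    "pep_e": -1.0
   },
   "lower_bound": -5.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_ser",
   "name": "T_ser",
   "metabolites": {
    "ser_e": -1.0,
    "ser_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_thr",
   "name": "T_thr",
   "metabolites": {
    "thr_e": -1.0,
    "thr_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_ura",
   "name": "T_ura",
   "metabolites": {
    "ura_e": -1.0,
    "ura_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_ac",
   "name": "T_ac",
   "metabolites": {
    "ac_e": -1.0,
    "x_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "T_pep",
   "name": "T_pep",
   "metabolites": {
    "pep_e": -1.0,
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
    "ser_c": -1.0,
    "thr_c": -0.5,
    "ura_c": -0.1,
    "x_c": -0.2,
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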