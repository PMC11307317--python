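{
 "id": "toynet_redundant",
 "version": "1",
 "metabolites": [
  {
   "id": "A1_e",
   "compartment": "e"
  },
  {
   "id": "A2_e",
   "compartment": "e"
  },
  {
   "id": "B_c",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_A1",
   "name": "EX_A1",
   "metabolites": {
    "A1_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "EX_A2",
   "name": "EX_A2",
   "metabolites": {
    "A2_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "C1",
   "name": "C1",
   "metabolites": {
    "A1_e": -1.0,
    "B_c": 1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "C2",
   "name": "C2",
   "metabolites": {
    "A2_e": -1.0,
    "B_c": 1.0
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
    "B_c": -1.0
   },
   "lower_bound": 0.0,
   "upper_bound": 8.0,
   "objective_coefficient": 1.0,
   "gene_reaction_rule": ""
  }
 ],
 "genes": [],
 "compartments": {
  "c": "cytosol",
  "e": "extracellular"
 }
}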