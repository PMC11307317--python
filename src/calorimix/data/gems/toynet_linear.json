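{
 "id": "toynet_linear",
 "version": "1",
 "metabolites": [
  {
   "id": "A_e",
   "compartment": "e"
  },
  {
   "id": "B_c",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_A",
   "name": "EX_A",
   "metabolites": {
    "A_e": -1.0
   },
   "lower_bound": -10.0,
   "upper_bound": 0.0,
   "objective_coefficient": 0.0,
   "gene_reaction_rule": ""
  },
  {
   "id": "CONV",
   "name": "CONV",
   "metabolites": {
    "A_e": -1.0,
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
   "upper_bound": 1000.0,
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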