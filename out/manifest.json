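{
 "files": {
  "hub_scores.csv": "57a156037e31b8c81d8437814135bd83cfc1de00e01807cccd43dbaa2656aaeb",
  "hub_scores.pdb": "aec4f081a26d718852c7aebc151789794c6269dfc7871b721d9ad092dc38251e",
  "mi_long.csv": "aa840cf8aa8d2e0b208809ff3264338eb71e23f349575d264b679d2c02b32ddc",
  "mi_matrix.csv": "dcd39437909c9c5c4cf7d87c36439b2706c35dc20d06a668ce86c75e6c47fcc5",
  "pathways.json": "fd993cd2e6f956e5cb490ad2eb306e8d95738edec787908ce4db1ab1ce68abdc",
  "pipelines.csv": "58d0e7329f56a5ea73ca08a7b6c833b3124b5c1c69fcec95580cb3224ba58506"
 },
 "parameters": {
  "cluster_cutoffs": [
   1.2,
   0.85
  ],
  "contact_cutoffs": [
   40.0,
   10.0
  ],
  "contact_distance": 4.5,
  "contact_mode": "heavy",
  "label_map": null,
  "mi_aggregation": "max",
  "mi_bins": 24,
  "microswitches": [],
  "min_separation": 10.0,
  "min_sequence_separation": 3,
  "nonbonded_params": null,
  "output_dir": "out",
  "partner_chain": null,
  "pca_n_extreme": 30,
  "pipeline_proximity": 7.0,
  "receptor_chain": "A",
  "seed": 0,
  "sinks": null,
  "snp_positions": [],
  "sources": [
   "A:6"
  ],
  "stride": 1,
  "structure": "fx/structure.pdb",
  "tm_ranges": {
   "TM1": [
    132,
    165
   ],
   "TM2": [
    173,
    199
   ],
   "TM3": [
    221,
    254
   ],
   "TM4": [
    264,
    288
   ],
   "TM5": [
    305,
    334
   ],
   "TM6": [
    343,
    367
   ],
   "TM7": [
    377,
    400
   ]
  },
  "top_fraction": 0.1,
  "top_pipelines": 5,
  "torsion_table": "fx/torsions.csv",
  "trajectories": []
 },
 "warnings": [
  "1 admissible source-sink pairs unreachable in graph"
 ]
}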