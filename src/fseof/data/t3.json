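{
 "id": "T3_redundant_toy",
 "metabolites": [
  {"id": "A", "name": "internal carbon pool", "compartment": "c", "formula": "C", "charge": null},
  {"id": "X", "name": "detour intermediate", "compartment": "c", "formula": "C", "charge": null},
  {"id": "P", "name": "product", "compartment": "c", "formula": "C", "charge": null}
 ],
 "reactions": [
  {"id": "EX_a", "name": "carbon uptake", "mets": {"A": 1.0}, "lb": 0.0, "ub": 10.0, "gpr": "", "subsystem": "exchange"},
  {"id": "R_bio", "name": "biomass", "mets": {"A": -1.0}, "lb": 0.0, "ub": 1000.0, "gpr": "", "subsystem": "biomass"},
  {"id": "R_direct", "name": "one-step route", "mets": {"A": -1.0, "P": 1.0}, "lb": 0.0, "ub": 1000.0, "gpr": "gD", "subsystem": "product"},
  {"id": "R_ax", "name": "detour step 1", "mets": {"A": -1.0, "X": 1.0}, "lb": 0.0, "ub": 1000.0, "gpr": "gX1", "subsystem": "product"},
  {"id": "R_xp", "name": "detour step 2", "mets": {"X": -1.0, "P": 1.0}, "lb": 0.0, "ub": 1000.0, "gpr": "gX2", "subsystem": "product"},
  {"id": "EX_p", "name": "product export", "mets": {"P": -1.0}, "lb": 0.0, "ub": 1000.0, "gpr": "", "subsystem": "exchange"}
 ],
 "biomass": "R_bio",
 "objective": "R_bio"
}
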