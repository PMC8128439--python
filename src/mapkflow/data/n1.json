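{
 "name": "N1",
 "nodes": [
  {
   "id": 1,
   "label": "signal",
   "role": "source"
  },
  {
   "id": 2,
   "label": "RAF",
   "role": "kinase"
  },
  {
   "id": 3,
   "label": "MEK",
   "role": "kinase"
  },
  {
   "id": 4,
   "label": "ERK",
   "role": "kinase"
  },
  {
   "id": 5,
   "label": "MLK",
   "role": "kinase"
  },
  {
   "id": 6,
   "label": "JNK",
   "role": "kinase"
  },
  {
   "id": 7,
   "label": "TAOK",
   "role": "kinase"
  },
  {
   "id": 8,
   "label": "p38",
   "role": "kinase"
  },
  {
   "id": 9,
   "label": "BACH1",
   "role": "output"
  }
 ],
 "edges": [
  {
   "src": 1,
   "dst": 2,
   "fraction_name": "alpha1",
   "kind": "pathway"
  },
  {
   "src": 1,
   "dst": 5,
   "fraction_name": "alpha2",
   "kind": "pathway"
  },
  {
   "src": 1,
   "dst": 7,
   "fraction_name": "A12",
   "kind": "pathway"
  },
  {
   "src": 2,
   "dst": 3,
   "fraction_name": "unit",
   "kind": "pathway"
  },
  {
   "src": 3,
   "dst": 4,
   "fraction_name": "unit",
   "kind": "pathway"
  },
  {
   "src": 5,
   "dst": 6,
   "fraction_name": "alpha3",
   "kind": "pathway"
  },
  {
   "src": 5,
   "dst": 8,
   "fraction_name": "A3",
   "kind": "crosstalk"
  },
  {
   "src": 7,
   "dst": 6,
   "fraction_name": "alpha4",
   "kind": "crosstalk"
  },
  {
   "src": 7,
   "dst": 8,
   "fraction_name": "A4",
   "kind": "pathway"
  },
  {
   "src": 8,
   "dst": 4,
   "fraction_name": "A5",
   "kind": "crosstalk"
  },
  {
   "src": 8,
   "dst": 9,
   "fraction_name": "alpha5",
   "kind": "pathway"
  },
  {
   "src": 4,
   "dst": 6,
   "fraction_name": "A6",
   "kind": "crosstalk"
  },
  {
   "src": 4,
   "dst": 9,
   "fraction_name": "alpha6",
   "kind": "pathway"
  },
  {
   "src": 6,
   "dst": 9,
   "fraction_name": "unit",
   "kind": "pathway"
  },
  {
   "src": 6,
   "dst": 4,
   "fraction_name": "unit",
   "kind": "repression"
  },
  {
   "src": 7,
   "dst": 4,
   "fraction_name": "unit",
   "kind": "repression"
  }
 ],
 "splits": {
  "alpha1": 0.2,
  "alpha2": 0.2,
  "alpha3": 0.5,
  "alpha4": 0.5,
  "alpha5": 0.5,
  "alpha6": 0.5
 }
}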