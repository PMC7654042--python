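{
 "metabolites": [
  "A",
  "B"
 ],
 "reactions": [
  {
   "id": "R1",
   "lb": 0,
   "ub": null,
   "stoich": {
    "A": 1
   }
  },
  {
   "id": "R2",
   "lb": 0,
   "ub": null,
   "stoich": {
    "A": -1,
    "B": 1
   }
  },
  {
   "id": "R3",
   "lb": 0,
   "ub": null,
   "stoich": {
    "B": -1
   }
  }
 ],
 "target": [
  {
   "coeffs": {
    "R3": -1
   },
   "rhs": -1
  }
 ],
 "c": 1
}
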