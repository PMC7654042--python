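{
 "metabolites": [
  "A",
  "B",
  "C"
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
    "A": -1,
    "C": 1
   }
  },
  {
   "id": "R4",
   "lb": 0,
   "ub": null,
   "stoich": {
    "B": -1
   }
  },
  {
   "id": "R5",
   "lb": 0,
   "ub": null,
   "stoich": {
    "C": -1
   }
  }
 ],
 "target": [
  {
   "coeffs": {
    "R4": -1
   },
   "rhs": -1
  }
 ],
 "c": 1,
 "desired": [
  {
   "coeffs": {
    "R5": -1
   },
   "rhs": -1
  }
 ]
}
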