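{
 "metabolites": [
  "A",
  "B",
  "C",
  "D"
 ],
 "reactions": [
  {
   "id": "R1",
   "lb": 0,
   "ub": 10,
   "stoich": {
    "A": 1
   }
  },
  {
   "id": "R2",
   "lb": null,
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
    "B": -1,
    "C": 1
   }
  },
  {
   "id": "R4",
   "lb": 0,
   "ub": null,
   "stoich": {
    "A": -1,
    "C": 1
   }
  },
  {
   "id": "R5",
   "lb": null,
   "ub": null,
   "stoich": {
    "C": -1,
    "D": 1
   }
  },
  {
   "id": "R6",
   "lb": 0,
   "ub": null,
   "stoich": {
    "D": -1
   }
  },
  {
   "id": "R7",
   "lb": 0,
   "ub": null,
   "stoich": {
    "C": -1
   }
  },
  {
   "id": "R8",
   "lb": 0,
   "ub": null,
   "stoich": {
    "B": -1,
    "D": 1
   }
  },
  {
   "id": "R9",
   "lb": 0,
   "ub": null,
   "stoich": {
    "A": -1,
    "D": 1
   }
  },
  {
   "id": "R10",
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
    "R6": -1
   },
   "rhs": -1
  },
  {
   "coeffs": {
    "R6": -1,
    "R7": 1
   },
   "rhs": 0
  }
 ],
 "c": 1,
 "desired": [
  {
   "coeffs": {
    "R7": -1
   },
   "rhs": -1
  }
 ]
}
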