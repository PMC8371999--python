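{
  "version": "toy-0.1",
  "_comment": "Synthetic miniature lexical resource for tests and examples. Not an extract of WordNet: senses, links and information-content values are invented, chosen so the headache entry exercises synonym/hyponym/hypernym queries with distinct Resnik scores.",
  "taxonomy": {
    "entity.n.01": null,
    "state.n.01": "entity.n.01",
    "artifact.n.01": "entity.n.01",
    "pain.n.01": "state.n.01",
    "worry.n.01": "state.n.01",
    "concern.n.01": "state.n.01",
    "vexation.n.01": "state.n.01",
    "dead_weight.n.01": "worry.n.01",
    "burden.n.01": "worry.n.01",
    "fardel.n.01": "worry.n.01",
    "imposition.n.01": "worry.n.01",
    "bugaboo.n.01": "worry.n.01",
    "pill.n.01": "worry.n.01",
    "business.n.01": "worry.n.01",
    "car.n.01": "artifact.n.01",
    "jeep.n.01": "car.n.01"
  },
  "ic": {
    "entity.n.01": 0.0,
    "state.n.01": 0.9,
    "artifact.n.01": 1.0,
    "pain.n.01": 3.5,
    "worry.n.01": 4.0,
    "concern.n.01": 3.0,
    "vexation.n.01": 2.5,
    "dead_weight.n.01": 5.1,
    "burden.n.01": 4.6,
    "fardel.n.01": 5.3,
    "imposition.n.01": 4.8,
    "bugaboo.n.01": 5.5,
    "pill.n.01": 4.9,
    "business.n.01": 4.4,
    "car.n.01": 3.0,
    "jeep.n.01": 5.0
  },
  "lemmas": {
    "entity.n.01": ["entity"],
    "state.n.01": ["state"],
    "artifact.n.01": ["artifact"],
    "pain.n.01": ["headache", "cephalalgia"],
    "worry.n.01": ["headache", "worry"],
    "concern.n.01": ["headache", "concern"],
    "vexation.n.01": ["headache", "vexation"],
    "dead_weight.n.01": ["dead_weight"],
    "burden.n.01": ["burden"],
    "fardel.n.01": ["fardel"],
    "imposition.n.01": ["imposition"],
    "bugaboo.n.01": ["bugaboo"],
    "pill.n.01": ["pill"],
    "business.n.01": ["business"],
    "car.n.01": ["car", "auto", "automobile", "machine"],
    "jeep.n.01": ["jeep"]
  },
  "relations": {
    "pain.n.01": {"hyponyms": [], "hypernyms": ["state.n.01"]},
    "worry.n.01": {
      "hyponyms": [
        "dead_weight.n.01", "burden.n.01", "fardel.n.01", "imposition.n.01",
        "bugaboo.n.01", "pill.n.01", "business.n.01"
      ],
      "hypernyms": ["state.n.01"]
    },
    "concern.n.01": {"hyponyms": [], "hypernyms": ["state.n.01"]},
    "vexation.n.01": {"hyponyms": [], "hypernyms": ["state.n.01"]},
    "car.n.01": {"hyponyms": ["jeep.n.01"], "hypernyms": ["artifact.n.01"]},
    "jeep.n.01": {"hyponyms": [], "hypernyms": ["car.n.01"]}
  }
}
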