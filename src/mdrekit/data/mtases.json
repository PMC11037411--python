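{
  "Dam": {
    "name": "Dam",
    "pattern": "GATC",
    "marks": [
      {"strand": "top", "index": 1, "mod": "m6A"},
      {"strand": "bottom", "index": 2, "mod": "m6A"}
    ],
    "frequency_class": "site_specific"
  },
  "M.EcoGII": {
    "name": "M.EcoGII",
    "pattern": "A",
    "marks": [{"strand": "top", "index": 0, "mod": "m6A"}],
    "frequency_class": "frequent"
  },
  "M.Aba4572I": {
    "name": "M.Aba4572I",
    "pattern": "CGATCG",
    "marks": [
      {"strand": "top", "index": 2, "mod": "m6A"},
      {"strand": "bottom", "index": 3, "mod": "m6A"}
    ],
    "frequency_class": "site_specific"
  },
  "M.Eco57I": {
    "name": "M.Eco57I",
    "pattern": "CTGAAG",
    "marks": [{"strand": "top", "index": 4, "mod": "m6A"}],
    "frequency_class": "site_specific"
  },
  "M.EcoRI": {
    "name": "M.EcoRI",
    "pattern": "GAATTC",
    "marks": [
      {"strand": "top", "index": 2, "mod": "m6A"},
      {"strand": "bottom", "index": 3, "mod": "m6A"}
    ],
    "frequency_class": "site_specific"
  },
  "M.EcoEI": {
    "name": "M.EcoEI",
    "pattern": "GAGN7ATGC",
    "marks": [
      {"strand": "top", "index": 1, "mod": "m6A"},
      {"strand": "bottom", "index": 11, "mod": "m6A"}
    ],
    "frequency_class": "site_specific"
  },
  "M.EcoR124I": {
    "name": "M.EcoR124I",
    "pattern": "GAAN6RTCG",
    "marks": [
      {"strand": "top", "index": 2, "mod": "m6A"},
      {"strand": "bottom", "index": 10, "mod": "m6A"}
    ],
    "frequency_class": "site_specific"
  },
  "M.BamHI": {
    "name": "M.BamHI",
    "pattern": "GGATCC",
    "marks": [
      {"strand": "top", "index": 3, "mod": "m4C"},
      {"strand": "bottom", "index": 2, "mod": "m4C"}
    ],
    "frequency_class": "site_specific"
  },
  "M.Fnu4HI": {
    "name": "M.Fnu4HI",
    "pattern": "GCNGC",
    "marks": [
      {"strand": "top", "index": 1, "mod": "m5C"},
      {"strand": "bottom", "index": 3, "mod": "m5C"}
    ],
    "frequency_class": "site_specific"
  }
}
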