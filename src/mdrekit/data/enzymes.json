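{
  "DpnI": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "within_site", "top_cut_offset": 1, "bottom_cut_offset": 1},
    "response": {"full": "high", "hemi_top": "partial", "hemi_bottom": "partial", "none": "none"},
    "cofactor_note": "Mg2+"
  },
  "MboI": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "within_site", "top_cut_offset": -1, "bottom_cut_offset": 3},
    "response": {"full": "none", "hemi_top": "none", "hemi_bottom": "none", "none": "high"},
    "cofactor_note": "Mg2+"
  },
  "DpnII": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "within_site", "top_cut_offset": -1, "bottom_cut_offset": 3},
    "response": {"full": "none", "hemi_top": "none", "hemi_bottom": "none", "none": "high"},
    "cofactor_note": "Mg2+"
  },
  "Sau3AI": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "within_site", "top_cut_offset": -1, "bottom_cut_offset": 3},
    "response": {"full": "high", "hemi_top": "high", "hemi_bottom": "high", "none": "high"},
    "cofactor_note": "Mg2+; cleaves GATC regardless of m6A"
  },
  "BamHI": {
    "reader": "GGATCC:2:m6A",
    "mode": {"type": "within_site", "top_cut_offset": 0, "bottom_cut_offset": 4},
    "response": {"full": "high", "hemi_top": "high", "hemi_bottom": "high", "none": "high"},
    "cofactor_note": "Mg2+; not affected by Dam methylation"
  },
  "FcyTI": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "within_site", "top_cut_offset": 1, "bottom_cut_offset": 1},
    "response": {"full": "high", "hemi_top": "partial", "hemi_bottom": "partial", "none": "none"},
    "cofactor_note": "Mg2+; PD-(D/E)XK-wH, cleaves within Gm6A|TC"
  },
  "Psp4BI": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "within_site", "top_cut_offset": 1, "bottom_cut_offset": 1},
    "response": {"full": "high", "hemi_top": "partial", "hemi_bottom": "partial", "none": "none"},
    "cofactor_note": "Mg2+; PD-(D/E)XK-wH, heat-labile candidate"
  },
  "HhiV4I": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "distance_range", "min_nt": 1, "max_nt": 23, "side": "both"},
    "response": {"full": "high", "hemi_top": "partial", "hemi_bottom": "partial", "none": "partial"},
    "two_site": {"fast_spacer": [13, 27], "slow_spacers": [[8, 11], [43, 1000000]]},
    "cofactor_note": "Mn2+-dependent REase; distance range is a placeholder (vicinity of, not within, the site)"
  },
  "Ahi29725I": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "distance_range", "min_nt": 1, "max_nt": 23, "side": "both"},
    "response": {"full": "high", "hemi_top": "partial", "hemi_bottom": "partial", "none": "none"},
    "cofactor_note": "Mg2+/Mn2+; wH-GIY-YIG, cleaves G6mATC at N1-23"
  },
  "Apa233I": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "distance_range", "min_nt": 1, "max_nt": 23, "side": "both"},
    "response": {"full": "high", "hemi_top": "high", "hemi_bottom": "high", "none": "none"},
    "cofactor_note": "Mg2+/Mn2+; wH-GIY-YIG, cuts fully and hemi-modified oligos"
  },
  "HtuIII": {
    "reader": "GATC:1:m6A",
    "mode": {"type": "nicking", "strand": "top", "offset": -2, "pair_spacer": [5, 30]},
    "response": {"full": "partial", "hemi_top": "none", "hemi_bottom": "none", "none": "none"},
    "cofactor_note": "Mn2+/Co2+; PUA-wH-HNH, top-strand nick |NGm6ATC-N14-Gm6ATC"
  }
}
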