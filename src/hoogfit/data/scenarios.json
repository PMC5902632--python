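{
  "e12dna_free_10C_A3T10": {
    "spin_label": "A3C8",
    "p_b": 0.0024,
    "k_ex": 5411.0,
    "delta_omega": 3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 10.0,
    "annotation": "free E12DNA, A3-T10 Watson-Crick/Hoogsteen breathing",
    "nominal": ["r1", "r2"]
  },
  "echinomycin_bound_10C": {
    "spin_label": "A3C8",
    "p_b": 0.0207,
    "k_ex": 743.0,
    "delta_omega": 3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 10.0,
    "annotation": "DNA-echinomycin complex, A3-T10 flanking the CG binding step",
    "nominal": ["r1", "r2"]
  },
  "e12dna_free_25C_T6A7": {
    "spin_label": "A7C8",
    "p_b": 0.0087,
    "k_ex": 8089.0,
    "delta_omega": 3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 25.0,
    "annotation": "free E12DNA, tandem T6-A7 Watson-Crick/Hoogsteen breathing",
    "nominal": ["r1", "r2"]
  },
  "echinomycin_bound_25C_T6A7": {
    "spin_label": "A7C8",
    "p_b": 0.0337,
    "k_ex": 597.0,
    "delta_omega": -3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 25.0,
    "annotation": "DNA-echinomycin complex, tandem Hoogsteen bp exchanging toward transient Watson-Crick",
    "nominal": ["r1", "r2"]
  },
  "e12dna_free_10C_T10N3": {
    "spin_label": "T10N3",
    "p_b": 0.0024,
    "k_ex": 5411.0,
    "delta_omega": -2.0,
    "r1": 1.5,
    "r2": 15.0,
    "nucleus": "N15",
    "temperature": 10.0,
    "annotation": "free E12DNA, A3-T10 breathing seen from the thymine imino nitrogen",
    "nominal": ["r1", "r2"]
  },
  "acdna_free_T6A9": {
    "spin_label": "A9C8",
    "p_b": 0.0079,
    "k_ex": 3000.0,
    "delta_omega": 3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 25.0,
    "annotation": "free AcDNA, T6-A9 Watson-Crick/Hoogsteen breathing",
    "nominal": ["k_ex", "r1", "r2"]
  },
  "acdna_bound_T6A9_a": {
    "spin_label": "A9C8a",
    "p_b": 0.006,
    "k_ex": 3000.0,
    "delta_omega": 3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 25.0,
    "annotation": "DNA-actinomycin D complex, T6-A9 ('a' resonance set)",
    "nominal": ["k_ex", "r1", "r2"]
  },
  "acdna_bound_T6A9_b": {
    "spin_label": "A9C8b",
    "p_b": 0.0077,
    "k_ex": 3000.0,
    "delta_omega": 3.0,
    "r1": 2.5,
    "r2": 25.0,
    "nucleus": "C13",
    "temperature": 25.0,
    "annotation": "DNA-actinomycin D complex, T6-A9 ('b' resonance set)",
    "nominal": ["k_ex", "r1", "r2"]
  }
}
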