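{
  "comment": "Three-group amino acid partitions for the six physicochemical properties used by the composition/transition/distribution descriptors. These are the standard partitions of the SVM-Prot / PROFEAT descriptor lineage; override via PPConfig(groups_path=...) with a file of the same shape.",
  "properties": {
    "hydrophobicity": {
      "polar": "RKEDQN",
      "neutral": "GASTPHY",
      "hydrophobic": "CLVIMFW"
    },
    "vdw_volume": {
      "small": "GASTPDC",
      "medium": "NVEQIL",
      "large": "MHKFRYW"
    },
    "polarity": {
      "low": "LIFWCMVY",
      "medium": "PATGS",
      "high": "HQRKNED"
    },
    "polarizability": {
      "low": "GASDT",
      "medium": "CPNVEQIL",
      "high": "KMHFRYW"
    },
    "secondary_structure": {
      "helix": "EALMQKRH",
      "strand": "VIYCWFT",
      "coil": "GNPSD"
    },
    "solvent_accessibility": {
      "buried": "ALFCGIVW",
      "exposed": "RKQEND",
      "intermediate": "MSPTHY"
    }
  }
}
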