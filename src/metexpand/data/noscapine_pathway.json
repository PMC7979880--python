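{
  "name": "noscapine",
  "description": "Biosynthetic pathway from norcoclaurine to noscapine: 17 metabolites, 17 reactions, 11 generalized rule classes. Metabolite names omit the (S)- stereo prefixes used in the literature because the network treats stereoisomers as one compound; downstream intermediate identities follow the standard pathway naming, with the ring-chain tautomer of the deacetylation product represented in its cyclic hemiacetal form. The promiscuous esterase step (CXE1 acting on the 13-O-acetyl intermediate) is a documented reconstruction.",
  "metabolites": [
    "norcoclaurine",
    "coclaurine",
    "N-methylcoclaurine",
    "3'-hydroxy-N-methylcoclaurine",
    "reticuline",
    "scoulerine",
    "tetrahydrocolumbamine",
    "canadine",
    "N-methylcanadine",
    "1-hydroxy-N-methylcanadine",
    "1,13-dihydroxy-N-methylcanadine",
    "1-hydroxy-13-O-acetyl-N-methylcanadine",
    "1,8-dihydroxy-13-O-acetyl-N-methylcanadine",
    "4'-O-desmethyl-3-O-acetylpapaveroxine",
    "3-O-acetylpapaveroxine",
    "narcotine hemiacetal",
    "noscapine"
  ],
  "reactions": [
    {"substrate": "norcoclaurine", "product": "coclaurine", "rule": "omt-aromatic", "enzyme": "Ps6OMT"},
    {"substrate": "coclaurine", "product": "N-methylcoclaurine", "rule": "nmt-secondary", "enzyme": "PsCNMT"},
    {"substrate": "N-methylcoclaurine", "product": "3'-hydroxy-N-methylcoclaurine", "rule": "arom-hydroxylation", "enzyme": "CYP80B (NMCH)"},
    {"substrate": "3'-hydroxy-N-methylcoclaurine", "product": "reticuline", "rule": "omt-aromatic", "enzyme": "Ps4'OMT"},
    {"substrate": "reticuline", "product": "scoulerine", "rule": "bbe-bridge", "enzyme": "BBE"},
    {"substrate": "scoulerine", "product": "tetrahydrocolumbamine", "rule": "omt-aromatic", "enzyme": "PsS9OMT"},
    {"substrate": "tetrahydrocolumbamine", "product": "canadine", "rule": "methylenedioxy", "enzyme": "CAS (CYP719A)"},
    {"substrate": "canadine", "product": "N-methylcanadine", "rule": "nmt-quaternary", "enzyme": "TNMT"},
    {"substrate": "N-methylcanadine", "product": "1-hydroxy-N-methylcanadine", "rule": "arom-hydroxylation", "enzyme": "CYP82Y1"},
    {"substrate": "1-hydroxy-N-methylcanadine", "product": "1,13-dihydroxy-N-methylcanadine", "rule": "aliph-hydroxylation", "enzyme": "CYP82X2"},
    {"substrate": "1,13-dihydroxy-N-methylcanadine", "product": "1-hydroxy-13-O-acetyl-N-methylcanadine", "rule": "oat-acetyl", "enzyme": "AT1"},
    {"substrate": "1-hydroxy-13-O-acetyl-N-methylcanadine", "product": "1,8-dihydroxy-13-O-acetyl-N-methylcanadine", "rule": "aliph-hydroxylation", "enzyme": "CYP82X1"},
    {"substrate": "1,8-dihydroxy-13-O-acetyl-N-methylcanadine", "product": "4'-O-desmethyl-3-O-acetylpapaveroxine", "rule": "ring-opening", "enzyme": "spontaneous"},
    {"substrate": "4'-O-desmethyl-3-O-acetylpapaveroxine", "product": "3-O-acetylpapaveroxine", "rule": "omt-aromatic", "enzyme": "MT2/MT3"},
    {"substrate": "3-O-acetylpapaveroxine", "product": "narcotine hemiacetal", "rule": "est-hydrolysis", "enzyme": "CXE1"},
    {"substrate": "narcotine hemiacetal", "product": "noscapine", "rule": "alc-oxidation", "enzyme": "NOS (SDR)"},
    {"substrate": "1-hydroxy-13-O-acetyl-N-methylcanadine", "product": "1,13-dihydroxy-N-methylcanadine", "rule": "est-hydrolysis", "enzyme": "CXE1 (promiscuous)"}
  ]
}
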