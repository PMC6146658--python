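"""Per-family benchmark counts used as fixture inputs by the acceptance
suite and by ``scripts/acceptance.py``.

These are reference tallies for a five-family TF inventory in an
allopolyploid oilseed genome and its two diploid ancestors; the suite
feeds them through the summary operations and checks the aggregate
arithmetic.
"""

FAMILIES = ("AP2/EREBP", "bZIP", "MYB", "NAC", "WRKY")

#: identified genes per family in the focal (allopolyploid) species
FAMILY_SIZES = {
    "AP2/EREBP": 518,
    "bZIP": 252,
    "MYB": 721,
    "NAC": 398,
    "WRKY": 278,
}

#: per-family novel / conserved counts; the remainder is multi-copy
FOCAL_CATEGORY_COUNTS = {
    "AP2/EREBP": {"novel": 33, "conserved": 66},
    "bZIP": {"novel": 22, "conserved": 26},
    "MYB": {"novel": 65, "conserved": 54},
    "NAC": {"novel": 29, "conserved": 30},
    "WRKY": {"novel": 19, "conserved": 24},
}

#: ancestor genes with no focal counterpart, per ancestor species
LOST_COUNTS = {
    "B. rapa": {"AP2/EREBP": 12, "bZIP": 7, "MYB": 8, "NAC": 1, "WRKY": 2},
    "B. oleracea": {"AP2/EREBP": 14, "bZIP": 5, "MYB": 16, "NAC": 16, "WRKY": 4},
}

#: genes differentially expressed under >=1 treatment, per family
UNIQUE_DEGS = {
    "AP2/EREBP": 140,
    "bZIP": 75,
    "MYB": 141,
    "NAC": 68,
    "WRKY": 50,
}

#: crucial (stimulus-annotated) DEGs per family
CRUCIAL_TOTALS = {
    "AP2/EREBP": 93,
    "bZIP": 42,
    "MYB": 94,
    "NAC": 48,
    "WRKY": 38,
}

#: crucial DEGs responsive to each treatment, per family
CRUCIAL_PER_TREATMENT = {
    "cold": {"AP2/EREBP": 41, "bZIP": 11, "MYB": 39, "NAC": 22, "WRKY": 18},
    "heat": {"AP2/EREBP": 62, "bZIP": 32, "MYB": 61, "NAC": 40, "WRKY": 27},
    "drought": {"AP2/EREBP": 11, "bZIP": 2, "MYB": 9, "NAC": 4, "WRKY": 4},
    "salt": {"AP2/EREBP": 17, "bZIP": 7, "MYB": 9, "NAC": 5, "WRKY": 2},
    "ABA": {"AP2/EREBP": 9, "bZIP": 10, "MYB": 16, "NAC": 5, "WRKY": 6},
}
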