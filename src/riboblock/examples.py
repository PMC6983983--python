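"""A small worked example used throughout the documentation and tests.

``EXAMPLE_SEQUENCE`` is a 129-nt riboswitch-like sequence and
``EXAMPLE_BLOCK_MOTIFS`` a list of ten block motifs.  Running
block-location feature extraction on them demonstrates the conventions:
1-based first-occurrence locations, 0 for an absent block.
"""

EXAMPLE_SEQUENCE = (
    "CCGCAUUCUCAGGGCAGCGUGAAAUUCCCUACUGGCGGUCAAGCGCGCGAGCGUUUGUU"
    "AUAAGGCAAAUCAGCAGAUUUGGUGAAAUUCCAAAGCCAACAGUUACAGUCUGGAUGAAAGAGAGUAAAC"
)

EXAMPLE_BLOCK_MOTIFS = [
    "GGUUC", "CCC", "AAAAACUA", "GUGC", "UAUA",
    "UCUACC", "GGGC", "GGAUG", "GGG", "CUGAGA",
]

# first-occurrence locations of the ten motifs on the example sequence
EXAMPLE_OBSERVATION = [0, 27, 0, 0, 59, 0, 12, 112, 12, 0]
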