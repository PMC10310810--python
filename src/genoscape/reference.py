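"""Reference demographic counts used in worked examples and checks.

``APOE4_ALLELE_COUNTS`` tabulates, for each of the two landscape groups
of a published Japanese late-onset Alzheimer's discovery cohort
(1,947 cases / 2,192 cognitively normal controls), how many cases (LOAD)
and controls (CN) carry 0, 1 or 2 copies of the APOE epsilon-4 allele.
These counts are the input of the exact contingency-table examples:
comparing the LOAD rows of the two groups with the Fisher-Freeman-Halton
test, and deriving APOE4 carrier percentages per row.
"""

# group -> phenotype -> (n with 0 alleles, n with 1, n with 2)
APOE4_ALLELE_COUNTS = {
    1: {"load": (457, 383, 78), "cn": (678, 206, 11)},
    2: {"load": (674, 311, 44), "cn": (1112, 179, 6)},
}
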