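"""Previously described rhodococcal alkB loci with printed genomic contexts.

Each entry is an ordered product-string context around a focal alkB gene
("*" marks the focal position) for an alkane monooxygenase characterized in
earlier work, together with the revised type the context-based rules should
assign.  The two partial-cluster (AlkB2) loci are embedded in the conserved
manA-ahcY region that hosts every known partial cluster; the remaining
contexts are used exactly as printed.  These serve as a concordance surface
for the typing rules.
"""

from __future__ import annotations

_RUBA = "rubredoxin"
_RUBB = "rubredoxin reductase"
_ALKU = "TetR family transcriptional regulator AlkU"
_MANA = "mannose-6-phosphate isomerase"
_AHCY = "adenosylhomocysteinase"

#: (locus id, strain, ordered products with "*" focal, expected revised type)
KNOWN_CONTEXTS: list[tuple[str, str, list[str], str]] = [
    (
        "CAB51053",
        "R. erythropolis NRRL B-16531",
        ["*", _RUBA, _RUBA, _RUBB, _ALKU],
        "AlkB1",
    ),
    (
        "CAC37038",
        "R. erythropolis NRRL B-16531",
        [_MANA, "cationic transporter", "*", _RUBA, _RUBA, _ALKU, _AHCY],
        "AlkB2",
    ),
    (
        "CAC40954",
        "R. erythropolis NRRL B-16531",
        ["*", "glutamil t-RNA synthetase"],
        "AlkB4",
    ),
    (
        "ACX30747",
        "R. ruber SP2B",
        ["*", _RUBA, _RUBA, _RUBB],
        "AlkB1",
    ),
    (
        "WP_241385946",
        "Rhodococcus sp. CH91",
        [_MANA, "*", _RUBA, _RUBA, "TetR family transcriptional regulator", _AHCY],
        "AlkB2",
    ),
    (
        "WP_241384812",
        "Rhodococcus sp. CH91",
        ["aminotransferase", "cold-shock protein", "*", "AbiEi family antitoxin domain-containing protein"],
        "AlkB5",
    ),
    (
        "AMY23060",
        "R. fascians PBTS 2",
        ["alpha/beta hydrolase", "*", "ATP-binding protein"],
        "AlkB7",
    ),
    (
        "AYJ49258",
        "Rhodococcus sp. PI Y",
        [_MANA, "*", _AHCY],
        "AlkB0",
    ),
]
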