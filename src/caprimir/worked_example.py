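"""Published summary statistics used as worked examples.

Counts from a two-library (dry period ``D`` vs peak lactation ``P``) dairy
goat mammary-gland small-RNA sequencing study; used by the examples, the
regression tests and the acceptance script as *inputs* — every derived number
(normalized expression, fold change, p-value) is recomputed by this package
at run time.
"""

from __future__ import annotations

__all__ = [
    "RAW_READS",
    "CLEAN_READS",
    "UNIQUE_TAGS",
    "DE_COUNTS",
    "PUBLISHED_LOG2FC",
    "PUBLISHED_NE",
    "PUBLISHED_PVALUES",
]

#: raw and clean read totals per library
RAW_READS = {"D": 15_706_825, "P": 17_349_265}
CLEAN_READS = {"D": 14_851_375, "P": 15_712_891}
UNIQUE_TAGS = {"D": 788_915, "P": 1_108_514}

#: raw counts (D, P) of the 15 highly abundant differentially expressed
#: miRNAs reported by the study
DE_COUNTS = {
    "miR-2887": (385, 1671),
    "miR-451": (749, 1665),
    "miR-2478": (869, 1888),
    "miR-199b": (1565, 290),
    "miR-128": (8512, 1408),
    "miR-25": (36578, 5728),
    "miR-145": (41213, 6254),
    "miR-98": (2531, 370),
    "miR-222": (5223, 734),
    "miR-181b": (5330, 734),
    "miR-199a-3p": (152691, 20829),
    "miR-93": (3593, 460),
    "miR-221": (7848, 790),
    "let-7b": (443620, 32993),
    "let-7c": (341112, 27377),
}

#: published normalized expressions (per million clean reads) for miR-2887
PUBLISHED_NE = {"miR-2887": (25.9235, 106.3458)}

#: published log2 fold changes (P-NE / D-NE), 4-decimal rounding
PUBLISHED_LOG2FC = {
    "miR-2887": 2.0364,
    "miR-451": 1.0711,
    "miR-2478": 1.0381,
    "miR-199b": -2.5134,
    "miR-128": -2.6772,
    "miR-25": -2.7563,
    "miR-145": -2.8016,
    "miR-98": -2.8555,
    "miR-222": -2.9124,
    "miR-181b": -2.9416,
    "miR-199a-3p": -2.9553,
    "miR-93": -3.0468,
    "miR-221": -3.3938,
    "let-7b": -3.8304,
    "let-7c": -3.7206,
}

#: published p-values; 0.0 means "printed as 0" (below double precision)
PUBLISHED_PVALUES = {
    "miR-2887": 4.3e-175,
    "miR-451": 1.25e-68,
    "miR-2478": 8.41e-74,
    "miR-199b": 3e-227,
    "miR-128": 0.0,
    "miR-25": 0.0,
    "miR-145": 0.0,
    "miR-98": 0.0,
    "miR-222": 0.0,
    "miR-181b": 0.0,
    "miR-199a-3p": 0.0,
    "miR-93": 0.0,
    "miR-221": 0.0,
    "let-7b": 0.0,
    "let-7c": 0.0,
}

#: a reference let-7a mature sequence (worked example for A+U content: 14/22)
LET7A_MATURE = "ugagguaguagguuguauaguu"
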