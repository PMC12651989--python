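"""Published reference values for the *H. manillensis* decorsin study.

These constants live in the report layer only: library code never reads
them, so enumeration and geometry results are always computed, and the
reports compare computed values against these figures with explicit
agreement flags.  Disagreement is a finding, not an error.
"""

from __future__ import annotations

#: Published cluster total lengths (bp), keyed by (genome source, cluster).
TABLE1_SPAN: dict[tuple[str, str], int] = {
    ("guan", "decorsin"): 18_901,
    ("guan", "hirudin"): 17_950,
    ("zheng", "decorsin"): 19_219,
    ("zheng", "hirudin"): 16_069,
    ("liu", "decorsin"): 17_149,
    ("liu", "hirudin"): 13_634,
}

#: Published decorsin-to-hirudin cluster gaps (bp) per genome source.
#: These three figures are mutually inconsistent under any single
#: convention derivable from the published coordinates.
TABLE1_GAP: dict[str, int] = {
    "guan": 140_046,
    "zheng": 121_121,
    "liu": 133_389,
}

#: Published skip-only multimericity census for the Hman_DV3 gene
#: (k repeats -> number of factors).  Exhaustive enumeration under the
#: stated parity junction rule reproduces k = 1, 2, 5, 6 but not
#: k = 3, 4 (closed form C(6+k, 2k) gives 84 and 45).
DV3_SKIP_CENSUS: dict[int, int] = {1: 21, 2: 70, 3: 61, 4: 32, 5: 11, 6: 1}

#: Published total number of factors with >= 1 repeat (skip only).
DV3_TOTAL: int = 196

#: Published motif census for the Hman_DV3 factors: number carrying two
#: RGD/KGD motifs, number carrying at least one, and the resulting
#: total of putative decorsins.
DV3_MOTIF_TWO: int = 27
DV3_MOTIF_AT_LEAST_ONE: int = 99
DV3_DECORSIN_TOTAL: int = 126

#: Multimericity classes treated as reproduction targets (the others
#: are covered by the closed-form/brute-force enumeration oracle).
DV3_TARGET_CLASSES: tuple[int, ...] = (1, 2, 5, 6)

#: Published monomeric motif-bearing variant counts per multimeric gene.
MONOMER_COUNTS: dict[str, int] = {
    "Hman_DV1": 1,
    "Hman_DV2": 5,
    "Hman_DV3": 8,
    "Hman_DV5": 2,
}

#: Published names of the sixteen deduced monomeric variants.
MONOMER_NAMES: tuple[str, ...] = (
    "Hman_DV1s",
    "Hman_DV2s-1",
    "Hman_DV2s-2",
    "Hman_DV2s-3",
    "Hman_DV2s-4",
    "Hman_DV2s-5",
    "Hman_DV3s-1a",
    "Hman_DV3s-1b",
    "Hman_DV3s-2a",
    "Hman_DV3s-2b",
    "Hman_DV3s-3a",
    "Hman_DV3s-3b",
    "Hman_DV3s-4a",
    "Hman_DV3s-4b",
    "Hman_DV5sa",
    "Hman_DV5sb",
)
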