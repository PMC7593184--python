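"""Shared constants: haplotype, nuclear-background and gene naming.

The three mitochondrial haplotypes (BRA, CAL, YEM) and the three outbred
nuclear backgrounds (Brazil, California, Yemen) follow the seed-beetle
introgression-line system in which each haplotype has a native nuclear
background. Animal mitogenomes carry 13 protein-coding genes (PCGs).
"""

from __future__ import annotations

HAPLOTYPES: tuple[str, str, str] = ("BRA", "CAL", "YEM")

NUCLEAR_BACKGROUNDS: tuple[str, str, str] = ("Brazil", "California", "Yemen")

#: native (coevolved) haplotype of each nuclear background
NATIVE_HAPLOTYPE: dict[str, str] = {
    "Brazil": "BRA",
    "California": "CAL",
    "Yemen": "YEM",
}

THERMAL_REGIMES: tuple[str, str] = ("23C", "35C")

#: generations of experimental evolution elapsed under each thermal regime
GENERATIONS_BY_REGIME: dict[str, int] = {"35C": 36, "23C": 23}

#: the 13 mitochondrial protein-coding genes, alphabetical
PCG_NAMES: tuple[str, ...] = (
    "atp6",
    "atp8",
    "cob",
    "cox1",
    "cox2",
    "cox3",
    "nad1",
    "nad2",
    "nad3",
    "nad4",
    "nad4l",
    "nad5",
    "nad6",
)

#: NCBI genetic code for invertebrate mitochondria
INVERTEBRATE_MITO_TABLE = 5
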