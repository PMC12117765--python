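"""Canonical COG/KOG single-letter functional categories.

Each letter maps to (name, broad class). The four broad classes follow the
original COG/KOG classification; "Mobilome" (X) was added with COG2014 and is
emitted by eggNOG-mapper.
"""

from __future__ import annotations

KOG_LETTERS: dict[str, tuple[str, str]] = {
    # Information storage and processing
    "J": ("Translation, ribosomal structure and biogenesis", "Information storage and processing"),
    "A": ("RNA processing and modification", "Information storage and processing"),
    "K": ("Transcription", "Information storage and processing"),
    "L": ("Replication, recombination and repair", "Information storage and processing"),
    "B": ("Chromatin structure and dynamics", "Information storage and processing"),
    # Cellular processes and signaling
    "D": ("Cell cycle control, cell division, chromosome partitioning", "Cellular processes and signaling"),
    "Y": ("Nuclear structure", "Cellular processes and signaling"),
    "V": ("Defense mechanisms", "Cellular processes and signaling"),
    "T": ("Signal transduction mechanisms", "Cellular processes and signaling"),
    "M": ("Cell wall/membrane/envelope biogenesis", "Cellular processes and signaling"),
    "N": ("Cell motility", "Cellular processes and signaling"),
    "Z": ("Cytoskeleton", "Cellular processes and signaling"),
    "W": ("Extracellular structures", "Cellular processes and signaling"),
    "U": ("Intracellular trafficking, secretion, and vesicular transport", "Cellular processes and signaling"),
    "O": ("Posttranslational modification, protein turnover, chaperones", "Cellular processes and signaling"),
    # Metabolism
    "C": ("Energy production and conversion", "Metabolism"),
    "G": ("Carbohydrate transport and metabolism", "Metabolism"),
    "E": ("Amino acid transport and metabolism", "Metabolism"),
    "F": ("Nucleotide transport and metabolism", "Metabolism"),
    "H": ("Coenzyme transport and metabolism", "Metabolism"),
    "I": ("Lipid transport and metabolism", "Metabolism"),
    "P": ("Inorganic ion transport and metabolism", "Metabolism"),
    "Q": ("Secondary metabolites biosynthesis, transport and catabolism", "Metabolism"),
    # Mobilome / poorly characterized
    "X": ("Mobilome: prophages, transposons", "Mobilome"),
    "R": ("General function prediction only", "Poorly characterized"),
    "S": ("Function unknown", "Poorly characterized"),
}


def letter_name(letter: str) -> str:
    """Human-readable name for a KOG letter (falls back to the letter itself)."""
    entry = KOG_LETTERS.get(letter)
    return entry[0] if entry else letter


def letter_class(letter: str) -> str | None:
    """Broad functional class for a KOG letter, or None if unknown."""
    entry = KOG_LETTERS.get(letter)
    return entry[1] if entry else None
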