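"""Small shared sequence helpers (thin wrappers over Biopython)."""

from __future__ import annotations

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: the 61 sense codons, lexicographic
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement, case-preserving (lowercase tails stay lowercase)."""
    return str(Seq(seq).reverse_complement())


def translate(nt: str) -> str:
    """Standard-code translation; stop codons rendered as ``*``.

    Raises ValueError for length not a multiple of 3 or non-ACGT letters.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    if not set(nt) <= DNA_ALPHABET:
        bad = sorted(set(nt) - DNA_ALPHABET)
        raise ValueError(f"non-ACGT letters in sequence: {bad}")
    return str(Seq(nt).translate())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng, length: int, forbidden: tuple[str, ...] = ()) -> str:
    """Uniform random DNA, rejection-sampled to exclude ``forbidden`` motifs."""
    bases = "ACGT"
    while True:
        seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if not any(m in seq for m in forbidden):
            return seq


def random_codons(rng, n: int, forbidden: tuple[str, ...] = ()) -> str:
    """``n`` random sense codons (stop-free ORF filler), motif-rejected."""
    while True:
        seq = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n))
        if not any(m in seq for m in forbidden):
            return seq
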