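"""Degenerate-primer in-silico PCR and consensus CRISPR guide discovery.

Supports the HLA side of the platform: cloning HLA class I loci from
cDNA with locus-specific degenerate primer pairs (each primer carries a
lowercase 5' Gibson-homology tail and an uppercase locus-specific
annealing portion), and finding SpCas9 protospacers shared by every
allele of a locus set, so a single guide can disrupt all classical HLA
class I genes at once.

Annealing requires an exact IUPAC-compatible match of the full uppercase
portion; tails never anneal.  There is no mismatch model — exactness
keeps every amplicon auditable against a brute-force expansion oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from ._seq import IUPAC_SETS, revcomp

MAX_EXPANSION_LEN = 30
DEFAULT_PROTO_LEN = 19
DEFAULT_PAM = "NGG"


class HlaToolsError(Exception):
    pass


@dataclass(frozen=True)
class Primer:
    """A PCR primer with case-encoded structure: lowercase 5' tail
    (Gibson overlap, never anneals) + uppercase annealing portion."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise HlaToolsError(f"{self.name}: empty primer")
        bad = set(self.sequence.upper()) - set(IUPAC_SETS)
        if bad:
            raise HlaToolsError(f"{self.name}: illegal letters {sorted(bad)}")
        if not self.annealing or not self.annealing.isupper():
            raise HlaToolsError(
                f"{self.name}: lowercase tail must precede an all-uppercase "
                "annealing portion"
            )
        if len(self.annealing) < 15:
            raise HlaToolsError(f"{self.name}: annealing portion under 15 nt")

    @property
    def tail(self) -> str:
        i = 0
        while i < len(self.sequence) and self.sequence[i].islower():
            i += 1
        return self.sequence[:i]

    @property
    def annealing(self) -> str:
        return self.sequence[len(self.tail):]


def _matches_at(pattern: str, text: str, pos: int) -> bool:
    return all(text[pos + i] in IUPAC_SETS[p] for i, p in enumerate(pattern))


def iupac_matches(pattern: str, text: str) -> list[tuple[int, str]]:
    """All (0-based position, strand) where an IUPAC pattern matches.

    Minus-strand hits are reported at the leftmost base of the matched
    window in forward-text coordinates.
    """
    if not pattern:
        raise HlaToolsError("empty pattern")
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC_SETS)
    if bad:
        raise HlaToolsError(f"illegal IUPAC letters {sorted(bad)}")
    text = text.upper()
    hits = []
    rc_pattern = "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))
    n, m = len(text), len(pattern)
    for i in range(n - m + 1):
        if _matches_at(pattern, text, i):
            hits.append((i, "+"))
        if _matches_at(rc_pattern, text, i):
            hits.append((i, "-"))
    return hits


_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def expand_degenerate(pattern: str) -> list[str]:
    """All concrete expansions of an IUPAC pattern, lexicographic."""
    pattern = pattern.upper()
    if len(pattern) > MAX_EXPANSION_LEN:
        raise HlaToolsError(
            f"pattern length {len(pattern)} exceeds expansion guard {MAX_EXPANSION_LEN}"
        )
    bad = set(pattern) - set(IUPAC_SETS)
    if bad:
        raise HlaToolsError(f"illegal IUPAC letters {sorted(bad)}")
    pools = [sorted(IUPAC_SETS[c]) for c in pattern]
    return ["".join(p) for p in itertools.product(*pools)]


@dataclass(frozen=True)
class Amplicon:
    sequence: str  # full product, primer tails included (case preserved)
    start: int     # leftmost template coordinate covered by the fwd primer
    end: int       # rightmost template coordinate covered by the rev primer

    def __len__(self) -> int:
        return len(self.sequence)


def in_silico_pcr(
    template: str, fwd: Primer, rev: Primer, max_product: int = 10000
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    One amplicon per (forward plus-strand hit, reverse minus-strand hit)
    pair with the forward site upstream and product size within
    ``max_product``.  Product sequences incorporate the full primers, so
    lowercase Gibson tails appear at both ends, ready for assembly into a
    linearized vector.
    """
    template = template.upper()
    fwd_hits = [i for i, s in iupac_matches(fwd.annealing, template) if s == "+"]
    rev_hits = [i for i, s in iupac_matches(rev.annealing, template) if s == "-"]
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            left_inner = f + len(fwd.annealing)
            if left_inner > r:
                continue  # reverse site upstream of (or overlapping) forward
            end = r + len(rev.annealing)
            middle = template[left_inner: r]
            seq = fwd.sequence + middle + revcomp(rev.sequence)
            if len(seq) <= max_product:
                products.append(Amplicon(sequence=seq, start=f, end=end))
    return products


@dataclass(frozen=True)
class GuideHit:
    """A protospacer+PAM present in every input template."""

    protospacer: str
    pam: str
    positions: tuple[tuple[int, str], ...]  # per-template (position, strand)

    @property
    def site(self) -> str:
        return self.protospacer + self.pam


def find_consensus_guides(
    templates: list[str],
    proto_len: int = DEFAULT_PROTO_LEN,
    pam: str = DEFAULT_PAM,
) -> list[GuideHit]:
    """Protospacers (either strand, immediately followed by a PAM match)
    shared by every template; sorted by position in template 1."""
    if len(templates) < 2:
        raise HlaToolsError("consensus search needs at least 2 templates")
    if not 17 <= proto_len <= 23:
        raise HlaToolsError("proto_len must be within [17, 23]")
    templates = [t.upper() for t in templates]
    site_len = proto_len + len(pam)

    def sites(text: str) -> dict[str, tuple[int, str]]:
        found: dict[str, tuple[int, str]] = {}
        for strand, s in (("+", text), ("-", revcomp(text))):
            for i in range(len(s) - site_len + 1):
                window = s[i: i + site_len]
                if _matches_at(pam, window, proto_len):
                    pos = i if strand == "+" else len(s) - i - site_len
                    found.setdefault(window, (pos, strand))
        return found

    first = sites(templates[0])
    rest = [sites(t) for t in templates[1:]]
    hits = []
    for window, (pos, strand) in first.items():
        if all(window in other for other in rest):
            hits.append(
                GuideHit(
                    protospacer=window[:proto_len],
                    pam=window[proto_len:],
                    positions=tuple(
                        [(pos, strand)] + [other[window] for other in rest]
                    ),
                )
            )
    hits.sort(key=lambda h: (h.positions[0][0], h.positions[0][1], h.site))
    return hits


# ---------------------------------------------------------------------------
# primer table I/O

PRIMER_COLUMNS = ["name", "sequence"]


def read_primers(path) -> dict[str, Primer]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row["name"]: Primer(row["name"], row["sequence"]) for row in df.to_dict("records")}


def write_guide_hits(hits: list[GuideHit], path) -> None:
    pd.DataFrame(
        [
            {
                "protospacer": h.protospacer,
                "pam": h.pam,
                "template1_pos": h.positions[0][0],
                "template1_strand": h.positions[0][1],
            }
            for h in hits
        ],
        columns=["protospacer", "pam", "template1_pos", "template1_strand"],
    ).to_csv(path, sep="\t", index=False)
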