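"""Germline TCR gene segments and backbone plasmid libraries.

The toolkit never downloads real germline data.  Instead it carries a
deterministic generator (:func:`make_fixture_library`) that produces, for
every V/J/C gene named in the packaged CMV clonotype table, a *synthetic*
germline segment with valid CDR3 anchors, plus one backbone plasmid per V
gene: a TRAV--TRBC2 vector and a TRAC--furin-SGSG-P2A--TRBV insert
plasmid, both designed to be linearized by the blunt cutters EcoRV and
FspI.  Users with real germline FASTA (e.g. IMGT exports) can load it
through :func:`load_segments` with the same annotation sidecar.

Anchor convention: for V segments ``anchor`` is the 0-based index of the
first base of the conserved cysteine codon; for J segments, of the
conserved phenylalanine/tryptophan codon.  CDR3 junctions are
anchor-inclusive on both sides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA_ALPHABET, random_codons, random_dna, translate
from .gibson_engine import ECORV, FSPI, DnaFragment, digest

DEFAULT_ALLELE = "01"

#: motifs that must stay unique in backbone plasmids (linearization sites)
_FORBIDDEN = (ECORV.site, FSPI.site)

# in-frame cloning elements (fixed nucleotide spellings, configurable via
# BackboneLibrary.elements)
FURIN_NT = "CGGGCCAAGAGG"  # RAKR
SGSG_NT = "TCTGGATCTGGA"  # SGSG
P2A_NT = "GCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
JUNCTION_PEPTIDE = "RAKRSGSGATNFSLLKQAGDVEENPGP"  # furin-SGSG-P2A


class GermlineError(Exception):
    pass


class SegmentClass(str, Enum):
    V_ALPHA = "V_alpha"
    J_ALPHA = "J_alpha"
    V_BETA = "V_beta"
    J_BETA = "J_beta"
    C_ALPHA = "C_alpha"
    C_BETA = "C_beta"

    @property
    def chain(self) -> str:
        return "alpha" if self.value.endswith("alpha") else "beta"

    @property
    def kind(self) -> str:
        return self.value[0]  # 'V', 'J' or 'C'


@dataclass(frozen=True)
class GeneSegment:
    """One germline gene segment with CDR3-anchor annotation."""

    name: str
    segment_class: SegmentClass
    sequence: str
    anchor: int = 0
    frame_offset: int = 0
    allele: str = DEFAULT_ALLELE

    def __post_init__(self):
        if not self.sequence:
            raise GermlineError(f"{self.key}: empty sequence")
        if self.sequence != self.sequence.upper() or not set(self.sequence) <= DNA_ALPHABET:
            raise GermlineError(f"{self.key}: sequence must be uppercase ACGT")
        if not 0 <= self.anchor < len(self.sequence):
            raise GermlineError(f"{self.key}: anchor {self.anchor} outside sequence")
        if self.anchor % 3 != self.frame_offset % 3:
            raise GermlineError(
                f"{self.key}: anchor {self.anchor} inconsistent with "
                f"frame_offset {self.frame_offset}"
            )
        aa = self.anchor_residue
        if self.segment_class.kind == "V" and aa != "C":
            raise GermlineError(f"{self.key}: V anchor codon translates to {aa}, not C")
        if self.segment_class.kind == "J" and aa not in ("F", "W"):
            raise GermlineError(f"{self.key}: J anchor codon translates to {aa}, not F/W")

    @property
    def key(self) -> str:
        return f"{self.name}*{self.allele}"

    @property
    def anchor_residue(self) -> str:
        codon = self.sequence[self.anchor: self.anchor + 3]
        return translate(codon) if len(codon) == 3 else "?"

    @property
    def pre_anchor(self) -> str:
        """Sequence upstream of the anchor codon (excluded from the CDR3)."""
        return self.sequence[: self.anchor]

    @property
    def post_anchor(self) -> str:
        """Sequence downstream of the anchor codon (the J 'remainder')."""
        return self.sequence[self.anchor + 3:]


class SegmentSet:
    """Collection of :class:`GeneSegment`, indexed by gene name and key."""

    def __init__(self, segments: list[GeneSegment]):
        self.segments = list(segments)
        self.by_key: dict[str, GeneSegment] = {}
        for seg in segments:
            if seg.key in self.by_key:
                raise GermlineError(f"duplicate gene*allele key {seg.key}")
            self.by_key[seg.key] = seg
        self.by_name = {seg.name: seg for seg in segments}

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def get(self, name: str) -> GeneSegment:
        gene, allele = normalize_gene_name(name)
        seg = self.by_key.get(f"{gene}*{allele}") or self.by_name.get(gene)
        if seg is None:
            raise GermlineError(f"unknown gene segment {name!r}")
        return seg

    def of_class(self, cls: SegmentClass) -> list[GeneSegment]:
        return [s for s in self.segments if s.segment_class is cls]

    def v_segments(self, chain: str) -> list[GeneSegment]:
        cls = SegmentClass.V_ALPHA if chain == "alpha" else SegmentClass.V_BETA
        return self.of_class(cls)

    def j_segments(self, chain: str) -> list[GeneSegment]:
        cls = SegmentClass.J_ALPHA if chain == "alpha" else SegmentClass.J_BETA
        return self.of_class(cls)

    def c_segment(self, chain: str) -> GeneSegment:
        cls = SegmentClass.C_ALPHA if chain == "alpha" else SegmentClass.C_BETA
        return self.of_class(cls)[0]


_GENE_RE = re.compile(r"^[A-Z]{2,}(?:[0-9][0-9A-Z-]*)?$")


def normalize_gene_name(raw: str) -> tuple[str, str]:
    """Normalize a TCR gene token to ``(gene, allele)``.

    Reconciles typesetting variants such as ``TRAV*3*01`` (stray asterisk
    before the gene number) with ``TRAV3*01``.  A trailing two-digit
    ``*NN`` token is split off as the allele, defaulting to ``01``.
    """
    token = raw.strip()
    if not token:
        raise GermlineError("empty gene name")
    parts = token.split("*")
    allele = DEFAULT_ALLELE
    if len(parts) > 1 and re.fullmatch(r"\d{2}", parts[-1]):
        allele = parts[-1]
        parts = parts[:-1]
    gene = "".join(parts)
    if not _GENE_RE.match(gene):
        raise GermlineError(f"unparseable gene name {raw!r}")
    return gene, allele


# ---------------------------------------------------------------------------
# FASTA + annotation sidecar I/O

ANNOTATION_COLUMNS = ["gene", "allele", "class", "anchor", "frame_offset"]


def load_segments(fasta_path, annotation_path) -> SegmentSet:
    """Load gene segments from FASTA plus a TSV annotation sidecar.

    FASTA headers carry ``GENE*ALLELE``; the sidecar supplies segment
    class, anchor and frame offset per record.  Records with missing
    annotation raise immediately; anchor-codon violations are aggregated
    into a single error listing every offender.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise GermlineError(f"annotation sidecar missing columns {sorted(missing_cols)}")
    ann_index = {
        (row["gene"], row["allele"]): row for row in ann.to_dict("records")
    }

    segments: list[GeneSegment] = []
    offenders: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene, allele = normalize_gene_name(rec.id)
        key = f"{gene}*{allele}"
        if key in seen:
            raise GermlineError(f"duplicate gene*allele key {key}")
        seen.add(key)
        row = ann_index.get((gene, allele))
        if row is None:
            raise GermlineError(f"missing anchor annotation for record {rec.id!r}")
        try:
            segments.append(
                GeneSegment(
                    name=gene,
                    allele=allele,
                    segment_class=SegmentClass(row["class"]),
                    sequence=str(rec.seq).upper(),
                    anchor=int(row["anchor"]),
                    frame_offset=int(row["frame_offset"]),
                )
            )
        except GermlineError as exc:
            offenders.append(str(exc))
    if offenders:
        raise GermlineError("anchor validation failed: " + "; ".join(offenders))
    return SegmentSet(segments)


def write_segments(segments: SegmentSet, fasta_path, annotation_path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.key, description="") for s in segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "gene": s.name,
                "allele": s.allele,
                "class": s.segment_class.value,
                "anchor": s.anchor,
                "frame_offset": s.frame_offset,
            }
            for s in segments
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Backbone plasmids


@dataclass(frozen=True)
class Feature:
    """GenBank-style feature: 0-based half-open interval on the top strand."""

    name: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class AnnotatedPlasmid:
    fragment: DnaFragment
    features: tuple[Feature, ...]

    @property
    def sequence(self) -> str:
        return self.fragment.sequence


@dataclass(frozen=True)
class BackboneLibrary:
    """Per-V-gene backbone plasmids plus the shared cloning elements."""

    trav_trbc2: dict[str, AnnotatedPlasmid]
    trac_trbv: dict[str, AnnotatedPlasmid]
    elements: dict[str, str]

    def validate(self) -> None:
        for kind, plasmids in (("TRAV-TRBC2", self.trav_trbc2), ("TRAC-TRBV", self.trac_trbv)):
            for gene, plasmid in plasmids.items():
                if plasmid.fragment.topology != "circular":
                    raise GermlineError(f"{kind} plasmid for {gene} is not circular")
                for enz in (ECORV, FSPI):
                    n = len(digest(plasmid.fragment, [enz]))
                    if n != 1:
                        raise GermlineError(
                            f"{kind} plasmid for {gene}: {n} {enz.name} sites, expected 1"
                        )
                spans = sorted((f.start, f.end) for f in plasmid.features)
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    if s2 < e1:
                        raise GermlineError(f"{kind} plasmid for {gene}: overlapping features")


# Genes used by the packaged CMV clonotype table; J genes map to the anchor
# codon observed in their junctions (TTC for TRBJ1-2 / TRBJ2-7, else TTT).
TABLE_TRAV = ("TRAV3", "TRAV25", "TRAV35", "TRAV26-2", "TRAV24")
TABLE_TRAJ = {
    "TRAJ26": "TTT", "TRAJ39": "TTT", "TRAJ31": "TTT", "TRAJ50": "TTT",
    "TRAJ49": "TTT", "TRAJ47": "TTT", "TRAJ43": "TTT",
}
TABLE_TRBV = ("TRBV28", "TRBV12-3", "TRBV29-1", "TRBV16", "TRBV27")
TABLE_TRBJ = {
    "TRBJ1-1": "TTT", "TRBJ2-3": "TTT", "TRBJ1-2": "TTC",
    "TRBJ2-2": "TTT", "TRBJ2-7": "TTC",
}

V_PRE_ANCHOR_CODONS = 20   # ATG + 19 codons upstream of the anchor Cys
J_POST_ANCHOR_CODONS = 10  # J remainder carried into reads and constructs
C_CODONS = 30


def _make_v(rng, name: str, cls: SegmentClass) -> GeneSegment:
    while True:
        seq = "ATG" + random_codons(rng, V_PRE_ANCHOR_CODONS - 1, _FORBIDDEN) + "TGT"
        if not any(m in seq for m in _FORBIDDEN):
            return GeneSegment(name, cls, seq, anchor=len(seq) - 3, frame_offset=0)


def _make_j(rng, name: str, cls: SegmentClass, anchor_codon: str) -> GeneSegment:
    while True:
        seq = anchor_codon + random_codons(rng, J_POST_ANCHOR_CODONS, _FORBIDDEN)
        if not any(m in seq for m in _FORBIDDEN):
            return GeneSegment(name, cls, seq, anchor=0, frame_offset=0)


def make_fixture_segments(seed: int) -> SegmentSet:
    """Deterministic synthetic germline covering the packaged CMV genes."""
    rng = np.random.default_rng(seed)
    segs: list[GeneSegment] = []
    for name in TABLE_TRAV:
        segs.append(_make_v(rng, name, SegmentClass.V_ALPHA))
    for name, codon in TABLE_TRAJ.items():
        segs.append(_make_j(rng, name, SegmentClass.J_ALPHA, codon))
    for name in TABLE_TRBV:
        segs.append(_make_v(rng, name, SegmentClass.V_BETA))
    for name, codon in TABLE_TRBJ.items():
        segs.append(_make_j(rng, name, SegmentClass.J_BETA, codon))
    segs.append(
        GeneSegment("TRAC", SegmentClass.C_ALPHA, random_codons(rng, C_CODONS, _FORBIDDEN))
    )
    segs.append(
        GeneSegment(
            "TRBC2", SegmentClass.C_BETA, random_codons(rng, C_CODONS - 1, _FORBIDDEN) + "TAA"
        )
    )
    return SegmentSet(segs)


def _build_trav_plasmid(v: GeneSegment, trbc2: GeneSegment, elements, stuffer, filler):
    parts = [
        ("IRDR_L", elements["irdr_left"]),
        (v.name, v.pre_anchor),
        ("EcoRV", ECORV.site),
        ("stuffer", stuffer),
        ("FspI", FSPI.site),
        ("TRBC2", trbc2.sequence),
        ("IRDR_R", elements["irdr_right"]),
        ("backbone", filler),
    ]
    return _annotate(parts, name=f"{v.name}-TRBC2-pSB")


def _build_trbv_plasmid(trbv: GeneSegment, trac: GeneSegment, elements, filler):
    parts = [
        ("EcoRV", ECORV.site),
        ("TRAC", trac.sequence),
        ("furin", elements["furin_nt"]),
        ("SGSG", elements["sgsg_nt"]),
        ("P2A", elements["p2a_nt"]),
        (trbv.name, trbv.pre_anchor),
        ("FspI", FSPI.site),
        ("backbone", filler),
    ]
    return _annotate(parts, name=f"TRAC-{trbv.name}")


def _annotate(parts: list[tuple[str, str]], name: str) -> AnnotatedPlasmid:
    seq, features, pos = [], [], 0
    for fname, fseq in parts:
        features.append(Feature(fname, pos, pos + len(fseq)))
        seq.append(fseq)
        pos += len(fseq)
    return AnnotatedPlasmid(
        fragment=DnaFragment("".join(seq), topology="circular", name=name),
        features=tuple(features),
    )


def make_fixture_library(seed: int) -> tuple[SegmentSet, BackboneLibrary]:
    """Synthetic germline plus backbone plasmids, byte-identical per seed.

    Every plasmid carries exactly one EcoRV and one FspI site in the
    designed linearization positions; the loop below regenerates the whole
    set in the (rare) event a junction between random parts recreates a
    site.
    """
    rng = np.random.default_rng(seed)
    for _ in range(64):
        segments = make_fixture_segments(int(rng.integers(0, 2**31)))
        elements = {
            "irdr_left": random_dna(rng, 40, _FORBIDDEN),
            "irdr_right": random_dna(rng, 40, _FORBIDDEN),
            "furin_nt": FURIN_NT,
            "sgsg_nt": SGSG_NT,
            "p2a_nt": P2A_NT,
            "junction_peptide": JUNCTION_PEPTIDE,
        }
        trbc2 = segments.c_segment("beta")
        trac = segments.c_segment("alpha")
        trav_trbc2 = {
            v.name: _build_trav_plasmid(
                v, trbc2, elements, random_dna(rng, 120, _FORBIDDEN),
                random_dna(rng, 200, _FORBIDDEN),
            )
            for v in segments.v_segments("alpha")
        }
        trac_trbv = {
            v.name: _build_trbv_plasmid(v, trac, elements, random_dna(rng, 250, _FORBIDDEN))
            for v in segments.v_segments("beta")
        }
        library = BackboneLibrary(trav_trbc2, trac_trbv, elements)
        try:
            library.validate()
        except GermlineError:
            continue
        return segments, library
    raise GermlineError("could not generate a valid fixture library")
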