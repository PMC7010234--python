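"""From paired clonotype to a validated Sleeping Beauty TCR construct.

A full-length TCRαβ gene is assembled from exactly four DNA fragments:

* the TRAV--TRBC2 vector, linearized out of its backbone plasmid by
  EcoRV + FspI (this fragment also carries the IR/DR transposase binding
  sites and the plasmid backbone);
* a CDR3α fragment, built from two synthetic single-strand oligos whose
  3' ends anneal over ``anneal_len`` (default 15) bases;
* the TRAC--furin-SGSG-P2A--TRBV insert, cut out of its plasmid by the
  same two enzymes (the leftover backbone piece is discarded);
* a CDR3β fragment, likewise two oligos.

Each CDR3 fragment carries ``hom_len`` (default 15) bases of terminal
homology copied from the abutting ends of its neighbor fragments, the
CDR3 junction itself, and the germline J remainder downstream of the J
anchor codon (J varies per clonotype while the backbone libraries are
indexed by V only, so the J remainder must travel with the junction).

The expression cassette reads TRAV - CDR3α - TRAJ remainder - TRAC -
furin-SGSG-P2A - TRBV - CDR3β - TRBJ remainder - TRBC2 as one open
reading frame; the ribosome-skipping P2A element splits it into separate
α and β chains at translation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp, translate
from .germline import (
    BackboneLibrary,
    Feature,
    GermlineError,
    SegmentSet,
)
from .gibson_engine import (
    ECORV,
    FSPI,
    DnaFragment,
    Junction,
    assemble,
    digest,
)
from .pairseq import Clonotype

DEFAULT_ANNEAL_LEN = 15
DEFAULT_HOM_LEN = 15
DUPLEX_LENGTH_CAP = 200


class ConstructError(Exception):
    pass


@dataclass(frozen=True)
class Cdr3Fragment:
    """A CDR3 gene fragment as a duplex plus its two constituent oligos."""

    chain_type: str
    duplex: str
    oligo_top: str
    oligo_bottom: str
    anneal_len: int = DEFAULT_ANNEAL_LEN
    name: str = ""
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if overlap_extend(self.oligo_top, self.oligo_bottom, self.anneal_len) != self.duplex:
            raise ConstructError(f"{self.name}: oligos do not reconstruct the duplex")

    @property
    def measured_overlap(self) -> int:
        """Length of the exact reverse-complement match between the two
        oligo 3' ends (measured, not assumed)."""
        limit = min(len(self.oligo_top), len(self.oligo_bottom))
        best = 0
        for k in range(1, limit + 1):
            if self.oligo_top[-k:] == revcomp(self.oligo_bottom[-k:]):
                best = k
        return best

    def as_dna_fragment(self) -> DnaFragment:
        return DnaFragment(self.duplex, topology="linear", name=self.name)


def overlap_extend(oligo_top: str, oligo_bottom: str, overlap: int) -> str:
    """Reconstruct the duplex a polymerase would fill in from two oligos
    annealed over their 3'-terminal ``overlap`` bases."""
    bottom_rc = revcomp(oligo_bottom)
    if oligo_top[-overlap:] != bottom_rc[:overlap]:
        raise ConstructError("oligo 3' ends do not anneal at the stated overlap")
    return oligo_top + bottom_rc[overlap:]


def linearized_backbones(
    clonotype: Clonotype, library: BackboneLibrary
) -> tuple[DnaFragment, DnaFragment]:
    """EcoRV+FspI digests of the two backbone plasmids for a clonotype:
    (TRAV-TRBC2 vector fragment, TRAC-TRBV insert fragment).  The
    TRAC-TRBV plasmid's non-insert backbone piece is discarded."""
    try:
        trav_plasmid = library.trav_trbc2[clonotype.trav]
    except KeyError:
        raise ConstructError(f"no TRAV-TRBC2 backbone for gene {clonotype.trav}") from None
    try:
        trbv_plasmid = library.trac_trbv[clonotype.trbv]
    except KeyError:
        raise ConstructError(f"no TRAC-TRBV backbone for gene {clonotype.trbv}") from None

    def pick(plasmid, marker: str, name: str) -> DnaFragment:
        pieces = digest(plasmid.fragment, [ECORV, FSPI], require_cut=True)
        if len(pieces) != 2:
            raise ConstructError(f"{plasmid.fragment.name}: expected 2 pieces, got {len(pieces)}")
        for piece in pieces:
            if marker in piece.sequence or revcomp(marker) in piece.sequence:
                return DnaFragment(piece.sequence, "linear", name=name)
        raise ConstructError(f"{plasmid.fragment.name}: marker feature not found after digest")

    vector = pick(trav_plasmid, library.elements["irdr_left"], f"{clonotype.trav}-TRBC2 vector")
    insert = pick(trbv_plasmid, library.elements["p2a_nt"], f"TRAC-{clonotype.trbv} insert")
    return vector, insert


def design_cdr3_fragment(
    chain_type: str,
    clonotype: Clonotype,
    germline: SegmentSet,
    library: BackboneLibrary,
    anneal_len: int = DEFAULT_ANNEAL_LEN,
    hom_len: int = DEFAULT_HOM_LEN,
    max_len: int = DUPLEX_LENGTH_CAP,
) -> Cdr3Fragment:
    """Design the two-oligo CDR3 gene fragment for one chain.

    duplex = ``hom_len`` bases copied from the abutting end of the
    upstream fragment + CDR3 nt + germline J remainder + ``hom_len``
    bases from the abutting end of the downstream fragment.  The two
    oligos split near the duplex midpoint with a 3' overlap of exactly
    ``anneal_len``; lengths differ by at most 1 (ties favor the top
    oligo).
    """
    vector, insert = linearized_backbones(clonotype, library)
    if chain_type == "alpha":
        j = germline.get(clonotype.traj)
        cdr3, upstream, downstream = clonotype.cdr3a_nt, vector, insert
    elif chain_type == "beta":
        j = germline.get(clonotype.trbj)
        cdr3, upstream, downstream = clonotype.cdr3b_nt, insert, vector
    else:
        raise ConstructError(f"unknown chain type {chain_type!r}")

    duplex = (
        upstream.sequence[-hom_len:] + cdr3 + j.post_anchor + downstream.sequence[:hom_len]
    )
    if len(duplex) > max_len:
        raise ConstructError(
            f"CDR3 {chain_type} duplex length {len(duplex)} exceeds cap {max_len}"
        )
    warnings = tuple(
        f"duplex contains {enz.name} site ({enz.site}); re-linearization hazard"
        for enz in (ECORV, FSPI)
        if enz.site in duplex
    )
    split = math.ceil((len(duplex) + anneal_len) / 2)
    return Cdr3Fragment(
        chain_type=chain_type,
        duplex=duplex,
        oligo_top=duplex[:split],
        oligo_bottom=revcomp(duplex[split - anneal_len:]),
        anneal_len=anneal_len,
        name=f"CDR3{'a' if chain_type == 'alpha' else 'b'}_{clonotype.id}",
        warnings=warnings,
    )


@dataclass(frozen=True)
class AssemblyPlan:
    """An ordered, oriented 4-fragment set proven to close into one circle."""

    clonotype_id: str
    fragments: tuple[DnaFragment, ...]
    cdr3_alpha: Cdr3Fragment
    cdr3_beta: Cdr3Fragment
    junction_homologies: tuple[Junction, ...]
    min_hom: int

    def __post_init__(self):
        if len(self.fragments) != 4:
            raise ConstructError("a standard TCR build uses exactly 4 fragments")
        short = [j for j in self.junction_homologies if j.length < self.min_hom]
        if short:
            raise ConstructError(f"junction homology below {self.min_hom} bp: {short}")


def plan_assembly(
    clonotype: Clonotype,
    library: BackboneLibrary,
    germline: SegmentSet,
    anneal_len: int = DEFAULT_ANNEAL_LEN,
    hom_len: int = DEFAULT_HOM_LEN,
) -> AssemblyPlan:
    """Resolve the 4 fragments and their junction homologies for one
    clonotype: vector, CDR3α, TRAC-TRBV insert, CDR3β."""
    vector, insert = linearized_backbones(clonotype, library)
    cdr3a = design_cdr3_fragment(
        "alpha", clonotype, germline, library, anneal_len, hom_len
    )
    cdr3b = design_cdr3_fragment(
        "beta", clonotype, germline, library, anneal_len, hom_len
    )
    ordered = (vector, cdr3a.as_dna_fragment(), insert, cdr3b.as_dna_fragment())
    junctions = tuple(
        Junction(
            left=ordered[i].name,
            right=ordered[(i + 1) % 4].name,
            homology=ordered[i].sequence[-hom_len:],
        )
        for i in range(4)
    )
    return AssemblyPlan(
        clonotype_id=clonotype.id,
        fragments=ordered,
        cdr3_alpha=cdr3a,
        cdr3_beta=cdr3b,
        junction_homologies=junctions,
        min_hom=hom_len,
    )


@dataclass(frozen=True)
class ValidationReport:
    orf_ok: bool
    cdr3a_match: bool
    cdr3b_match: bool
    p2a_junction_ok: bool
    premature_stop: bool
    irdr_flank_ok: bool

    @property
    def all_ok(self) -> bool:
        return (
            self.orf_ok
            and self.cdr3a_match
            and self.cdr3b_match
            and self.p2a_junction_ok
            and self.irdr_flank_ok
            and not self.premature_stop
        )


@dataclass(frozen=True)
class TcrConstruct:
    """Assembled circular SB transposon plus feature map and validation."""

    clonotype_id: str
    fragment: DnaFragment  # circular, rotated so the cassette starts at 0
    features: tuple[Feature, ...]
    report: ValidationReport

    @property
    def sequence(self) -> str:
        return self.fragment.sequence


def _cassette_rotation(seq: str, start_marker: str) -> str | None:
    """Rotate/flip a circular sequence so ``start_marker`` sits at 0."""
    for s in (seq, revcomp(seq)):
        doubled = s + s
        i = doubled.find(start_marker)
        if 0 <= i < len(s):
            return doubled[i: i + len(s)]
    return None


def validate_construct(
    product: DnaFragment,
    clonotype: Clonotype,
    germline: SegmentSet,
    library: BackboneLibrary,
) -> TcrConstruct:
    """Check an assembled circle against its intended clonotype.

    Verifies (a) a single uninterrupted ORF from the TRAV start codon to
    the TRBC2 stop, (b) the α and β CDR3 peptides each appearing exactly
    once in the translation, (c) exactly one furin-SGSG-P2A junction
    peptide, (d) both IR/DR elements flanking the cassette.  All findings
    are report fields; nothing raises.
    """
    if product.topology != "circular":
        raise ConstructError("validation requires a circular product")
    trav = germline.get(clonotype.trav)
    trbc2 = germline.c_segment("beta")
    rotated = _cassette_rotation(product.sequence, trav.pre_anchor)
    if rotated is None:
        report = ValidationReport(False, False, False, False, True, False)
        return TcrConstruct(clonotype.id, product, (), report)

    orf_end = rotated.find(trbc2.sequence)
    if orf_end >= 0:
        orf = rotated[: orf_end + len(trbc2.sequence)]
    else:
        orf = rotated
    in_frame = len(orf) % 3 == 0
    protein_orf = translate(orf[: 3 * (len(orf) // 3)]) if orf else ""
    premature_stop = "*" in protein_orf[:-1]
    orf_ok = orf_end >= 0 and in_frame and not premature_stop and protein_orf.endswith("*")

    protein_all = translate(rotated[: 3 * (len(rotated) // 3)])
    cdr3a_match = protein_all.count(clonotype.cdr3a_aa) == 1
    cdr3b_match = protein_all.count(clonotype.cdr3b_aa) == 1
    p2a_ok = protein_all.count(library.elements["junction_peptide"]) == 1

    irdr_l, irdr_r = library.elements["irdr_left"], library.elements["irdr_right"]
    lpos, rpos = rotated.find(irdr_l), rotated.find(irdr_r)
    irdr_flank_ok = (
        rotated.count(irdr_l) == 1
        and rotated.count(irdr_r) == 1
        and orf_end >= 0
        and rpos > orf_end
        and lpos > rpos
    )

    report = ValidationReport(
        orf_ok=orf_ok,
        cdr3a_match=cdr3a_match,
        cdr3b_match=cdr3b_match,
        p2a_junction_ok=p2a_ok,
        premature_stop=premature_stop,
        irdr_flank_ok=irdr_flank_ok,
    )
    features = _feature_map(rotated, clonotype, germline, library)
    return TcrConstruct(
        clonotype.id,
        DnaFragment(rotated, "circular", name=f"SB-{clonotype.id}"),
        features,
        report,
    )


def _feature_map(
    rotated: str, clonotype: Clonotype, germline: SegmentSet, library: BackboneLibrary
) -> tuple[Feature, ...]:
    """Annotate cassette features by exact sequence walk from position 0;
    parts that do not match where expected are simply omitted."""
    trav = germline.get(clonotype.trav)
    traj = germline.get(clonotype.traj)
    trbv = germline.get(clonotype.trbv)
    trbj = germline.get(clonotype.trbj)
    el = library.elements
    parts = [
        ("TRAV", trav.pre_anchor),
        ("linker", "GAT"),
        ("CDR3a", clonotype.cdr3a_nt),
        ("TRAJ_remainder", traj.post_anchor),
        ("linker", "ATC"),
        ("TRAC", germline.c_segment("alpha").sequence),
        ("furin", el["furin_nt"]),
        ("SGSG", el["sgsg_nt"]),
        ("P2A", el["p2a_nt"]),
        ("TRBV", trbv.pre_anchor),
        ("linker", "TGC"),
        ("CDR3b", clonotype.cdr3b_nt),
        ("TRBJ_remainder", trbj.post_anchor),
        ("linker", "GCA"),
        ("TRBC2", germline.c_segment("beta").sequence),
    ]
    features: list[Feature] = []
    pos = 0
    for name, seq in parts:
        if rotated[pos: pos + len(seq)] != seq:
            return tuple(features)  # walk stops at the first divergence
        if name != "linker":
            features.append(Feature(name, pos, pos + len(seq)))
        pos += len(seq)
    for name, marker in (("IRDR_R", el["irdr_right"]), ("IRDR_L", el["irdr_left"])):
        i = rotated.find(marker)
        if i >= 0:
            features.append(Feature(name, i, i + len(marker)))
    return tuple(features)


def build_construct(
    clonotype: Clonotype,
    library: BackboneLibrary,
    germline: SegmentSet,
    anneal_len: int = DEFAULT_ANNEAL_LEN,
    hom_len: int = DEFAULT_HOM_LEN,
) -> tuple[TcrConstruct, AssemblyPlan, tuple[Junction, ...]]:
    """plan -> Gibson assemble -> validate, end to end for one clonotype."""
    plan = plan_assembly(clonotype, library, germline, anneal_len, hom_len)
    product, junctions = assemble(list(plan.fragments), min_hom=hom_len)
    construct = validate_construct(product, clonotype, germline, library)
    return construct, plan, tuple(junctions)


def oligo_order_sheet(plans: list[AssemblyPlan]) -> pd.DataFrame:
    """Synthesis order sheet for every CDR3 oligo in a set of plans."""
    rows = []
    for plan in plans:
        for frag in (plan.cdr3_alpha, plan.cdr3_beta):
            for suffix, oligo in (("top", frag.oligo_top), ("bottom", frag.oligo_bottom)):
                rows.append(
                    {"name": f"{frag.name}_{suffix}", "sequence": oligo, "length": len(oligo)}
                )
    return pd.DataFrame(rows, columns=["name", "sequence", "length"])


def write_construct_fasta(constructs: list[TcrConstruct], path) -> None:
    with open(path, "w") as fh:
        for c in constructs:
            fh.write(f">{c.fragment.name} circular len={len(c.sequence)}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i: i + 70] + "\n")


def write_feature_table(construct: TcrConstruct, path) -> None:
    pd.DataFrame(
        [
            {"name": f.name, "start": f.start, "end": f.end, "strand": f.strand}
            for f in construct.features
        ],
        columns=["name", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)
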