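"""Demultiplexing, CDR3 extraction, chain pairing and clonotype calling.

The in-silico counterpart of retrieving each single T cell's TCRα and
TCRβ CDR3 junctions from pooled, well-barcoded amplicon reads:

1. assign every read to a well by its 5'/3' barcode pair (mismatch
   tolerant, ambiguous reads binned as unassigned);
2. identify the V gene from the read-borne V prefix (nearest germline by
   Hamming distance, ties rejected);
3. extract the anchor-inclusive CDR3 junction — conserved V cysteine
   codon through conserved J phenylalanine/tryptophan codon — by locating
   the germline J remainder in the read;
4. collapse reads per well into supported chains, flag dual-α/β wells,
   pair productive chains, and deduplicate paired clonotypes across
   wells.

A chain is *productive* when its junction is in frame, stop-free, starts
with C and ends with F or W.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from ._seq import hamming, translate
from .assaymath import rate_percent
from .germline import GeneSegment, SegmentSet, normalize_gene_name
from .simdata import BarcodeScheme, ReadRecord

DEFAULT_MAX_MISMATCH = 1
DEFAULT_MIN_READS = 5
DEFAULT_DUAL_FRACTION = 0.2
DEFAULT_MIN_PREFIX = 20
_V_MAX_MISMATCH_FRACTION = 0.25  # V prefix hits above this are noise
_J_MAX_MISMATCH = 3


class PairingError(Exception):
    pass


@dataclass(frozen=True)
class Clonotype:
    """One paired TCRαβ in the clonotype-table row schema.

    The amino-acid junctions are always the translation of the nucleotide
    junctions; TRBD is frequently unassignable from CDR3 reads and may be
    empty.
    """

    id: str
    trav: str
    traj: str
    cdr3a_nt: str
    cdr3a_aa: str
    trbv: str
    trbj: str
    cdr3b_nt: str
    cdr3b_aa: str
    trbd: str = ""

    def __post_init__(self):
        for nt, aa, label in (
            (self.cdr3a_nt, self.cdr3a_aa, "alpha"),
            (self.cdr3b_nt, self.cdr3b_aa, "beta"),
        ):
            got = translate_cdr3(nt)
            if got != aa:
                raise PairingError(
                    f"{self.id}: {label} junction aa {aa!r} is not the "
                    f"translation of its nt junction ({got!r})"
                )
            if not aa.startswith("C") or aa[-1] not in "FW":
                raise PairingError(f"{self.id}: {label} junction {aa!r} lacks C...F/W anchors")

    @property
    def pair_key(self) -> tuple:
        return (self.trav, self.traj, self.cdr3a_nt, self.trbv, self.trbj, self.cdr3b_nt)


def translate_cdr3(cdr3_nt: str) -> str:
    """Standard-code translation of a junction; stops rendered as ``*``."""
    return translate(cdr3_nt)


@dataclass(frozen=True)
class ChainCall:
    chain_type: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    support: int

    def __post_init__(self):
        if self.support <= 0:
            raise PairingError("reported chains require positive read support")

    @property
    def cdr3_aa(self) -> str | None:
        if len(self.cdr3_nt) % 3 != 0:
            return None
        return translate_cdr3(self.cdr3_nt)

    @property
    def productive(self) -> bool:
        aa = self.cdr3_aa
        return (
            aa is not None
            and "*" not in aa
            and aa.startswith("C")
            and len(aa) >= 2
            and aa[-1] in "FW"
        )


@dataclass
class WellCall:
    well: str
    alpha_chains: list[ChainCall] = field(default_factory=list)
    beta_chains: list[ChainCall] = field(default_factory=list)
    dual_alpha: bool = False
    dual_beta: bool = False


# ---------------------------------------------------------------------------
# step 1: demultiplexing


def demultiplex(
    reads: list[ReadRecord],
    scheme: BarcodeScheme,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to wells by barcode pair; ambiguous or distant
    barcodes land in the unassigned bin (never fatal)."""
    by_well: dict[str, list[ReadRecord]] = {}
    unassigned: list[ReadRecord] = []
    for read in reads:
        seq = read.sequence
        row = _match_barcode(seq[: scheme.bc_len5], scheme.five_prime, max_mismatch)
        col = _match_barcode(seq[-scheme.bc_len3:], scheme.three_prime, max_mismatch)
        if row is None or col is None:
            unassigned.append(read)
        else:
            by_well.setdefault(scheme.well_label(row, col), []).append(read)
    return by_well, unassigned


def _match_barcode(observed: str, barcodes: tuple[str, ...], max_mismatch: int) -> int | None:
    candidates = [
        i for i, bc in enumerate(barcodes) if hamming(observed, bc) <= max_mismatch
    ]
    return candidates[0] if len(candidates) == 1 else None


# ---------------------------------------------------------------------------
# steps 2-3: V assignment and CDR3 extraction


@dataclass(frozen=True)
class VAssignment:
    segment: GeneSegment
    v_end: int        # read position where the germline V prefix ends
    mismatches: int


def assign_v_gene(
    insert: str,
    v_segments: list[GeneSegment],
    min_prefix: int = DEFAULT_MIN_PREFIX,
) -> VAssignment | None:
    """Best V by Hamming distance of the read's leading ``min_prefix``
    bases against every germline V pre-anchor region; ties or distances
    above the noise threshold return None."""
    probe = insert[:min_prefix]
    if len(probe) < min_prefix:
        return None
    threshold = int(min_prefix * _V_MAX_MISMATCH_FRACTION)
    best: VAssignment | None = None
    tied = False
    for v in v_segments:
        pre = v.pre_anchor
        if len(pre) < min_prefix:
            continue
        pos = pre.find(probe)
        if pos >= 0:
            d = 0
        else:
            pos, d = min(
                ((p, hamming(probe, pre[p: p + min_prefix]))
                 for p in range(len(pre) - min_prefix + 1)),
                key=lambda t: t[1],
            )
        if d > threshold:
            continue
        cand = VAssignment(v, v_end=len(pre) - pos, mismatches=d)
        if best is None or d < best.mismatches:
            best, tied = cand, False
        elif d == best.mismatches:
            tied = True
    return None if tied else best


def extract_cdr3(
    insert: str,
    v: VAssignment | GeneSegment,
    j_segments: list[GeneSegment],
    max_j_mismatch: int = _J_MAX_MISMATCH,
) -> tuple[str, str] | None:
    """CDR3 junction spanning the V anchor Cys codon through the J anchor
    Phe/Trp codon, located by matching the germline J remainder in the
    read suffix.  Returns ``(j_gene, cdr3_nt)`` or None."""
    if isinstance(v, GeneSegment):
        va = assign_v_gene(insert, [v])
        if va is None:
            return None
    else:
        va = v
    start = va.v_end
    best = None
    tied = False
    for j in j_segments:
        tail = j.post_anchor
        if not tail or len(insert) < start + 6 + len(tail):
            continue
        pos = insert.find(tail, start + 3)
        d = 0
        if pos < 0:
            pos, d = min(
                ((p, hamming(tail, insert[p: p + len(tail)]))
                 for p in range(start + 3, len(insert) - len(tail) + 1)),
                key=lambda t: t[1],
            )
            if d > max_j_mismatch:
                continue
        if pos - start < 6:  # junction must hold both anchor codons
            continue
        if best is None or d < best[2]:
            best, tied = (j.name, insert[start:pos], d), False
        elif d == best[2]:
            tied = True
    if best is None or tied:
        return None
    return best[0], best[1]


# ---------------------------------------------------------------------------
# step 4: per-well consensus, pairing, deduplication


def call_well(well: str, reads: list[ReadRecord], germline: SegmentSet) -> WellCall:
    """Collapse a well's reads into supported chain calls (no thresholds)."""
    v_alpha = germline.v_segments("alpha")
    v_beta = germline.v_segments("beta")
    j_alpha = germline.j_segments("alpha")
    j_beta = germline.j_segments("beta")
    counts: dict[tuple, int] = {}
    for read in reads:
        insert = read.sequence
        va = assign_v_gene(insert, v_alpha + v_beta)
        if va is None:
            continue
        chain = va.segment.segment_class.chain
        hit = extract_cdr3(insert, va, j_alpha if chain == "alpha" else j_beta)
        if hit is None:
            continue
        j_gene, cdr3 = hit
        counts[(chain, va.segment.name, j_gene, cdr3)] = (
            counts.get((chain, va.segment.name, j_gene, cdr3), 0) + 1
        )
    call = WellCall(well=well)
    for (chain, v_name, j_name, cdr3), support in sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        target = call.alpha_chains if chain == "alpha" else call.beta_chains
        target.append(ChainCall(chain, v_name, j_name, cdr3, support))
    return call


def strip_barcodes(read: ReadRecord, scheme: BarcodeScheme) -> ReadRecord:
    return replace(
        read,
        sequence=read.sequence[scheme.bc_len5: -scheme.bc_len3],
        quality=read.quality[scheme.bc_len5: -scheme.bc_len3],
    )


def call_clonotypes(
    well_calls: list[WellCall],
    min_reads: int = DEFAULT_MIN_READS,
    dual_fraction: float = DEFAULT_DUAL_FRACTION,
) -> tuple[list[Clonotype], dict]:
    """Threshold chains, flag dual-chain wells, pair α/β, deduplicate.

    Chains need ``min_reads`` supporting reads.  A second same-type
    productive chain at >= ``dual_fraction`` of the top chain's support
    marks the well dual-α (or dual-β).  Wells with exactly one productive
    α and one productive β yield a paired clonotype; clonotypes are
    deduplicated across wells on (V, J, CDR3 nt) of both chains.
    """
    clonotypes: list[Clonotype] = []
    seen: dict[tuple, Clonotype] = {}
    analyzed = dual_a = dual_b = paired_wells = 0
    for wc in well_calls:
        kept_a = [c for c in wc.alpha_chains if c.support >= min_reads]
        kept_b = [c for c in wc.beta_chains if c.support >= min_reads]
        prod_a = [c for c in kept_a if c.productive]
        prod_b = [c for c in kept_b if c.productive]
        if not (kept_a or kept_b):
            continue
        analyzed += 1
        wc.dual_alpha = (
            len(prod_a) >= 2 and prod_a[1].support >= dual_fraction * prod_a[0].support
        )
        wc.dual_beta = (
            len(prod_b) >= 2 and prod_b[1].support >= dual_fraction * prod_b[0].support
        )
        dual_a += wc.dual_alpha
        dual_b += wc.dual_beta
        if len(prod_a) == 1 and len(prod_b) == 1:
            paired_wells += 1
            a, b = prod_a[0], prod_b[0]
            key = (a.v_gene, a.j_gene, a.cdr3_nt, b.v_gene, b.j_gene, b.cdr3_nt)
            if key not in seen:
                ct = Clonotype(
                    id=f"TCR{len(seen) + 1}",
                    trav=a.v_gene,
                    traj=a.j_gene,
                    cdr3a_nt=a.cdr3_nt,
                    cdr3a_aa=a.cdr3_aa,
                    trbv=b.v_gene,
                    trbj=b.j_gene,
                    cdr3b_nt=b.cdr3_nt,
                    cdr3b_aa=b.cdr3_aa,
                )
                seen[key] = ct
                clonotypes.append(ct)
    summary = {
        "analyzed_wells": analyzed,
        "paired_wells": paired_wells,
        "unique_clonotypes": len(clonotypes),
        "dual_alpha_wells": dual_a,
        "dual_beta_wells": dual_b,
        "dual_alpha_pct": rate_percent(dual_a, analyzed) if analyzed else 0.0,
        "dual_beta_pct": rate_percent(dual_b, analyzed) if analyzed else 0.0,
    }
    return clonotypes, summary


@dataclass
class PairingResult:
    well_calls: list[WellCall]
    clonotypes: list[Clonotype]
    summary: dict
    n_assigned: int
    n_unassigned: int


def run_pairing(
    reads: list[ReadRecord],
    scheme: BarcodeScheme,
    germline: SegmentSet,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_reads: int = DEFAULT_MIN_READS,
    dual_fraction: float = DEFAULT_DUAL_FRACTION,
) -> PairingResult:
    """Full pipeline: demultiplex -> extract -> pair -> deduplicate."""
    by_well, unassigned = demultiplex(reads, scheme, max_mismatch)
    well_calls = [
        call_well(well, [strip_barcodes(r, scheme) for r in reads_], germline)
        for well, reads_ in sorted(by_well.items())
    ]
    clonotypes, summary = call_clonotypes(well_calls, min_reads, dual_fraction)
    return PairingResult(
        well_calls=well_calls,
        clonotypes=clonotypes,
        summary=summary,
        n_assigned=sum(len(v) for v in by_well.values()),
        n_unassigned=len(unassigned),
    )


# ---------------------------------------------------------------------------
# clonotype table I/O

CLONOTYPE_COLUMNS = [
    "UCN", "TRAV", "TRAJ", "cdr3a_nt", "cdr3a_aa",
    "TRBV", "TRBD", "TRBJ", "cdr3b_nt", "cdr3b_aa",
]


def write_clonotypes(clonotypes: list[Clonotype], path) -> None:
    pd.DataFrame(
        [
            {
                "UCN": c.id,
                "TRAV": c.trav,
                "TRAJ": c.traj,
                "cdr3a_nt": c.cdr3a_nt,
                "cdr3a_aa": c.cdr3a_aa,
                "TRBV": c.trbv,
                "TRBD": c.trbd,
                "TRBJ": c.trbj,
                "cdr3b_nt": c.cdr3b_nt,
                "cdr3b_aa": c.cdr3b_aa,
            }
            for c in clonotypes
        ],
        columns=CLONOTYPE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_clonotypes(path) -> list[Clonotype]:
    """Read a clonotype TSV, normalizing gene tokens (stray asterisks,
    defaulted alleles) on the way in."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    clonotypes = []
    for row in df.to_dict("records"):
        trbd = row.get("TRBD", "")
        clonotypes.append(
            Clonotype(
                id=row["UCN"],
                trav=normalize_gene_name(row["TRAV"])[0],
                traj=normalize_gene_name(row["TRAJ"])[0],
                cdr3a_nt=row["cdr3a_nt"],
                cdr3a_aa=row["cdr3a_aa"],
                trbv=normalize_gene_name(row["TRBV"])[0],
                trbj=normalize_gene_name(row["TRBJ"])[0],
                cdr3b_nt=row["cdr3b_nt"],
                cdr3b_aa=row["cdr3b_aa"],
                trbd=normalize_gene_name(trbd)[0] if trbd else "",
            )
        )
    return clonotypes
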