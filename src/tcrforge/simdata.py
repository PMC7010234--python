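"""Synthetic barcoded amplicon reads for a plate-based paired-TCR run.

Emulates the pooled end product of a combinatorially barcoded multiplex
protocol for single T cells sorted one-per-well into a 96-well plate:
each well is labeled by a unique (5' row barcode, 3' column barcode)
pair, and every read carries

    [5' well barcode][V-region prefix][CDR3 junction][J remainder][C stub][3' well barcode]

with i.i.d. substitution errors at a configurable per-base rate.  Truth
metadata (well, chain, clonotype) rides on each record and is written to
a sidecar TSV for testing only — the caller pipeline never sees it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA_ALPHABET, hamming
from .germline import SegmentSet

DEFAULT_BC_LEN = 8
DEFAULT_MIN_DIST = 3
V_PREFIX_LEN = 40   # germline V bases upstream of the junction carried per read
C_STUB_LEN = 20     # constant-region bases downstream of the J remainder
QUALITY_CHAR = "I"  # constant Q40; quality realism is a non-goal


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class BarcodeScheme:
    """Combinatorial 5' (row) x 3' (column) well barcodes."""

    five_prime: tuple[str, ...]
    three_prime: tuple[str, ...]

    def __post_init__(self):
        for side in (self.five_prime, self.three_prime):
            if len({len(b) for b in side}) != 1:
                raise SimulationError("barcodes within a side must share one length")
        if len(self.five_prime) > 26:
            raise SimulationError("row barcodes limited to 26 (A..Z labels)")

    @property
    def bc_len5(self) -> int:
        return len(self.five_prime[0])

    @property
    def bc_len3(self) -> int:
        return len(self.three_prime[0])

    def well_label(self, row: int, col: int) -> str:
        return f"{chr(ord('A') + row)}{col + 1}"

    def wells(self) -> list[str]:
        return [
            self.well_label(i, j)
            for i in range(len(self.five_prime))
            for j in range(len(self.three_prime))
        ]

    def barcodes_for(self, well: str) -> tuple[str, str]:
        row = ord(well[0]) - ord("A")
        col = int(well[1:]) - 1
        return self.five_prime[row], self.three_prime[col]

    def min_pairwise_distance(self) -> int:
        dists = [
            hamming(a, b)
            for side in (self.five_prime, self.three_prime)
            for a, b in itertools.combinations(side, 2)
        ]
        return min(dists) if dists else len(self.five_prime[0])


def build_default_scheme(
    rows: int = 8,
    cols: int = 12,
    bc_len: int = DEFAULT_BC_LEN,
    seed: int = 0,
    min_dist: int = DEFAULT_MIN_DIST,
) -> BarcodeScheme:
    """Greedy, seeded barcode design with pairwise Hamming distance
    >= ``min_dist`` within each side; addresses exactly rows x cols wells."""
    rng = np.random.default_rng(seed)

    def pick(n: int) -> tuple[str, ...]:
        chosen: list[str] = []
        for _ in range(20000):
            cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=bc_len))
            if all(hamming(cand, c) >= min_dist for c in chosen):
                chosen.append(cand)
                if len(chosen) == n:
                    return tuple(chosen)
        raise SimulationError(
            f"cannot place {n} barcodes of length {bc_len} at distance >= {min_dist}"
        )

    return BarcodeScheme(five_prime=pick(rows), three_prime=pick(cols))


@dataclass(frozen=True)
class PlantedChain:
    chain_type: str  # 'alpha' | 'beta'
    v_gene: str
    j_gene: str
    cdr3_nt: str
    clonotype_id: str = ""

    def __post_init__(self):
        if self.chain_type not in ("alpha", "beta"):
            raise SimulationError(f"bad chain type {self.chain_type!r}")
        if not set(self.cdr3_nt) <= DNA_ALPHABET:
            raise SimulationError(f"CDR3 must be ACGT: {self.cdr3_nt!r}")


@dataclass
class PlateLayout:
    """Planted chains per well; occupancy may be 0, 1 cell, or dual chains."""

    wells: dict[str, list[PlantedChain]] = field(default_factory=dict)

    def n_chains(self) -> int:
        return sum(len(chains) for chains in self.wells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "well": well,
                "chain_type": c.chain_type,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "cdr3_nt": c.cdr3_nt,
                "clonotype_id": c.clonotype_id,
            }
            for well, chains in sorted(self.wells.items())
            for c in chains
        ]
        return pd.DataFrame(
            rows, columns=["well", "chain_type", "v_gene", "j_gene", "cdr3_nt", "clonotype_id"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        layout = cls()
        for row in df.to_dict("records"):
            layout.wells.setdefault(row["well"], []).append(
                PlantedChain(
                    chain_type=row["chain_type"],
                    v_gene=row["v_gene"],
                    j_gene=row["j_gene"],
                    cdr3_nt=row["cdr3_nt"],
                    clonotype_id=row.get("clonotype_id", ""),
                )
            )
        return layout


def layout_from_clonotypes(assignments: dict[str, "object"]) -> PlateLayout:
    """Plant one paired clonotype per well; ``assignments`` maps well label
    to a Clonotype-like object (trav/traj/cdr3a_nt/trbv/trbj/cdr3b_nt)."""
    layout = PlateLayout()
    for well, ct in assignments.items():
        layout.wells[well] = [
            PlantedChain("alpha", ct.trav, ct.traj, ct.cdr3a_nt, ct.id),
            PlantedChain("beta", ct.trbv, ct.trbj, ct.cdr3b_nt, ct.id),
        ]
    return layout


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str
    well: str = ""
    chain_type: str = ""
    clonotype_id: str = ""

    def __post_init__(self):
        if len(self.quality) != len(self.sequence):
            raise SimulationError("quality and sequence lengths differ")


def _insert_for(chain: PlantedChain, germline: SegmentSet) -> str:
    v = germline.get(chain.v_gene)
    j = germline.get(chain.j_gene)
    c = germline.c_segment(chain.chain_type)
    return (
        v.pre_anchor[-V_PREFIX_LEN:]
        + chain.cdr3_nt
        + j.post_anchor
        + c.sequence[:C_STUB_LEN]
    )


def simulate_reads(
    layout: PlateLayout,
    scheme: BarcodeScheme,
    germline: SegmentSet,
    reads_per_chain: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadRecord]:
    """Emit exactly ``reads_per_chain`` reads per planted chain.

    Substitutions are i.i.d. per base at ``error_rate`` over the whole
    read, barcodes included.  Fixed seed gives byte-identical output.
    Unknown gene names raise before any read is produced.
    """
    if not 0 <= error_rate < 0.25:
        raise SimulationError("error_rate must be in [0, 0.25)")
    inserts = {}
    for well, chains in sorted(layout.wells.items()):
        if well not in set(scheme.wells()):
            raise SimulationError(f"well {well} not addressed by the barcode scheme")
        for chain in chains:
            inserts[(well, id(chain))] = _insert_for(chain, germline)

    rng = np.random.default_rng(seed)
    records: list[ReadRecord] = []
    counter = 0
    for well, chains in sorted(layout.wells.items()):
        bc5, bc3 = scheme.barcodes_for(well)
        for chain in chains:
            template = bc5 + inserts[(well, id(chain))] + bc3
            for _ in range(reads_per_chain):
                seq = _mutate(template, error_rate, rng)
                counter += 1
                records.append(
                    ReadRecord(
                        id=f"read{counter:06d}|{well}|{chain.chain_type}",
                        sequence=seq,
                        quality=QUALITY_CHAR * len(seq),
                        well=well,
                        chain_type=chain.chain_type,
                        clonotype_id=chain.clonotype_id,
                    )
                )
    return records


def _mutate(seq: str, error_rate: float, rng) -> str:
    if error_rate == 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def write_fastq(records: list[ReadRecord], path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id.split("|")[0],
            description="",
            letter_annotations={
                "phred_quality": [ord(q) - 33 for q in r.quality]
            },
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fastq")


def read_fastq(path) -> list[ReadRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        records.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                quality="".join(chr(q + 33) for q in quals),
            )
        )
    return records


def write_truth(records: list[ReadRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": r.id.split("|")[0],
                "well": r.well,
                "chain_type": r.chain_type,
                "clonotype_id": r.clonotype_id,
            }
            for r in records
        ],
        columns=["read_id", "well", "chain_type", "clonotype_id"],
    ).to_csv(path, sep="\t", index=False)
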