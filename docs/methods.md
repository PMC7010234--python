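# Methods

## Scope and model

`tcrforge` models the dry-lab half of a rapid TCR cloning platform: the
informatics of recovering paired TCRαβ CDR3 junctions from single-cell
barcoded amplicon sequencing, and the sequence-level design, assembly
and validation of full-length TCRαβ genes as Sleeping Beauty (SB)
transposon plasmids. Wet-lab physics — PCR chemistry and amplification
bias, transposase mechanics, reporter-cell biology, flow-cytometer
behavior — is out of scope; where a wet-lab step has a deterministic
sequence-level consequence (a restriction cut, an overhang removed by
single-strand nuclease, a homology merged by Gibson chemistry), that
consequence is modeled exactly.

## CDR3 junction convention

Junctions are anchor-inclusive: a CDR3 nucleotide junction runs from
the first base of the conserved V-region cysteine codon through the
last base of the conserved J-region phenylalanine/tryptophan codon.
Every junction in the packaged CMV clonotype table starts with C and
ends with F under this convention, which is what forces it. A chain is
*productive* when its junction length is a multiple of 3, its
translation is stop-free, and the C…F/W anchors are intact. Translation
is standard-code via Biopython with stops rendered `*`; ambiguity codes
and partial codons are rejected rather than guessed.

## Synthetic germline and backbone fixtures

No real germline or plasmid sequence is bundled; `make_fixture_library`
generates, deterministically per seed, a synthetic stand-in for every
V/J/C gene the clonotype table uses (24 segments: 5 TRAV, 7 TRAJ,
5 TRBV, 5 TRBJ, TRAC, TRBC2):

* V segments: `ATG` + 19 random sense codons + a terminal Cys codon;
  the anchor sits at position 60, so the cassette upstream of every
  junction is an in-frame, stop-free ORF head of fixed length.
* J segments: the anchor F/W codon (matching the codon observed in the
  table's junctions) + 10 random sense codons; the post-anchor
  "J remainder" (30 nt) is what reads and CDR3 fragments carry.
* TRAC is 30 sense codons; TRBC2 is 29 sense codons plus a TAA stop —
  the single intended stop of the whole cassette.

Backbone plasmids — one TRAV–TRBC2 vector plasmid per TRAV and one
TRAC–furin-SGSG-P2A–TRBV insert plasmid per TRBV — are laid out so that
a double digest with the blunt cutters EcoRV (`GATATC`) and FspI
(`TGCGCA`) excises a stuffer (vector plasmid) or releases the insert
(TRBV plasmid). Every random region is rejection-sampled against the
two recognition sites, and the whole library is regenerated in the rare
event a junction between parts recreates one, so each plasmid carries
exactly one site per enzyme. The half-site residues left at the blunt
cuts (`GAT`, `ATC`, `TGC`, `GCA`) are whole codons and remain in frame;
they appear in the final construct as one-residue linkers. IR/DR
transposase-binding elements are synthetic 40-mers flanking the
cassette. The furin–SGSG–P2A junction is spelled RAKR / SGSG /
ATNFSLLKQAGDVEENPGP with fixed codons, configurable through the
library's `elements` map.

Users with real germline data load it through `load_segments` (FASTA
plus a TSV sidecar of gene, allele, class, anchor, frame offset); the
anchor-codon invariants are enforced on load, with all offenders
reported at once.

## Read simulation

Reads emulate the final pooled product of the combinatorially barcoded
multiplex protocol as a single merged read:

    5' barcode (8 nt) · V pre-anchor tail (40 nt) · CDR3 · J remainder (30 nt) · C stub (20 nt) · 3' barcode (8 nt)

Wells are addressed by the (row, column) barcode pair; barcodes are
greedily sampled per seed under a pairwise Hamming distance ≥ 3 within
each side, since the published oligo sequences are not available and the
algorithmic content is the combinatorial labeling, not the letters.
Errors are i.i.d. substitutions at a configurable per-base rate over
the whole read (indels are not simulated; the default error rate in
demos is 0, the documented regime for exact-recovery guarantees).
Quality strings are constant Q40. Each planted chain emits exactly
`reads_per_chain` reads; a fixed seed gives byte-identical FASTQ.
The simulator emits truth metadata (well, chain, clonotype) to a
sidecar used only by tests.

The defaults — 96 wells, 8-nt barcodes, 50 reads per chain — are the
demo study conditions; `reads_per_chain` trades runtime for redundancy
and anything ≥ `min_reads` preserves the error-free recovery property.

## Clonotype calling

* **Demultiplexing**: a read is assigned to the unique well whose
  barcode pair lies within `max_mismatch` (default 1) per side;
  ambiguous or distant reads are binned as unassigned, never fatal.
  With the default distance-3 scheme, `max_mismatch = 1` is below half
  the minimum pairwise distance, so assignment is unambiguous by
  construction.
* **V assignment**: nearest germline by Hamming distance of the read's
  leading 20 bases against each V's pre-anchor region (exact substring
  fast path, sliding-window fallback). Hits above 25 % mismatch are
  noise; ties return no call. Alignment-free matching is sufficient at
  fixture divergence and is property-tested; swapping in an aligner for
  real data is a user-level extension.
* **CDR3 extraction**: the germline J remainder is located in the read
  (exact, then best-approximate within 3 mismatches; ties reject); the
  junction is the span from the V anchor position to the start of the
  remainder. Junctions shorter than two codons are rejected.
* **Consensus and pairing**: per well, identical (chain, V, J, CDR3)
  calls accumulate read support; chains need `min_reads` (default 5)
  support. A second same-type productive chain at ≥ `dual_fraction`
  (default 0.2) of the top chain's support marks a dual-α/β well.
  Wells with exactly one productive α and one productive β pair;
  dual wells deliberately do not, since the pairing is ambiguous.
  Clonotypes deduplicate across wells on (V, J, CDR3 nt) of both
  chains. The published protocol does not describe its consensus rules;
  these two thresholds are exposed configuration with documented
  defaults. Dual-chain rates are reported via `rate_percent`.

## Gibson engine

Fragments are dsDNA with top-strand sequence, topology, and end
descriptors (blunt, 5' or 3' overhang with the single-stranded
sequence). Digestion follows each enzyme's cut geometry on both strands
(EcoRV and FspI blunt; NotI leaves 4-nt 5' overhangs); a circular
substrate with k sites yields k linear pieces, a linear one k+1.
`blunt_ends` removes overhangs, mirroring mung-bean nuclease treatment.

Assembly is exact-match terminal-homology merging: homologies of at
least `min_hom` (default 15) bases are searched only in the outermost
`2 × min_hom` window of each fragment end, in either orientation, and
the longest match per end pair wins. The solver does a DFS over the
junction graph of oriented fragments, enumerates every circular closure
using all fragments, and compares products up to rotation and reverse
complement (lexicographically minimal rotation of the sequence or its
reverse complement). No closure raises "incomplete assembly"; more than
one distinct closure raises "ambiguous assembly" listing the
alternatives — an assembly is only returned with a uniqueness proof.
Real Gibson chemistry tolerates mismatched overlaps; exactness was
chosen because no tolerance is published and it keeps a brute-force
permutation × orientation enumerator viable as an independent oracle
(the test suite runs 200 randomized agreement checks). Internal
(non-terminal) homologies are ignored — a documented limitation.

## Construct design and validation

The cassette order TRAV → CDR3α → TRAJ remainder → TRAC →
furin-SGSG-P2A → TRBV → CDR3β → TRBJ remainder → TRBC2 is fixed by the
two library designs. The J remainder travels on the CDR3 fragment
because backbones are indexed by V only while J varies per clonotype.
Each CDR3 fragment duplex is 15-bp upstream homology + junction +
J remainder + 15-bp downstream homology; with the synthetic fixtures
this lands near 95–110 bp (a hard cap of 200 bp is the only enforced
size constraint). The two oligos split at `ceil((L + anneal_len) / 2)`
so their 3' overlap is exactly `anneal_len` (default 15) and their
lengths differ by at most one base, the tie going to the top oligo.
Junction CDR3s containing an EcoRV or FspI site trigger a
re-linearization-hazard warning but are not rejected.

Validation rotates the assembled circle to the TRAV start, then checks:
one ORF from the TRAV ATG to the TRBC2 stop with no premature stop;
the α and β CDR3 peptides each exactly once in the translation; exactly
one furin-SGSG-P2A junction peptide; both IR/DR elements present once
and flanking the cassette. All findings are report booleans — nothing
raises — so negative controls (deleted P2A, out-of-frame junctions)
read out as failed fields. Both `anneal_len` and `hom_len` round-trip
across [15, 40] (property-tested).

## HLA utilities

Primer annealing is an exact IUPAC-compatible match of the full
uppercase portion; lowercase Gibson tails never anneal and are carried
verbatim into predicted amplicons (one product per forward-plus /
reverse-minus hit pair in orientation, capped by `max_product`).
`iupac_matches` and `expand_degenerate` are cross-checked against each
other as oracle and implementation. Consensus guide discovery collects
every protospacer (default 19 nt, bounds 17–23) immediately followed by
a PAM match (default NGG) on either strand of the first template and
keeps those literally present, with PAM, in all templates. Packaged toy
alleles are synthetic and labeled as such; they embed the real
consensus protospacer and primer sites so the end-to-end path is
exercised without bundling HLA data.

## Assay arithmetic

Promoter coordinates follow the biology convention with no position 0:
an interval spanning the TSS counts `|start| + end` bases (hence
−319..+46 → 365 and −1800..+119 → 1919); same-sign intervals count
inclusively. `rate_percent` rounds half-away-from-zero; note that 1/86
is 1.1627…, which this convention reports as 1.2 even though truncation
would print 1.1 — the convention is documented precisely because the
two disagree on that value. Specific lysis is reported as-is, including
values below 0 or above 100. Flow-cytometry summaries are limited to a
threshold fraction and a mean; no compensation or gating trees.

## Numerical and degenerate-input choices

Seeds feed `numpy.random.default_rng` exclusively; every generator is
byte-deterministic per seed. Ties are rejections, not guesses: tied V
candidates, tied J matches and equidistant barcodes all produce "no
call" rather than an arbitrary winner. Empty inputs (empty FASTA, empty
plate, zero-site digests without `require_cut`) are valid and return
empty results; genuinely contradictory inputs (annotation missing,
anchors not translating to C/F/W, inconsistent nt/aa junction pairs)
raise immediately with the offending record named.

## What passing tests do and do not show

The synthetic generator reproduces the combinatorial and sequence
structure of the protocol — barcode geometry, read layout, junction
anchoring, fragment homologies — but not PCR amplification bias,
chimeric reads, indel errors, quality-score structure, allele
polymorphism or cross-well contamination. Exact recovery at error rate
0 and robustness at ~1 % substitutions therefore validate the
algorithms and their bookkeeping, not performance on real MiSeq data.
Likewise the Gibson model proves sequence-level closure uniqueness, not
reaction efficiency. TRBD assignment is not attempted (junction reads
rarely determine it); the field is carried through tables as blank.
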