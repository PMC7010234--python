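# tcrforge

Desk-scale toolkit for the in-silico core of a rapid T-cell receptor
discovery-and-engineering workflow: recovering paired TCRαβ CDR3
junctions from single T cells sorted into barcoded 96-well plates, and
turning each recovered clonotype into a full-length TCRαβ gene carried
on a *Sleeping Beauty* (SB) transposon plasmid by simulated Gibson
assembly — plus the surrounding HLA cloning, CRISPR consensus-guide and
assay-arithmetic utilities.

It is written for immunologists and genome engineers who want to
prototype, audit or teach this kind of pipeline without touching a wet
lab: every sequencing, cloning and validation step is modeled explicitly
and checked against independent brute-force oracles.

## What it computes

**Paired clonotype calling** (`simdata`, `pairseq`). Single T cells are
sorted one per well; each well is labeled by a unique combination of a
5' row barcode and a 3' column barcode (8 nt each, pairwise Hamming
distance ≥ 3). Pooled amplicon reads of the form

    [5' barcode][V prefix][CDR3 junction][J remainder][C stub][3' barcode]

are demultiplexed (mismatch-tolerant, ambiguous reads binned), V genes
assigned by nearest germline prefix, and the CDR3 junction extracted
anchor-inclusively — from the conserved V-region cysteine codon through
the conserved J-region phenylalanine/tryptophan codon, located via the
germline J remainder. Per well, reads collapse into supported chains; a
well with exactly one productive α and one productive β yields a paired
clonotype, and clonotypes are deduplicated across wells. Dual-α/β wells
are flagged and reported as rates.

**Construct assembly** (`germline`, `construct_design`,
`gibson_engine`). Each clonotype is built from exactly 4 fragments: a
TRAV–TRBC2 vector and a TRAC–furin-SGSG-P2A–TRBV insert (both
linearized from backbone plasmids by the blunt cutters EcoRV and FspI),
plus one CDR3 gene fragment per chain, each made of two synthetic
oligos whose 3' ends anneal over 15 bp and which carry 15-bp terminal
homologies copied from the abutting fragment ends. Gibson assembly is
modeled as exact terminal-homology merging with a uniqueness proof: the
solver enumerates all closures over fragment orders and orientations
and refuses ambiguous assemblies. The product is validated as a single
ORF (TRAV → CDR3α → TRAJ remainder → TRAC → furin-SGSG-P2A → TRBV →
CDR3β → TRBJ remainder → TRBC2) with both CDR3 peptides and the P2A
junction present exactly once and IR/DR transposase-binding elements
flanking the cassette.

**HLA utilities** (`hla_tools`). IUPAC degenerate-primer in-silico PCR
(lowercase Gibson tails, uppercase locus-specific annealing) and
consensus CRISPR protospacer discovery across allele sets (default
19-nt protospacer + NGG PAM).

**Assay arithmetic** (`assaymath`). Specific lysis
`100 × (experimental − spontaneous) / (maximum − spontaneous)`,
promoter interval lengths in transcription-start-site coordinates
(no position 0), half-away-from-zero rate percentages, and
threshold/mean event summaries.

The package carries a curated table of ten CMVpp65/HLA-A2-specific
paired clonotypes (CMV1–CMV10) used throughout as demo input and test
reference. Germline segments and backbone plasmids are synthetic
fixtures generated deterministically at run time; real germline FASTA
can be supplied with an annotation sidecar.

## Worked example

```sh
python examples/01_discover_clonotypes.py
```

```
simulated 1200 reads from 12 occupied wells
assigned 1200, unassigned 0
unique paired clonotypes: 10  (12 wells collapse to 10 by cross-well deduplication)
  TCR1  TRAV3    /TRAJ26  CAVYYGQNFVF        TRBV28   /TRBJ1-1  CASSNQGYTEAFF
  ...
summary: {'analyzed_wells': 12, 'paired_wells': 12, 'unique_clonotypes': 10, ...}
```

Twelve occupied wells (ten distinct clonotypes, two replated) produce
1200 reads at 50 reads per chain; the caller recovers all ten unique
pairs and no spurious ones. Building one of them:

```sh
python examples/02_assemble_construct.py
```

```
CMV1: 4 fragments
  TRAV3-TRBC2 vector          436 bp
  CDR3a_CMV1                   93 bp
  TRAC-TRBV28 insert          237 bp
  CDR3b_CMV1                   99 bp
oligo 3' overlap: 15 bp
circular product: 805 bp (= 865 fragment bp - 4 junctions x 15 bp)
validation: ValidationReport(orf_ok=True, cdr3a_match=True, cdr3b_match=True,
            p2a_junction_ok=True, premature_stop=False, irdr_flank_ok=True)
```

The four fragments close into one circle whose length is exactly the
fragment total minus the four 15-bp junction homologies, and every
validation check passes. `examples/03_hla_cloning.py` and
`examples/04_assay_arithmetic.py` demonstrate the HLA and assay
utilities the same way.

A thin CLI wraps the same library calls:

```sh
tcrforge run --seed 1 --outdir demo_run     # simulate -> call -> design -> assemble
tcrforge hla guide-find alleles.fasta
tcrforge stats lysis plate.csv
```

## Layout

```
src/tcrforge/     germline, simdata, pairseq, gibson_engine,
                  construct_design, hla_tools, assaymath, datasets, cli
examples/         one narrative script per capability
tests/            pytest suite incl. brute-force oracle properties
docs/methods.md   models, conventions, parameters, limitations
```
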