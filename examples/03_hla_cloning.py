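"""HLA locus cloning and consensus CRISPR guide discovery.

Builds six synthetic HLA-A-like alleles (real allele sequences are not
bundled), finds the protospacer+PAM shared by all of them — the class I
consensus target — and runs in-silico PCR with the degenerate HLA-A
primer pair, whose lowercase tails make the amplicon Gibson-ready for an
EcoRV/NotI-linearized, mung-bean-blunted lentivirus vector.
"""

from tcrforge.datasets import load_hla_primers, make_toy_hla_alleles
from tcrforge.gibson_engine import ECORV, NOTI, DnaFragment, blunt_ends, digest
from tcrforge.hla_tools import expand_degenerate, find_consensus_guides, in_silico_pcr

alleles = make_toy_hla_alleles(n=6, seed=1)
hits = find_consensus_guides(alleles, proto_len=19, pam="NGG")
print(f"protospacers shared by all {len(alleles)} alleles:")
for h in hits:
    print(f"  {h.protospacer}[{h.pam}] at {h.positions[0]}")

primers = load_hla_primers()
fwd, rev = primers["HLA-A_fwd"], primers["HLA-A_rev"]
print(f"\nHLA-A forward primer: {fwd.sequence}")
print(f"  (tail {len(fwd.tail)} nt, annealing {len(fwd.annealing)} nt, "
      f"{len(expand_degenerate(fwd.annealing))} concrete expansions)")

amps = in_silico_pcr(alleles[0], fwd, rev)
print(f"amplicons on allele 1: {len(amps)}; product {len(amps[0])} bp, "
      f"ends {amps[0].sequence[:8]}.../...{amps[0].sequence[-8:]} (lowercase = Gibson tails)")

# the receiving vector end: cut, then blunt the NotI overhang away
vector = DnaFragment("A" * 300 + ECORV.site + "C" * 40 + NOTI.site + "G" * 300,
                     topology="circular", name="toy-lentivector")
pieces = [blunt_ends(p) for p in digest(vector, [ECORV, NOTI])]
print(f"vector digest: {len(pieces)} pieces after blunting, "
      f"lengths {[len(p) for p in pieces]}")
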