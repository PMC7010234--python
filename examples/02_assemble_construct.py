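"""Assemble one clonotype into a Sleeping Beauty TCR construct.

Designs the two CDR3 gene fragments (two oligos each, 15-bp 3' overlap),
linearizes the TRAV-TRBC2 and TRAC-TRBV backbone plasmids with EcoRV +
FspI, Gibson-assembles the four fragments and validates the resulting
circular transposon: single ORF, both CDR3 peptides present once,
furin-SGSG-P2A junction intact, IR/DR elements flanking the cassette.
"""

from tcrforge.construct_design import build_construct, oligo_order_sheet, plan_assembly
from tcrforge.datasets import load_cmv_clonotypes
from tcrforge.germline import make_fixture_library

germline, library = make_fixture_library(seed=1)
cmv1 = load_cmv_clonotypes()[0]

plan = plan_assembly(cmv1, library, germline)
print(f"{cmv1.id}: {len(plan.fragments)} fragments")
for frag in plan.fragments:
    print(f"  {frag.name:25s} {len(frag):5d} bp")
print(f"oligo 3' overlap: {plan.cdr3_alpha.measured_overlap} bp")
print(oligo_order_sheet([plan]).to_string(index=False, max_colwidth=30))

construct, plan, junctions = build_construct(cmv1, library, germline)
total = sum(len(f) for f in plan.fragments)
print(f"\ncircular product: {len(construct.sequence)} bp "
      f"(= {total} fragment bp - 4 junctions x 15 bp)")
print("junctions:", [(j.left, j.right, j.length) for j in junctions])
print("validation:", construct.report)
print("all checks pass:", construct.report.all_ok)
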