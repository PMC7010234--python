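"""Packaged data: the CMV clonotype table, HLA primers, toy alleles.

The clonotype table is the set of ten unique CMVpp65/HLA-A2-specific
paired TCRαβ CDR3 sequences recovered from a seropositive donor; it is
both a worked input (simulate -> call -> assemble round trips) and the
reference against which clonotype calling is checked.  The HLA class I
locus primers and the consensus CRISPR protospacer are the published
degenerate cloning/editing reagents.  Real HLA allele sequences are not
bundled; :func:`make_toy_hla_alleles` builds synthetic stand-in alleles
that carry the real guide site and primer annealing sites.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from ._seq import random_dna, revcomp
from .hla_tools import Primer, expand_degenerate, read_primers
from .pairseq import Clonotype, read_clonotypes

#: SpCas9 protospacer shared by the classical HLA class I loci, with PAM
HLA_CLASS_I_GUIDE = "GGCTACTACAACCAGAGCG"
HLA_CLASS_I_PAM = "AGG"


def _data_path(name: str):
    return resources.files("tcrforge").joinpath("data", name)


def load_cmv_clonotypes() -> list[Clonotype]:
    """The ten packaged CMV-specific paired clonotypes (CMV1..CMV10)."""
    with resources.as_file(_data_path("cmv_clonotypes.tsv")) as path:
        return read_clonotypes(path)


def load_hla_primers() -> dict[str, Primer]:
    """Locus-specific HLA class I cloning primers with lowercase Gibson
    tails and uppercase (degenerate) annealing portions."""
    with resources.as_file(_data_path("hla_primers.tsv")) as path:
        return read_primers(path)


def make_toy_hla_alleles(
    n: int = 6, length: int = 600, seed: int = 0, locus: str = "HLA-A"
) -> list[str]:
    """Synthetic HLA-like allele sequences (NOT real HLA data).

    Each allele embeds, at shared positions, one concrete expansion of
    the locus forward-primer annealing site, the class-I consensus
    protospacer+PAM, and the reverse-primer annealing site — enough to
    exercise in-silico PCR and consensus guide discovery end to end.
    """
    primers = load_hla_primers()
    fwd = primers[f"{locus}_fwd"]
    rev = primers[f"{locus}_rev"]
    fwd_options = expand_degenerate(fwd.annealing)
    rev_options = expand_degenerate(rev.annealing)
    guide_site = HLA_CLASS_I_GUIDE + HLA_CLASS_I_PAM
    forbidden = (guide_site,)
    rng = np.random.default_rng(seed)
    alleles = []
    for _ in range(n):
        fwd_site = fwd_options[int(rng.integers(0, len(fwd_options)))]
        rev_site = rev_options[int(rng.integers(0, len(rev_options)))]
        core = (
            random_dna(rng, 60, forbidden)
            + fwd_site
            + random_dna(rng, 120, forbidden)
            + guide_site
            + random_dna(rng, 150, forbidden)
            + revcomp(rev_site)
        )
        pad = max(0, length - len(core) - 40)
        alleles.append(random_dna(rng, 40, forbidden) + core + random_dna(rng, pad, forbidden))
    return alleles
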