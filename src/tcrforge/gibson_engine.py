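"""In-silico restriction digestion, end blunting, and Gibson assembly.

This module is the computational core shared by the TCR / Sleeping Beauty
construct builder and the HLA lentivirus cloning utilities.  It models
double-stranded DNA fragments just concretely enough to be honest about
cloning chemistry:

* restriction digestion with correct cut geometry (blunt cutters such as
  EcoRV and FspI, or 5'-overhang cutters such as NotI), on circular or
  linear substrates;
* single-strand overhang removal (mung-bean-nuclease style blunting);
* Gibson assembly as exact terminal-homology merging, with an explicit
  uniqueness proof: the solver enumerates every circular closure over all
  fragment orders and orientations and raises if the outcome is not a
  single product up to rotation and reverse complement.

Homology detection is exact-match on terminal substrings.  Real Gibson
chemistry tolerates mismatches; exactness keeps every assembly auditable
and lets a brute-force enumerator serve as an independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from ._seq import revcomp

TERMINAL_WINDOW_FACTOR = 2  # homologies searched in the outermost 2*min_hom bases


class GibsonError(Exception):
    """Base class for digestion/assembly failures."""


class DigestError(GibsonError):
    pass


class IncompleteAssemblyError(GibsonError):
    """No circular closure uses the required fragments."""


class AmbiguousAssemblyError(GibsonError):
    """More than one distinct circular product is possible."""

    def __init__(self, products: list[str]):
        self.products = products
        super().__init__(
            f"ambiguous assembly: {len(products)} distinct circular closures"
        )


@dataclass(frozen=True)
class End:
    """One terminus of a linear duplex.

    kind is 'blunt', '5_overhang' or '3_overhang'; for overhangs ``seq``
    holds the single-stranded portion written 5'->3' on its own strand.
    """

    kind: str = "blunt"
    seq: str = ""

    def __post_init__(self):
        if self.kind not in ("blunt", "5_overhang", "3_overhang"):
            raise ValueError(f"unknown end kind {self.kind!r}")
        if self.kind == "blunt" and self.seq:
            raise ValueError("blunt end carries no overhang sequence")

    @property
    def is_blunt(self) -> bool:
        return self.kind == "blunt"


BLUNT = End()


@dataclass(frozen=True)
class DnaFragment:
    """A dsDNA molecule: top-strand span plus topology and end descriptors.

    For fragments with overhanging ends the ``sequence`` string covers the
    full physical span (single-stranded tails included); the ``end5`` /
    ``end3`` descriptors say how many terminal bases are single-stranded.
    """

    sequence: str
    topology: str = "linear"  # 'linear' | 'circular'
    end5: End = BLUNT
    end3: End = BLUNT
    name: str = ""

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "circular" and not (self.end5.is_blunt and self.end3.is_blunt):
            raise ValueError("circular fragments have no end descriptors")
        for end in (self.end5, self.end3):
            if len(end.seq) >= max(len(self.sequence), 1):
                raise ValueError("overhang length must be below fragment length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_blunt(self) -> bool:
        return self.end5.is_blunt and self.end3.is_blunt

    def reverse_complement(self) -> "DnaFragment":
        return replace(
            self,
            sequence=revcomp(self.sequence),
            end5=self.end3,
            end3=self.end5,
        )


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site plus strand cut offsets.

    ``cut_top``/``cut_bottom`` are offsets from the site start at which the
    top and bottom strands are severed.  Equal offsets give a blunt cut;
    cut_top < cut_bottom leaves 5' overhangs.
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    @property
    def is_palindromic(self) -> bool:
        return self.site == revcomp(self.site)


ECORV = Enzyme("EcoRV", "GATATC", 3, 3)
FSPI = Enzyme("FspI", "TGCGCA", 3, 3)
NOTI = Enzyme("NotI", "GCGGCCGC", 2, 6)

ENZYMES = {e.name: e for e in (ECORV, FSPI, NOTI)}


def _find_cuts(seq: str, enzymes: list[Enzyme], circular: bool) -> list[tuple[int, int]]:
    """All (top, bottom) cut coordinates, both strands, sorted by position."""
    n = len(seq)
    search = seq + seq[: max(len(e.site) for e in enzymes) - 1] if circular and seq else seq
    cuts: set[tuple[int, int]] = set()
    for enz in enzymes:
        sites = [enz.site]
        if not enz.is_palindromic:
            sites.append(revcomp(enz.site))
        for k, site in enumerate(sites):
            start = 0
            while True:
                s = search.find(site, start)
                if s == -1 or (circular and s >= n):
                    break
                if k == 0:
                    t, b = s + enz.cut_top, s + enz.cut_bottom
                else:  # site on bottom strand: mirror the offsets
                    t = s + len(site) - enz.cut_bottom
                    b = s + len(site) - enz.cut_top
                if circular:
                    shift = t % n - t
                    t, b = t + shift, b + shift
                    cuts.add((t, b))
                elif 0 <= min(t, b) and max(t, b) <= n:
                    cuts.add((t, b))
                start = s + 1
    return sorted(cuts)


def _ends_at_cut(seq2: str, t: int, b: int) -> tuple[End, End]:
    """(right end of the left piece, left end of the right piece) at a cut."""
    if t == b:
        return BLUNT, BLUNT
    if b > t:  # 5' overhangs on both new ends
        top = seq2[t:b]
        return End("5_overhang", revcomp(top)), End("5_overhang", top)
    top = seq2[b:t]  # t > b: 3' overhangs
    return End("3_overhang", top), End("3_overhang", revcomp(top))


def digest(
    fragment: DnaFragment, enzymes: list[Enzyme], require_cut: bool = False
) -> list[DnaFragment]:
    """Cut a fragment with one or more enzymes.

    A circular substrate with k recognition sites yields k linear pieces;
    a linear substrate yields k+1.  End descriptors on the new termini
    follow each enzyme's cut geometry.
    """
    seq = fragment.sequence
    circular = fragment.topology == "circular"
    cuts = _find_cuts(seq, enzymes, circular)
    if not cuts:
        if require_cut:
            raise DigestError(
                f"no recognition site for {[e.name for e in enzymes]} in "
                f"fragment {fragment.name or '<unnamed>'}"
            )
        return [fragment]

    seq2 = seq + seq  # uniform wrap-around indexing
    pieces: list[DnaFragment] = []
    if circular:
        for i, (t, b) in enumerate(cuts):
            t2, b2 = cuts[(i + 1) % len(cuts)]
            if (t2, b2) <= (t, b):
                t2, b2 = t2 + len(seq), b2 + len(seq)
            _, left_end = _ends_at_cut(seq2, t, b)
            right_end, _ = _ends_at_cut(seq2, t2, b2)
            pieces.append(
                DnaFragment(
                    sequence=seq2[min(t, b): max(t2, b2)],
                    end5=left_end,
                    end3=right_end,
                    name=f"{fragment.name}_frag{i + 1}" if fragment.name else "",
                )
            )
    else:
        prev_left = fragment.end5
        prev_t, prev_b = 0, 0
        for i, (t, b) in enumerate(cuts + [(len(seq), len(seq))]):
            if (t, b) == (len(seq), len(seq)):
                right_end = fragment.end3
            else:
                right_end, next_left = _ends_at_cut(seq2, t, b)
            pieces.append(
                DnaFragment(
                    sequence=seq[min(prev_t, prev_b): max(t, b)],
                    end5=prev_left,
                    end3=right_end,
                    name=f"{fragment.name}_frag{i + 1}" if fragment.name else "",
                )
            )
            if (t, b) != (len(seq), len(seq)):
                prev_left = next_left
                prev_t, prev_b = t, b
    return pieces


def blunt_ends(fragment: DnaFragment) -> DnaFragment:
    """Remove single-strand overhangs (mung-bean nuclease arithmetic)."""
    if fragment.topology == "circular":
        raise GibsonError("cannot blunt a circular molecule")
    seq = fragment.sequence
    lo = len(fragment.end5.seq)
    hi = len(seq) - len(fragment.end3.seq)
    return replace(fragment, sequence=seq[lo:hi], end5=BLUNT, end3=BLUNT)


@dataclass(frozen=True)
class Junction:
    """One resolved Gibson junction in the assembled circle."""

    left: str
    right: str
    homology: str

    @property
    def length(self) -> int:
        return len(self.homology)


def _terminal_homology(left_seq: str, right_seq: str, min_hom: int) -> int:
    """Longest k with suffix_k(left) == prefix_k(right), within the terminal
    search window; 0 when no homology of at least min_hom exists."""
    window = min(TERMINAL_WINDOW_FACTOR * min_hom, len(left_seq), len(right_seq))
    for k in range(window, min_hom - 1, -1):
        if left_seq[-k:] == right_seq[:k]:
            return k
    return 0


def canonical_circular(seq: str) -> str:
    """Lexicographically minimal rotation of min(seq, revcomp(seq))."""
    best = None
    for s in (seq.upper(), revcomp(seq.upper())):
        doubled = s + s
        for i in range(len(s)):
            cand = doubled[i: i + len(s)]
            if best is None or cand < best:
                best = cand
    return best or ""


def canonical_circular_equal(a: str, b: str) -> bool:
    """True iff two circular sequences match under rotation and/or
    reverse complement."""
    if len(a) != len(b):
        return False
    return canonical_circular(a) == canonical_circular(b)


def _closures_for(
    oriented: dict[tuple[int, int], str],
    indices: tuple[int, ...],
    min_hom: int,
) -> list[tuple[str, list[Junction], list[tuple[int, int]]]]:
    """Enumerate circular closures over a fragment subset via the junction
    graph (DFS over oriented fragments with homology-edge pruning)."""
    start = (indices[0], +1)  # global orientation fixed by the first fragment
    results = []

    def product_of(cycle: list[tuple[int, int]]) -> tuple[str, list[Junction]] | None:
        parts, juncs = [], []
        for pos, node in enumerate(cycle):
            nxt = cycle[(pos + 1) % len(cycle)]
            k = _terminal_homology(oriented[node], oriented[nxt], min_hom)
            if k == 0:
                return None
            parts.append(oriented[node][: len(oriented[node]) - k])
            juncs.append(
                Junction(
                    left=f"{node[0]}{'+' if node[1] > 0 else '-'}",
                    right=f"{nxt[0]}{'+' if nxt[1] > 0 else '-'}",
                    homology=oriented[node][-k:],
                )
            )
        return "".join(parts), juncs

    def dfs(path: list[tuple[int, int]], used: set[int]):
        if len(path) == len(indices):
            out = product_of(path)
            if out is not None:
                results.append((out[0], out[1], list(path)))
            return
        for idx in indices:
            if idx in used:
                continue
            for ori in (+1, -1):
                node = (idx, ori)
                if _terminal_homology(oriented[path[-1]], oriented[node], min_hom):
                    path.append(node)
                    used.add(idx)
                    dfs(path, used)
                    used.discard(idx)
                    path.pop()

    dfs([start], {indices[0]})
    return results


def enumerate_closures(
    fragments: list[DnaFragment], min_hom: int = 15
) -> dict[str, tuple[str, list[Junction]]]:
    """All distinct circular closures using every fragment, keyed by
    canonical (rotation/reverse-complement invariant) product sequence."""
    oriented = {}
    for i, f in enumerate(fragments):
        oriented[(i, +1)] = f.sequence.upper()
        oriented[(i, -1)] = revcomp(f.sequence.upper())
    found: dict[str, tuple[str, list[Junction]]] = {}
    for product, juncs, _cycle in _closures_for(
        oriented, tuple(range(len(fragments))), min_hom
    ):
        found.setdefault(canonical_circular(product), (product, juncs))
    return found


def assemble(
    fragments: list[DnaFragment],
    min_hom: int = 15,
    allow_unused: bool = False,
) -> tuple[DnaFragment, list[Junction]]:
    """Gibson-assemble linear fragments into a unique circular product.

    Terminal homologies of at least ``min_hom`` bases are merged once per
    junction, in either fragment orientation and any order.  The result is
    independent of input permutation and of reverse-complementing any
    fragment.  Raises :class:`IncompleteAssemblyError` when no circular
    closure exists over the required fragment set, and
    :class:`AmbiguousAssemblyError` when more than one distinct product
    (up to rotation/reverse complement) is possible.  With
    ``allow_unused``, maximal fragment subsets are tried instead.
    """
    if min_hom < 8:
        raise ValueError("min_hom must be at least 8")
    if not fragments:
        raise ValueError("no fragments given")
    for f in fragments:
        if f.topology != "linear":
            raise GibsonError("assembly substrates must be linear (digest first)")
        if not f.is_blunt:
            raise GibsonError(
                f"fragment {f.name or '<unnamed>'} has single-strand overhangs; "
                "apply blunt_ends first"
            )

    oriented = {}
    for i, f in enumerate(fragments):
        oriented[(i, +1)] = f.sequence.upper()
        oriented[(i, -1)] = revcomp(f.sequence.upper())

    sizes = [len(fragments)] if not allow_unused else range(len(fragments), 0, -1)
    for size in sizes:
        found: dict[str, tuple[str, list[Junction]]] = {}
        for subset in itertools.combinations(range(len(fragments)), size):
            for product, juncs, _cycle in _closures_for(oriented, subset, min_hom):
                found.setdefault(canonical_circular(product), (product, juncs))
        # closures collected per subset size; larger subsets win
        if found:
            if len(found) > 1:
                raise AmbiguousAssemblyError(sorted(found))
            product, juncs = next(iter(found.values()))
            names = [f.name or f"fragment_{i}" for i, f in enumerate(fragments)]
            juncs = [
                Junction(
                    left=_pretty(j.left, names),
                    right=_pretty(j.right, names),
                    homology=j.homology,
                )
                for j in juncs
            ]
            return DnaFragment(sequence=product, topology="circular", name="assembly"), juncs
    raise IncompleteAssemblyError("incomplete assembly: no circular closure found")


def _pretty(node: str, names: list[str]) -> str:
    idx, ori = int(node[:-1]), node[-1]
    return f"{names[idx]}({ori})"
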