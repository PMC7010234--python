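"""Digestion geometry, blunting, and the Gibson closure solver."""

import itertools

import numpy as np
import pytest

from tcrforge._seq import revcomp
from tcrforge.gibson_engine import (
    ECORV,
    FSPI,
    NOTI,
    AmbiguousAssemblyError,
    DigestError,
    DnaFragment,
    GibsonError,
    IncompleteAssemblyError,
    assemble,
    blunt_ends,
    canonical_circular,
    canonical_circular_equal,
    digest,
    enumerate_closures,
)


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestDigest:
    def test_single_cut_circle_yields_one_full_length_linear(self):
        circle = DnaFragment("AAAA" + ECORV.site + "CCCCGGGGTTTT", topology="circular")
        pieces = digest(circle, [ECORV])
        assert len(pieces) == 1
        assert pieces[0].topology == "linear" and pieces[0].is_blunt
        assert len(pieces[0]) == len(circle)
        assert canonical_circular_equal(pieces[0].sequence, circle.sequence)

    def test_linear_with_k_sites_yields_k_plus_one(self):
        seq = "AAA" + ECORV.site + "CCC" + ECORV.site + "GGG"
        pieces = digest(DnaFragment(seq), [ECORV])
        assert [p.sequence for p in pieces] == ["AAAGAT", "ATCCCCGAT", "ATCGGG"]

    def test_noti_leaves_complementary_four_base_5prime_overhangs(self):
        seq = "AAAAAAAAAA" + NOTI.site + "TTTTTTTTTT"
        left, right = digest(DnaFragment(seq), [NOTI])
        assert left.end3.kind == "5_overhang" and right.end5.kind == "5_overhang"
        assert left.end3.seq == right.end5.seq == "GGCC"
        assert left.end3.seq == revcomp(right.end5.seq)  # palindromic overhang

    def test_blunting_removes_overhangs(self):
        seq = "AAAAAAAAAA" + NOTI.site + "TTTTTTTTTT"
        left, right = digest(DnaFragment(seq), [NOTI])
        for piece in (left, right):
            blunted = blunt_ends(piece)
            assert blunted.is_blunt
            assert len(blunted) == len(piece) - 4

    def test_blunting_is_a_fixpoint_on_blunt_input(self):
        frag = DnaFragment("ACGTACGTACGT")
        assert blunt_ends(frag) == frag

    def test_blunting_trims_both_overhanging_ends(self):
        seq = NOTI.site + "A" * 20 + NOTI.site
        pieces = digest(DnaFragment(seq), [NOTI])
        middle = pieces[1]
        assert middle.end5.kind == middle.end3.kind == "5_overhang"
        assert len(blunt_ends(middle)) == len(middle) - 8

    def test_blunting_circular_raises(self):
        with pytest.raises(GibsonError):
            blunt_ends(DnaFragment("ACGTACGT", topology="circular"))

    def test_require_cut(self):
        frag = DnaFragment("ACGTACGTACGT")
        with pytest.raises(DigestError):
            digest(frag, [ECORV], require_cut=True)
        assert digest(frag, [ECORV]) == [frag]

    def test_site_on_bottom_strand_is_found(self):
        # EcoRV is palindromic; plant an asymmetric enzyme's site reversed
        seq = "AAAAAAAAAA" + revcomp(NOTI.site) + "TTTTTTTTTT"
        assert len(digest(DnaFragment(seq), [NOTI])) == 2


class TestAssemble:
    def test_two_fragment_closure_merges_each_homology_once(self):
        rng = np.random.default_rng(0)
        h1, h2 = _random_dna(rng, 15), _random_dna(rng, 15)
        x, y = _random_dna(rng, 30), _random_dna(rng, 25)
        a = DnaFragment(h1 + x + h2, name="a")
        b = DnaFragment(h2 + y + h1, name="b")
        product, junctions = assemble([a, b], min_hom=15)
        assert product.topology == "circular"
        assert len(product) == len(a) + len(b) - 2 * 15
        assert len(junctions) == 2
        assert all(j.length == 15 for j in junctions)

    def test_permutation_and_orientation_invariance(self):
        rng = np.random.default_rng(1)
        homs = [_random_dna(rng, 16) for _ in range(4)]
        frags = [
            DnaFragment(homs[i] + _random_dna(rng, 30) + homs[(i + 1) % 4], name=f"f{i}")
            for i in range(4)
        ]
        reference, _ = assemble(frags, min_hom=15)
        for perm in itertools.permutations(range(4)):
            shuffled = [frags[i] for i in perm]
            shuffled[perm[0] % 4] = shuffled[perm[0] % 4].reverse_complement()
            product, _ = assemble(shuffled, min_hom=15)
            assert canonical_circular_equal(product.sequence, reference.sequence)

    def test_self_circularization_of_single_fragment(self):
        rng = np.random.default_rng(2)
        h = _random_dna(rng, 15)
        frag = DnaFragment(h + _random_dna(rng, 50) + h)
        product, junctions = assemble([frag], min_hom=15)
        assert len(product) == len(frag) - 15
        assert len(junctions) == 1

    def test_incomplete_assembly_raises(self):
        rng = np.random.default_rng(3)
        a = DnaFragment(_random_dna(rng, 40))
        b = DnaFragment(_random_dna(rng, 40))
        with pytest.raises(IncompleteAssemblyError):
            assemble([a, b], min_hom=15)

    def test_ambiguous_assembly_lists_alternatives(self):
        """A partner whose insert can close in either orientation gives two
        distinct circular products; the solver must refuse to choose."""
        rng = np.random.default_rng(4)
        h = _random_dna(rng, 15)
        x, y = _random_dna(rng, 30), _random_dna(rng, 30)
        a = DnaFragment(revcomp(h) + x + h, name="a")
        b = DnaFragment(h + y + revcomp(h), name="b")
        with pytest.raises(AmbiguousAssemblyError) as err:
            assemble([a, b], min_hom=15)
        assert len(err.value.products) == 2

    def test_overhanging_fragments_rejected(self):
        seq = "AAAAAAAAAA" + NOTI.site + "TTTTTTTTTT"
        pieces = digest(DnaFragment(seq), [NOTI])
        with pytest.raises(GibsonError, match="blunt"):
            assemble(pieces, min_hom=8)

    def test_digest_then_reclose_reconstructs_plasmid(self):
        """Cut a single-site plasmid, add a re-closing terminal homology,
        and self-circularization reproduces the original sequence."""
        rng = np.random.default_rng(5)
        plasmid = DnaFragment(
            _random_dna(rng, 80) + ECORV.site + _random_dna(rng, 80),
            topology="circular",
        )
        (linear,) = digest(plasmid, [ECORV])
        extended = DnaFragment(linear.sequence + linear.sequence[:15])
        reclosed, _ = assemble([extended], min_hom=15)
        assert canonical_circular_equal(reclosed.sequence, plasmid.sequence)

    def test_allow_unused_prefers_maximal_subsets(self):
        rng = np.random.default_rng(6)
        h1, h2 = _random_dna(rng, 15), _random_dna(rng, 15)
        a = DnaFragment(h1 + _random_dna(rng, 30) + h2, name="a")
        b = DnaFragment(h2 + _random_dna(rng, 30) + h1, name="b")
        orphan = DnaFragment(_random_dna(rng, 40), name="orphan")
        with pytest.raises(IncompleteAssemblyError):
            assemble([a, b, orphan], min_hom=15)
        product, _ = assemble([a, b, orphan], min_hom=15, allow_unused=True)
        assert len(product) == len(a) + len(b) - 30


class TestCanonicalCircular:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ATGC", "GCAT", True),        # rotation
            ("ATGC", revcomp("GCAT"), True),  # reverse complement of a rotation
            ("ATGC", "ATGA", False),
            ("AAAA", "AAAT", False),
        ],
    )
    def test_equality(self, a, b, expected):
        assert canonical_circular_equal(a, b) is expected

    def test_canonical_form_is_rotation_invariant(self):
        seq = "ATCGGATCCA"
        for i in range(len(seq)):
            rotated = seq[i:] + seq[:i]
            assert canonical_circular(rotated) == canonical_circular(seq)


# ---------------------------------------------------------------------------
# independent brute-force oracle


def brute_force_closures(fragments, min_hom):
    """Enumerate circular products over ALL permutations and orientation
    vectors by direct string checks (independent of the junction-graph
    solver)."""
    window = 2 * min_hom

    def overlap(left, right):
        best = 0
        for k in range(min_hom, min(window, len(left), len(right)) + 1):
            if left[-k:] == right[:k]:
                best = k
        return best

    products = set()
    n = len(fragments)
    for perm in itertools.permutations(range(n)):
        for orient in itertools.product((0, 1), repeat=n):
            seqs = [
                fragments[i].sequence if o == 0 else revcomp(fragments[i].sequence)
                for i, o in zip(perm, orient)
            ]
            ks = [overlap(seqs[i], seqs[(i + 1) % n]) for i in range(n)]
            if all(k > 0 for k in ks):
                product = "".join(s[: len(s) - k] for s, k in zip(seqs, ks))
                products.add(canonical_circular(product))
    return products


def _random_instance(rng):
    """Random fragment set with planted circular homologies; occasionally
    a repeated homology to provoke ambiguity."""
    n = int(rng.integers(2, 6))
    min_hom = 8
    homs = [_random_dna(rng, int(rng.integers(min_hom, 13))) for _ in range(n)]
    if n >= 3 and rng.random() < 0.3:
        homs[1] = homs[0]  # repeated junction: possible ambiguity
    frags = []
    for i in range(n):
        middle = _random_dna(rng, int(rng.integers(15, 40)))
        seq = homs[i] + middle + homs[(i + 1) % n]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        frags.append(DnaFragment(seq, name=f"f{i}"))
    rng.shuffle(frags)
    return frags, min_hom


@pytest.mark.parametrize("seed", range(30))
def test_solver_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    frags, min_hom = _random_instance(rng)
    solver = set(enumerate_closures(frags, min_hom))
    oracle = brute_force_closures(frags, min_hom)
    assert solver == oracle
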