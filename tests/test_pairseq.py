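"""Demultiplexing, CDR3 extraction, pairing and clonotype calling."""

import pytest

from tcrforge.pairseq import (
    ChainCall,
    Clonotype,
    PairingError,
    assign_v_gene,
    call_clonotypes,
    call_well,
    demultiplex,
    extract_cdr3,
    run_pairing,
    translate_cdr3,
    read_clonotypes,
    write_clonotypes,
    WellCall,
)
from tcrforge.simdata import (
    BarcodeScheme,
    PlantedChain,
    PlateLayout,
    ReadRecord,
    layout_from_clonotypes,
    simulate_reads,
)


class TestTranslateCdr3:
    @pytest.mark.parametrize(
        "nt, aa",
        [
            ("TGCGCTGTATACTATGGTCAGAATTTTGTCTTT", "CAVYYGQNFVF"),
            ("TGCGCCAGCAGCCAAGGGGAGCTAGGGACTAGCGGGAGCCACGAGCAGTACTTC", "CASSQGELGTSGSHEQYF"),
            ("ATG", "M"),
            ("TGCTAATTT", "C*F"),  # stops rendered as *
        ],
    )
    def test_translation(self, nt, aa):
        assert translate_cdr3(nt) == aa

    def test_rejects_partial_codons_and_ambiguity(self):
        with pytest.raises(ValueError):
            translate_cdr3("TGCA")
        with pytest.raises(ValueError):
            translate_cdr3("TGCNNN")


def test_packaged_clonotypes_satisfy_junction_invariants(cmv_clonotypes):
    """aa junctions are the translation of nt junctions, C...F anchored."""
    assert len(cmv_clonotypes) == 10
    for ct in cmv_clonotypes:
        assert translate_cdr3(ct.cdr3a_nt) == ct.cdr3a_aa
        assert translate_cdr3(ct.cdr3b_nt) == ct.cdr3b_aa
        for aa in (ct.cdr3a_aa, ct.cdr3b_aa):
            assert aa.startswith("C") and aa.endswith("F")


def test_clonotype_rejects_inconsistent_aa():
    with pytest.raises(PairingError):
        Clonotype(
            id="X", trav="TRAV3", traj="TRAJ26",
            cdr3a_nt="TGCGCTTTT", cdr3a_aa="CAW",  # translation is CAF
            trbv="TRBV28", trbj="TRBJ1-1",
            cdr3b_nt="TGCGCTTTT", cdr3b_aa="CAF",
        )


class TestDemultiplex:
    def test_exact_and_single_mismatch_assignment(self, scheme, germ, cmv_clonotypes):
        layout = layout_from_clonotypes({"A1": cmv_clonotypes[0]})
        reads = simulate_reads(layout, scheme, germ, reads_per_chain=3, seed=0)
        by_well, unassigned = demultiplex(reads, scheme)
        assert set(by_well) == {"A1"} and not unassigned

        # one substitution in the 5' barcode stays assignable at max_mismatch=1
        r = reads[0]
        seq = list(r.sequence)
        seq[0] = "A" if seq[0] != "A" else "C"
        mutated = ReadRecord(r.id, "".join(seq), r.quality)
        by_well, unassigned = demultiplex([mutated], scheme, max_mismatch=1)
        assert set(by_well) == {"A1"} and not unassigned

    def test_equidistant_barcode_is_unassigned(self):
        # permissive scheme: distance-2 barcodes with max_mismatch=2
        permissive = BarcodeScheme(
            five_prime=("AAAAAAAA", "AAAAAACC"), three_prime=("GGGGGGGG",)
        )
        read = ReadRecord("r1", "AAAAAAAC" + "T" * 20 + "GGGGGGGG", "I" * 36)
        by_well, unassigned = demultiplex([read], permissive, max_mismatch=2)
        assert not by_well and len(unassigned) == 1

    def test_read_conservation(self, scheme, germ, cmv_clonotypes):
        layout = layout_from_clonotypes(
            {"A1": cmv_clonotypes[0], "H12": cmv_clonotypes[3]}
        )
        reads = simulate_reads(layout, scheme, germ, reads_per_chain=9,
                               error_rate=0.05, seed=2)
        by_well, unassigned = demultiplex(reads, scheme)
        assert sum(len(v) for v in by_well.values()) + len(unassigned) == len(reads)


def _insert(germ, ct, chain="alpha"):
    if chain == "alpha":
        v, j, cdr3 = germ.get(ct.trav), germ.get(ct.traj), ct.cdr3a_nt
        c = germ.c_segment("alpha")
    else:
        v, j, cdr3 = germ.get(ct.trbv), germ.get(ct.trbj), ct.cdr3b_nt
        c = germ.c_segment("beta")
    return v.pre_anchor[-40:] + cdr3 + j.post_anchor + c.sequence[:20]


class TestVAssignment:
    def test_error_free_read_hits_planted_v(self, germ, cmv_clonotypes):
        ct = cmv_clonotypes[0]
        hit = assign_v_gene(_insert(germ, ct), germ.v_segments("alpha"))
        assert hit is not None and hit.segment.name == ct.trav
        assert hit.v_end == 40

    def test_two_substitutions_still_assign(self, germ, cmv_clonotypes):
        """Brute-force check: fixtures diverge far beyond 2 mismatches."""
        ct = cmv_clonotypes[0]
        insert = list(_insert(germ, ct))
        for i in (2, 11):
            insert[i] = "A" if insert[i] != "A" else "G"
        hit = assign_v_gene("".join(insert), germ.v_segments("alpha"))
        assert hit is not None and hit.segment.name == ct.trav
        assert hit.mismatches == 2

    def test_random_sequence_assigns_nothing(self, germ):
        assert assign_v_gene("ACGT" * 30, germ.v_segments("alpha")) is None

    def test_tied_candidates_return_none(self, germ, cmv_clonotypes):
        ct = cmv_clonotypes[0]
        v = germ.get(ct.trav)
        twin = type(v)(
            name="TRAVTWIN", segment_class=v.segment_class,
            sequence=v.sequence, anchor=v.anchor, frame_offset=v.frame_offset,
        )
        assert assign_v_gene(_insert(germ, ct), [v, twin]) is None


class TestExtractCdr3:
    def test_planted_cmv1_alpha_junction(self, germ, cmv_clonotypes):
        ct = cmv_clonotypes[0]  # TRAV3 / TRAJ26
        hit = extract_cdr3(
            _insert(germ, ct), germ.get(ct.trav), germ.j_segments("alpha")
        )
        assert hit == ("TRAJ26", "TGCGCTGTATACTATGGTCAGAATTTTGTCTTT")

    def test_all_planted_junctions_recovered(self, germ, cmv_clonotypes):
        for ct in cmv_clonotypes:
            for chain in ("alpha", "beta"):
                v = germ.get(ct.trav if chain == "alpha" else ct.trbv)
                expected = (
                    (ct.traj, ct.cdr3a_nt) if chain == "alpha" else (ct.trbj, ct.cdr3b_nt)
                )
                hit = extract_cdr3(_insert(germ, ct, chain), v, germ.j_segments(chain))
                assert hit == expected, ct.id

    def test_read_without_j_suffix_returns_none(self, germ, cmv_clonotypes):
        ct = cmv_clonotypes[0]
        v = germ.get(ct.trav)
        insert = v.pre_anchor[-40:] + ct.cdr3a_nt  # J remainder missing
        assert extract_cdr3(insert, v, germ.j_segments("alpha")) is None

    def test_internal_stop_junction_extracted_but_nonproductive(self, germ):
        v = germ.get("TRAV3")
        j = germ.get("TRAJ26")
        junction = "TGCTAAGGTCAGTTT"  # C * G Q F
        insert = v.pre_anchor[-40:] + junction + j.post_anchor
        hit = extract_cdr3(insert, v, germ.j_segments("alpha"))
        assert hit == ("TRAJ26", junction)
        call = ChainCall("alpha", "TRAV3", "TRAJ26", junction, support=10)
        assert call.cdr3_aa == "C*GQF"
        assert not call.productive


class TestCallClonotypes:
    def _well(self, chains):
        wc = WellCall(well="A1")
        for chain in chains:
            (wc.alpha_chains if chain.chain_type == "alpha" else wc.beta_chains).append(chain)
        return wc

    def test_dual_alpha_flag_at_equal_support(self):
        a1 = ChainCall("alpha", "TRAV3", "TRAJ26", "TGCGCTGTATACTATGGTCAGAATTTTGTCTTT", 20)
        a2 = ChainCall("alpha", "TRAV24", "TRAJ43", "TGCGCCTTCCCGTACAATAACAATGACATGCGCTTT", 20)
        b = ChainCall("beta", "TRBV28", "TRBJ1-1", "TGCGCCAGCAGTAACCAGGGGTACACTGAAGCTTTCTTT", 20)
        wc = self._well([a1, a2, b])
        clonotypes, summary = call_clonotypes([wc])
        assert wc.dual_alpha and not wc.dual_beta
        assert summary["dual_alpha_wells"] == 1
        # >1 productive alpha: the well yields no unambiguous pair
        assert clonotypes == []

    def test_low_support_chains_dropped(self):
        a = ChainCall("alpha", "TRAV3", "TRAJ26", "TGCGCTGTATACTATGGTCAGAATTTTGTCTTT", 3)
        wc = self._well([a])
        clonotypes, summary = call_clonotypes([wc], min_reads=5)
        assert summary["analyzed_wells"] == 0 and clonotypes == []

    def test_empty_well_produces_nothing(self):
        clonotypes, summary = call_clonotypes([WellCall(well="A1")])
        assert clonotypes == [] and summary["analyzed_wells"] == 0
        assert summary["dual_alpha_pct"] == 0.0

    def test_cross_well_deduplication(self, germ, scheme, cmv_clonotypes):
        ct = cmv_clonotypes[0]
        layout = layout_from_clonotypes({"A1": ct, "B5": ct, "G9": ct})
        reads = simulate_reads(layout, scheme, germ, reads_per_chain=10, seed=4)
        result = run_pairing(reads, scheme, germ)
        assert result.summary["paired_wells"] == 3
        assert len(result.clonotypes) == 1
        assert result.clonotypes[0].pair_key == ct.pair_key


def test_end_to_end_recovery_with_substitution_noise(germ, scheme, cmv_clonotypes):
    """Consensus over redundant reads absorbs a 1% error rate."""
    layout = layout_from_clonotypes(
        {"A1": cmv_clonotypes[0], "B2": cmv_clonotypes[7], "C3": cmv_clonotypes[2]}
    )
    reads = simulate_reads(layout, scheme, germ, reads_per_chain=40,
                           error_rate=0.01, seed=8)
    result = run_pairing(reads, scheme, germ)
    assert {c.pair_key for c in result.clonotypes} == {
        cmv_clonotypes[i].pair_key for i in (0, 7, 2)
    }


def test_clonotype_table_roundtrip(cmv_clonotypes, tmp_path):
    path = tmp_path / "clonotypes.tsv"
    write_clonotypes(cmv_clonotypes, path)
    header = path.read_text().splitlines()[0]
    assert header == "UCN\tTRAV\tTRAJ\tcdr3a_nt\tcdr3a_aa\tTRBV\tTRBD\tTRBJ\tcdr3b_nt\tcdr3b_aa"
    back = read_clonotypes(path)
    assert [c.pair_key for c in back] == [c.pair_key for c in cmv_clonotypes]
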