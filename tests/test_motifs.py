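"""Promoter windows, IUPAC scanning, consensus derivation and conservation."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from notchscreen import (
    MotifDef,
    PromoterWindow,
    PromoterWindowSpec,
    annotate_promoter_map,
    call_conservation,
    derive_iupac_consensus,
    extract_window,
    scan_motif,
)
from notchscreen.motifs import (
    IUPAC_CODES,
    MotifHit,
    iupac_matches,
    reverse_complement,
)

MHAM = MotifDef("MHAM", "CACCTGC")
MNAM = MotifDef("MNAM", "GCAGCTG")
EBOX = MotifDef("EBOX", "CANNTG")
NBOX = MotifDef("NBOX", "CACNAG")
PAPER_MOTIFS = [EBOX, NBOX, MHAM, MNAM]


def naive_scan(seq: str, consensus: str):
    """Independent oracle: substring membership in the set of all expansions."""
    expansions = {
        "".join(bases)
        for bases in itertools.product(*(sorted(IUPAC_CODES[c]) for c in consensus))
    }
    m = len(consensus)
    rc = {reverse_complement(e) for e in expansions}
    hits = []
    for i in range(len(seq) - m + 1):
        site = seq[i : i + m]
        if site in expansions:
            hits.append((i, "+"))
        if site in rc:
            hits.append((i, "-"))
    return hits


class TestWindowSpec:
    def test_default_length_601(self):
        assert PromoterWindowSpec().length == 601

    def test_no_position_zero(self):
        spec = PromoterWindowSpec(3, 2)
        positions = [spec.index_to_pos(i) for i in range(spec.length)]
        assert positions == [-3, -2, -1, 1, 2, 3]
        with pytest.raises(ValueError):
            spec.pos_to_index(0)

    def test_pos_index_roundtrip(self):
        spec = PromoterWindowSpec(10, 5)
        for i in range(spec.length):
            assert spec.pos_to_index(spec.index_to_pos(i)) == i

    def test_negative_extents_rejected(self):
        with pytest.raises(ValueError):
            PromoterWindowSpec(-1, 5)


class TestExtractWindow:
    def test_plus_strand_slice(self):
        w = extract_window("AAACGTTT", 4, "+", PromoterWindowSpec(3, 2))
        assert w.seq == "AACGTT"

    def test_minus_strand_is_reverse_complement(self):
        spec = PromoterWindowSpec(3, 2)
        w = extract_window("AAACGTTT", 4, "-", spec)
        assert w.seq == reverse_complement("ACGTTT")  # rc of the [2:8] slice

    def test_default_window_is_601nt(self):
        seq = "A" * 2000
        w = extract_window(seq, 1000, "+")
        assert len(w.seq) == 601

    def test_truncation_keeps_tss_anchor(self, caplog):
        with caplog.at_level("WARNING", logger="notchscreen.motifs"):
            w = extract_window("ACGTACGTAC", 2, "+", PromoterWindowSpec(5, 3))
        assert "truncated" in caplog.text
        assert w.seq == "ACGTAC"
        assert w.tss_index == 2
        assert w.index_to_pos(w.tss_index) == 1

    def test_tss_outside_record_rejected(self):
        with pytest.raises(ValueError, match="TSS"):
            extract_window("ACGT", 9, "+")


class TestScanMotif:
    def test_single_plus_hit(self):
        w = PromoterWindow("g", "sp", "TTCACCTGCTT", PromoterWindowSpec(5, 5))
        hits = scan_motif(w, MHAM)
        assert len(hits) == 1
        assert hits[0].strand == "+"
        assert hits[0].matched == "CACCTGC"
        assert hits[0].start == -3  # match begins 3 nt upstream of the TSS base

    def test_palindromic_class_hits_both_strands(self):
        # free-standing sequence (no TSS anchor): positions are 1-based
        w = PromoterWindow("g", "sp", "CAGCTG", tss_index=None)
        hits = scan_motif(w, EBOX)
        assert [(h.start, h.strand) for h in hits] == [(1, "+"), (1, "-")]

    def test_poly_a_has_no_hits(self):
        w = PromoterWindow("g", "sp", "A" * 50, tss_index=None)
        for motif in PAPER_MOTIFS:
            assert scan_motif(w, motif) == []

    def test_overlapping_hits_all_reported(self):
        w = PromoterWindow("g", "sp", "CACATGCACATG", tss_index=None)
        starts = [h.start for h in scan_motif(w, EBOX, both_strands=False)]
        assert starts == [1, 7]
        w2 = PromoterWindow("g", "sp", "CACACGTGTG", tss_index=None)
        assert len(scan_motif(w2, EBOX)) >= 2

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_motif(PromoterWindow("g", "sp", "", tss_index=None), EBOX)

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifDef("bad", "CAXXTG")

    @given(st.integers(0, 10_000))
    def test_matches_naive_oracle_on_random_sequences(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        length = int(rng.integers(6, 200))
        seq = "".join(rng.choice(list("ACGT"), length))
        w = PromoterWindow("g", "sp", seq, tss_index=None)
        for motif in PAPER_MOTIFS:
            got = [(w.pos_to_index(h.start), h.strand) for h in scan_motif(w, motif)]
            assert sorted(got) == sorted(naive_scan(seq, motif.consensus)), (
                seq, motif.id)

    @given(st.integers(0, 10_000))
    def test_strand_closure_under_reverse_complement(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 80))
        w = PromoterWindow("g", "sp", seq, tss_index=None)
        w_rc = PromoterWindow("g", "sp", reverse_complement(seq), tss_index=None)
        for motif in PAPER_MOTIFS:
            fwd = {(w.pos_to_index(h.start), h.strand) for h in scan_motif(w, motif)}
            mirrored = {
                (len(seq) - (w_rc.pos_to_index(h.start) + len(motif.consensus)),
                 "+" if h.strand == "-" else "-")
                for h in scan_motif(w_rc, motif)
            }
            assert fwd == mirrored

    def test_every_mham_plus_hit_is_an_ebox_hit(self, rng):
        # CACCTGC starts with CACCTG, an instance of CANNTG
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), 60))
            w = PromoterWindow("g", "sp", seq, tss_index=None)
            mham_starts = {h.start for h in scan_motif(w, MHAM, both_strands=False)}
            ebox_starts = {h.start for h in scan_motif(w, EBOX, both_strands=False)}
            assert mham_starts <= ebox_starts


class TestConsensusDerivation:
    def test_singleton(self):
        assert derive_iupac_consensus(["CACCTGC"]) == "CACCTGC"

    def test_columnwise_sets_not_widened(self):
        sites = ["CAACTG", "CAGCTG", "CATCTG", "CACCTG"]
        assert derive_iupac_consensus(sites) == "CANCTG"

    def test_idempotent_on_duplicates(self):
        assert derive_iupac_consensus(["CACCTGC", "CACCTGC"]) == "CACCTGC"

    def test_order_invariant(self):
        sites = ["ACGT", "AGGT", "ATGA"]
        perms = list(itertools.permutations(sites))
        assert len({derive_iupac_consensus(p) for p in perms}) == 1

    @given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5),
                    min_size=1, max_size=8))
    def test_round_trip_every_site_matches(self, sites):
        consensus = derive_iupac_consensus(sites)
        assert all(iupac_matches(s, consensus) for s in sites)

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="length"):
            derive_iupac_consensus(["ACGT", "ACG"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            derive_iupac_consensus([])


def _hit(gene, species, motif="MHAM", start=-120, strand="+", matched="CACCTGC"):
    return MotifHit(gene, species, motif, start, strand, matched)


class TestConservation:
    def test_two_of_two_species_conserved(self):
        hits = [_hit("Chga", "mouse"), _hit("Chga", "chick")]
        calls = call_conservation(hits, {"mouse", "chick"}, m=2)
        assert len(calls) == 1 and calls[0].conserved

    def test_one_of_four_not_conserved(self):
        hits = [_hit("Robo2", "mouse", motif="MNAM", matched="GCAGCTG")]
        calls = call_conservation(hits, {"mouse", "chick", "human", "rat"}, m=2)
        assert not calls[0].conserved

    def test_positional_spread_reported_not_filtering(self):
        hits = [_hit("g", "mouse", start=-120), _hit("g", "chick", start=-100)]
        calls = call_conservation(hits, {"mouse", "chick"}, m=2)
        assert calls[0].conserved
        assert calls[0].positional_spread == 20

    def test_m_larger_than_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            call_conservation([], {"mouse"}, m=2)

    def test_m_defaults_to_all_species(self):
        hits = [_hit("g", "mouse"), _hit("g", "chick")]
        calls = call_conservation(hits, {"mouse", "chick", "rat"})
        assert not calls[0].conserved


class TestPromoterMap:
    def _windows(self, seq_by_species, spec=None):
        spec = spec or PromoterWindowSpec(10, 5)
        return {
            sp: PromoterWindow("Chga", sp, seq, spec) for sp, seq in seq_by_species.items()
        }

    def test_planted_motifs_reported_with_positions(self):
        seq = "T" * 2 + "CACCTGC" + "GCAGCTG"  # MHAM at idx 2, MNAM at idx 9
        windows = self._windows({"mouse": seq, "chick": seq})
        report = annotate_promoter_map("Chga", windows, [MHAM, MNAM], m=2)
        hits = report["hits"]
        assert set(hits["motif"]) == {"MHAM", "MNAM"}
        mham = hits[(hits["motif"] == "MHAM") & (hits["strand"] == "+")]
        assert set(mham["start"]) == {-8}
        cons = report["conservation"]
        assert cons["conserved"].all()

    def test_gene_with_no_motifs_still_reported(self):
        windows = self._windows({"mouse": "T" * 16})
        report = annotate_promoter_map("Chga", windows, [MHAM, MNAM], m=1)
        assert report["gene"] == "Chga"
        assert len(report["hits"]) == 0
        assert len(report["conservation"]) == 0

    def test_ebox_nested_inside_mham_is_annotated(self):
        seq = "TT" + "CACCTGC" + "T" * 7
        windows = self._windows({"mouse": seq})
        report = annotate_promoter_map("Chga", windows, [EBOX, MHAM], m=1)
        hits = report["hits"]
        ebox_plus = hits[(hits["motif"] == "EBOX") & (hits["strand"] == "+")]
        assert (ebox_plus["within"] == "MHAM").all()
        assert len(ebox_plus) == 1
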