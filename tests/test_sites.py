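import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Seq import reverse_complement

from crypticsplice import (
    GeneModel,
    IntegrityError,
    a3ss_event,
    a5ss_event,
    branchpoint_a_fraction,
    characterize_events,
    cryptic_distance,
    distance_histogram,
    extract_ss_windows,
    flag_nmd,
    included_sequence,
    motif_profile,
    ppt_score,
    window_offsets,
)
from crypticsplice.sites import extract_window
from conftest import mirror_cohort


class TestCrypticDistance:
    def test_plus_strand_upstream(self):
        e = a3ss_event("g", "c", "+", 1001, 2000, 1980)
        assert cryptic_distance(e) == 20

    def test_minus_strand_mirror(self):
        e = a3ss_event("g", "c", "-", 2000, 1001, 1021)
        assert cryptic_distance(e) == 20

    def test_downstream_shift_is_negative(self):
        e = a3ss_event("g", "c", "+", 1001, 2000, 2012)
        assert cryptic_distance(e) == -12

    def test_coincident_sites_forbidden_at_construction(self):
        with pytest.raises(IntegrityError):
            a3ss_event("g", "c", "+", 1001, 2000, 2000)

    def test_non_a3ss_rejected(self):
        e = a5ss_event("g", "c", "+", 2000, 1001, 1021)
        with pytest.raises(TypeError):
            cryptic_distance(e)


class TestDistanceHistogram:
    def test_log2_binning_and_mode(self):
        h = distance_histogram([9, 10, 12, 13, 40])
        row = h.table.set_index("bin_lo").loc[8]
        assert (row["bin_hi"], row["count"]) == (16, 4)
        assert h.mode_bin == (8, 16)

    def test_edge_bin(self):
        h = distance_histogram([1])
        assert h.table.iloc[0].tolist() == [1, 2, 1]
        assert h.mode_bin == (1, 2)

    def test_empty_input_not_an_error(self):
        h = distance_histogram([])
        assert h.table.empty and h.mode_bin is None

    def test_negative_distances_tabulated_separately(self):
        h = distance_histogram([9, -5, -6])
        assert h.table["count"].sum() == 1
        assert h.negative_table.set_index("bin_lo").loc[4, "count"] == 2


class TestWindowExtraction:
    GENOME = {"chr1": "".join("ACGT"[i % 4] for i in range(3000))}

    def test_plus_strand_coordinates(self):
        # offsets -3..+2 at site 2000 cover genomic 1998..2002
        seq = extract_window(self.GENOME, "chr1", 2000, "+", (-3, 2))
        assert seq == self.GENOME["chr1"][1997:2002]
        assert len(seq) == 5

    def test_minus_strand_is_reverse_complement_mirror(self):
        genome = {"chr1": self.GENOME["chr1"]}
        fwd = extract_window(genome, "chr1", 2000, "+", (-3, 2))
        mirrored = {"chr1": reverse_complement(genome["chr1"])}
        site = len(genome["chr1"]) - 2000 + 1
        rev = extract_window(mirrored, "chr1", site, "-", (-3, 2))
        assert rev == fwd

    def test_off_contig_window_skipped(self):
        assert extract_window(self.GENOME, "chr1", 5, "+", (-30, 9)) is None

    def test_all_simulated_canonical_windows_end_in_ag(self, small_cohort):
        a3ss = [e for e in small_cohort.sim.events if e.event_type == "A3SS"]
        windows = extract_ss_windows(a3ss, "canonical", small_cohort.sim.genome, (-30, 9))
        assert len(windows) == len(a3ss)
        for seq in windows.values():
            assert seq[28:30] == "AG"  # offsets -2, -1 of a 39-nt window

    def test_window_offsets_skip_zero(self):
        offs = window_offsets((-3, 2))
        assert offs == [-3, -2, -1, 1, 2]
        assert len(window_offsets((-30, 9))) == 39


class TestMotifProfile:
    def test_uniform_column_has_zero_bits(self):
        p = motif_profile(["A", "C", "G", "T"])
        assert p.info_content.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_column_has_two_bits(self):
        p = motif_profile(["A", "A", "A", "A"])
        assert p.info_content.iloc[0] == pytest.approx(2.0)

    def test_half_half_column_has_one_bit(self):
        p = motif_profile(["A", "A", "C", "C"])
        assert p.info_content.iloc[0] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self):
        p = motif_profile(["ACGT", "AAGT", "ACGA"])
        assert np.allclose(p.frequencies.sum(axis=1), 1.0)

    def test_n_excluded_per_position(self):
        p = motif_profile(["AN", "AA"])
        assert p.counts.iloc[1].sum() == 1
        assert p.frequencies.iloc[1]["A"] == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(IntegrityError):
            motif_profile(["AA", "A"])

    def test_small_sample_correction_lowers_ic(self):
        plain = motif_profile(["AA", "AA"]).info_content
        corrected = motif_profile(["AA", "AA"], small_sample_correction=True).info_content
        assert (corrected < plain).all()

    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_ic_bounds_hold_for_any_profile(self, seqs):
        p = motif_profile(seqs)
        assert ((p.info_content >= 0) & (p.info_content <= 2)).all()
        assert np.allclose(p.frequencies.sum(axis=1), 1.0)


class TestScores:
    def test_all_pyrimidine(self):
        assert ppt_score("TTTTCCTTTTCCTTTT") == 1.0

    def test_all_adenosine(self):
        assert branchpoint_a_fraction("AAAAAAAA") == 1.0
        assert ppt_score("AAAAAAAA") == 0.0

    def test_empty_window_is_missing(self):
        assert ppt_score("") is None
        assert branchpoint_a_fraction("NNN") is None


class TestNmdFlag:
    @staticmethod
    def _build(d: int, included: str | None = None):
        """Gene with a cryptic acceptor d nt upstream of the canonical one.

        ``included`` (length d) is the intronic sequence retained in the
        mRNA; its last two bases are the canonical acceptor's AG.
        """
        if included is None:
            included = ("T" * (d - 2)) + "AG"
        assert len(included) == d
        exon1 = "ATG" + "GCT" * 9  # CDS length 30 -> frame 0 at the junction
        intron = "GT" + "C" * 40 + "AG" + included  # cryptic AG then inclusion
        exon2 = "GGATCC" * 5
        seq = exon1 + intron + exon2
        e1 = (1, len(exon1))
        e2 = (len(exon1) + len(intron) + 1, len(seq))
        gene = GeneModel("g", "g.t1", "c", "+", exons=(e1, e2), cds=(e1, e2))
        canonical = len(exon1) + len(intron)
        event = a3ss_event("g", "c", "+", len(exon1) + 1, canonical, canonical - d)
        return event, gene, {"c": seq}

    def test_non_triplet_inclusion_is_frameshift(self):
        event, gene, genome = self._build(20)
        assert flag_nmd(event, gene, genome) == "frameshift"

    def test_in_frame_stop_is_ptc(self):
        event, gene, genome = self._build(21, "TAA" + "TTT" * 5 + "TAG")
        assert included_sequence(event, genome) == "TAA" + "TTT" * 5 + "TAG"
        assert flag_nmd(event, gene, genome) == "ptc_in_frame"

    def test_in_frame_without_stop_is_none(self):
        event, gene, genome = self._build(21, "TTT" * 6 + "CAG")
        assert flag_nmd(event, gene, genome) == "none"

    def test_no_cds_is_unknown_frame(self):
        event, gene, genome = self._build(21, "TTT" * 6 + "CAG")
        gene_no_cds = GeneModel(
            gene.gene_id, gene.transcript_id, gene.chrom, gene.strand, gene.exons
        )
        assert flag_nmd(event, gene_no_cds, genome) == "unknown_frame"

    def test_frame_prefix_from_upstream_cds(self):
        """A stop split across the junction is found via the CDS phase."""
        # exon1 CDS length 31 -> phase 1: last exonic base completes codons
        event, gene, genome = self._build(21, "TTT" * 6 + "CAG")
        exon1 = "ATG" + "GCT" * 9 + "T"  # 31 nt, ends ...T
        intron = "GT" + "C" * 40 + "AG" + "AA" + "TTT" * 5 + "CAAG"
        included = "AA" + "TTT" * 5 + "CAAG"
        assert len(included) == 21
        exon2 = "GGATCC" * 5
        seq = exon1 + intron + exon2
        e1 = (1, len(exon1))
        e2 = (len(exon1) + len(intron) + 1, len(seq))
        gene = GeneModel("g", "g.t1", "c", "+", exons=(e1, e2), cds=(e1, e2))
        canonical = len(exon1) + len(intron)
        event = a3ss_event("g", "c", "+", len(exon1) + 1, canonical, canonical - 21)
        # phase prefix "T" + "AA..." -> first codon TAA = stop
        assert flag_nmd(event, gene, {"c": seq}) == "ptc_in_frame"


class TestStrandMirror:
    def test_characterization_invariant_under_mirroring(self, small_cohort):
        genome_m, genes_m, junctions_m, mpos = mirror_cohort(small_cohort)
        a3ss = [e for e in small_cohort.sim.events if e.event_type == "A3SS"]
        ann = characterize_events(a3ss, small_cohort.sim.genome, small_cohort.sim.genes)

        flip = {"+": "-", "-": "+"}
        mirrored_events = [
            a3ss_event(
                e.gene_id, e.chrom, flip[e.strand],
                mpos(e.chrom, e.shared_site),
                mpos(e.chrom, e.canonical),
                mpos(e.chrom, e.alternative),
            )
            for e in a3ss
        ]
        ann_m = characterize_events(mirrored_events, genome_m, genes_m)
        for orig, mirr in zip(a3ss, mirrored_events):
            row, row_m = ann.loc[orig.event_id], ann_m.loc[mirr.event_id]
            assert row["distance"] == row_m["distance"]
            assert row["included_sequence"] == row_m["included_sequence"]
            assert row["nmd_flag"] == row_m["nmd_flag"]
            for col in ("ppt_canonical", "ppt_cryptic", "bp_a_canonical", "bp_a_cryptic"):
                assert row[col] == pytest.approx(row_m[col])
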