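"""Back-splice calling, annotation, presence filter, FPM and junction
sequences checked against construction cases, ground truth and brute force."""

import math

import numpy as np
import pandas as pd
import pytest

from cernaforge import circdetect
from cernaforge.simulate import (SimConfig, simulate_segment_alignments,
                                 make_design)


def _seg_df(rows, sample="s1"):
    return pd.DataFrame(
        [dict(read_id=r[0], segment_index=r[1], chrom=r[2], start=r[3],
              end=r[4], strand=r[5], sample=sample) for r in rows])


class TestCallBacksplice:
    def test_inverted_pair_yields_junction(self):
        seg = _seg_df([("r1", 0, "chr1", 350, 400, "+"),
                       ("r1", 1, "chr1", 100, 150, "+")])
        out = circdetect.call_backsplice(seg)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.chrom, row.start, row.end, row.strand) == ("chr1", 100, 400, "+")
        assert row.support_s1 == 1

    def test_minus_strand_mirrored(self):
        seg = _seg_df([("r1", 0, "chr1", 100, 150, "-"),
                       ("r1", 1, "chr1", 350, 400, "-")])
        out = circdetect.call_backsplice(seg)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start, row.end, row.strand) == (100, 400, "-")

    def test_linear_read_no_call(self):
        seg = _seg_df([("r1", 0, "chr1", 120, 180, "+")])
        assert circdetect.call_backsplice(seg).empty
        # forward splice: genomic order matches read order
        seg2 = _seg_df([("r2", 0, "chr1", 100, 150, "+"),
                        ("r2", 1, "chr1", 300, 350, "+")])
        assert circdetect.call_backsplice(seg2).empty

    def test_cross_chromosome_pair_ignored(self):
        seg = _seg_df([("r1", 0, "chr1", 350, 400, "+"),
                       ("r1", 1, "chr2", 100, 150, "+")])
        assert circdetect.call_backsplice(seg).empty

    def test_malformed_row_reports_line(self):
        seg = _seg_df([("r1", 0, "chr1", 350, 300, "+")])
        with pytest.raises(ValueError, match="line 0"):
            circdetect.call_backsplice(seg)

    def test_support_matches_simulator_truth(self, small_dataset):
        out = circdetect.call_backsplice(small_dataset.segments)
        truth = small_dataset.truth_support
        tj = small_dataset.truth_junctions().set_index("circ_id")
        wide = out.set_index(["chrom", "start", "end", "strand"])
        for row in truth.itertuples():
            j = tj.loc[row.circ_id]
            key = (j.chrom, j.start, j.end, j.strand)
            detected = (wide.loc[key, f"support_{row.sample}"]
                        if key in wide.index else 0)
            assert detected == row.crossings

    def test_zero_calls_on_linear_only_data(self, small_dataset):
        cfg = small_dataset.config
        linear = small_dataset.transcripts.query("kind == 'linear'")
        seg, _ = simulate_segment_alignments(linear, cfg)
        out = circdetect.call_backsplice(seg)
        assert out.empty


class TestAnnotate:
    @pytest.fixture()
    def two_exon_models(self):
        return pd.DataFrame([dict(gene_id="gA", chrom="chr1", strand="+",
                                  exon_starts=(100, 300), exon_ends=(200, 400))])

    def test_exact_boundary_annotation(self, two_exon_models):
        j = pd.DataFrame([dict(chrom="chr1", start=100, end=400, strand="+")])
        rec = circdetect.annotate(j, two_exon_models)
        row = rec.iloc[0]
        assert row.status == "annotated"
        assert row.host_gene == "gA"
        assert (row.exon_first, row.exon_last) == (1, 2)
        assert row.spliced_length == 200

    def test_off_boundary_is_unannotated(self, two_exon_models):
        j = pd.DataFrame([dict(chrom="chr1", start=101, end=400, strand="+")])
        rec = circdetect.annotate(j, two_exon_models)
        assert rec.iloc[0].status == "unannotated"

    def test_two_candidate_genes_flagged_ambiguous(self, two_exon_models):
        models = pd.concat([two_exon_models, pd.DataFrame([dict(
            gene_id="gB", chrom="chr1", strand="+",
            exon_starts=(100, 300), exon_ends=(200, 400))])], ignore_index=True)
        j = pd.DataFrame([dict(chrom="chr1", start=100, end=400, strand="+")])
        rec = circdetect.annotate(j, models)
        assert list(rec.status) == ["ambiguous", "ambiguous"]
        assert set(rec.host_gene) == {"gA", "gB"}

    def test_minus_strand_exon_numbering_in_transcription_order(self):
        models = pd.DataFrame([dict(gene_id="gM", chrom="chr1", strand="-",
                                    exon_starts=(100, 300, 500),
                                    exon_ends=(200, 400, 600))])
        j = pd.DataFrame([dict(chrom="chr1", start=100, end=400, strand="-")])
        rec = circdetect.annotate(j, models)
        # genomic exons 1..2 are transcription-order exons 2..3 on '-'
        assert (rec.iloc[0].exon_first, rec.iloc[0].exon_last) == (2, 3)

    def test_all_planted_circles_annotated_to_hosts(self, small_dataset):
        junctions = circdetect.call_backsplice(small_dataset.segments)
        rec = circdetect.annotate(junctions, small_dataset.models)
        truth = small_dataset.truth_junctions()
        by_coord = {(r.chrom, r.start, r.end, r.strand): r.host_gene
                    for r in truth.itertuples()}
        assert (rec.status == "annotated").all()
        for row in rec.itertuples():
            assert by_coord[(row.chrom, row.start, row.end, row.strand)] == row.host_gene


class TestPresenceFilter:
    def test_half_rule_on_group_of_eleven(self):
        # 6 of 11 nonzero: 6 >= ceil(5.5) so expressed
        design = pd.DataFrame(dict(sample=[f"s{i}" for i in range(11)],
                                   group=["g"] * 11))
        counts = pd.DataFrame([[1] * 6 + [0] * 5], index=["f"],
                              columns=design["sample"])
        mask, kept = circdetect.presence_filter(counts, design)
        assert mask.loc["f", "g"]
        counts.loc["f"] = [1] * 5 + [0] * 6  # 5 < ceil(5.5)
        mask, kept = circdetect.presence_filter(counts, design)
        assert not mask.loc["f", "g"]
        assert kept.empty

    def test_all_zero_feature_dropped(self, rng):
        design = make_design(SimConfig(seed=0, n_genes=2, n_circ=1, n_mirnas=1))
        counts = pd.DataFrame(
            rng.integers(0, 5, (10, len(design))),
            index=[f"f{i}" for i in range(10)], columns=design["sample"])
        counts.loc["f0"] = 0
        _, kept = circdetect.presence_filter(counts, design)
        assert "f0" not in kept.index

    def test_mask_equals_bruteforce_recount(self, rng):
        design = make_design(SimConfig(seed=0, n_genes=2, n_circ=1, n_mirnas=1))
        counts = pd.DataFrame(
            (rng.random((60, len(design))) < 0.4) * rng.integers(1, 9, (60, len(design))),
            index=[f"f{i}" for i in range(60)], columns=design["sample"])
        mask, _ = circdetect.presence_filter(counts, design, min_frac=0.5)
        for group, sub in design.groupby("group"):
            need = math.ceil(0.5 * len(sub))
            for f in counts.index:
                nz = sum(counts.loc[f, s] > 0 for s in sub["sample"])
                assert mask.loc[f, group] == (nz >= need)

    def test_idempotent_and_monotone_in_min_frac(self, rng):
        design = make_design(SimConfig(seed=0, n_genes=2, n_circ=1, n_mirnas=1))
        counts = pd.DataFrame(
            (rng.random((40, len(design))) < 0.5) * 3,
            index=[f"f{i}" for i in range(40)], columns=design["sample"])
        _, kept1 = circdetect.presence_filter(counts, design)
        _, kept2 = circdetect.presence_filter(kept1, design)
        pd.testing.assert_frame_equal(kept1, kept2)
        prev = None
        for frac in (0.9, 0.5, 0.2):
            _, kept = circdetect.presence_filter(counts, design, min_frac=frac)
            if prev is not None:
                assert set(prev.index) <= set(kept.index)
            prev = kept


class TestFPM:
    def test_simple_value(self):
        counts = pd.DataFrame({"s": [5]}, index=["f"])
        out = circdetect.fpm_normalize(counts, {"s": 1e6})
        assert out.loc["f", "s"] == 5.0

    def test_columns_sum_to_million_with_colsum_libraries(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (30, 4)),
                              columns=list("abcd"))
        counts.iloc[0] += 1  # avoid zero library
        out = circdetect.fpm_normalize(counts)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_log2_fpm_matches_hand_computation(self):
        counts = pd.DataFrame([[2, 0, 1], [8, 10, 0], [0, 10, 9]],
                              columns=list("xyz"), dtype=float)
        libs = counts.sum(axis=0)
        out = np.log2(circdetect.fpm_normalize(counts) + 1)
        for i in range(3):
            for j, s in enumerate("xyz"):
                hand = math.log2(counts.iloc[i, j] / libs[s] * 1e6 + 1)
                assert out.iloc[i, j] == pytest.approx(hand, abs=1e-12)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s": [0]}, index=["f"])
        with pytest.raises(ValueError):
            circdetect.fpm_normalize(counts)


class TestJunctionSequence:
    def test_definition_small_flank(self):
        assert circdetect.junction_sequence("ABCDEFGH", flank=2) == "GHAB"

    def test_wraparound_by_modular_index_oracle(self):
        seq = "ABCDEFGH"
        for flank in (5, 8, 11):
            expected = "".join(seq[(len(seq) - flank + i) % len(seq)]
                               for i in range(2 * flank))
            assert circdetect.junction_sequence(seq, flank=flank) == expected
        assert circdetect.junction_sequence(seq, flank=5) == "DEFGHABCDE"

    def test_doubled_sequence_slice_oracle(self):
        seq = "ACGTACGGTTAC"
        L = len(seq)
        for flank in range(1, L + 1):
            assert (circdetect.junction_sequence(seq, flank)
                    == (seq + seq)[L - flank:L + flank])

    def test_simulated_circle_junction_sequence(self, small_dataset):
        junctions = circdetect.call_backsplice(small_dataset.segments)
        rec = circdetect.annotate(junctions, small_dataset.models)
        row = rec.iloc[0]
        spliced = circdetect.circ_spliced_sequence(small_dataset.genome, row)
        out = circdetect.junction_sequence(spliced, flank=100)
        assert len(out) == 200
        assert out == (spliced + spliced)[len(spliced) - 100:len(spliced) + 100]

    def test_invalid_flank(self):
        with pytest.raises(ValueError):
            circdetect.junction_sequence("ACGT", flank=0)
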