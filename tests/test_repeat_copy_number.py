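import numpy as np
import pytest

from symbgc import repeat_copy_number as rcn
from symbgc.sequence_io import AlignedRead, Contig, InputError
from symbgc.synthetic_data import build_scenario

from conftest import tiny_scenario_config


def _read(read_id, contig, pos, seq, cigar=None, read1=True):
    return AlignedRead(
        read_id=read_id,
        contig_id=contig,
        pos=pos,
        cigar=cigar or [("M", len(seq))],
        seq=seq,
        is_reverse=not read1,
        is_read1=read1,
    )


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


class TestDepthSummary:
    def test_two_reads_tiling_once(self):
        reads = [
            _read("r1", "c1", 1, "A" * 100),
            _read("r2", "c1", 101, "A" * 100),
        ]
        summary = rcn.depth_summary(reads, ("c1", 1, 200))
        assert summary.mean_depth == pytest.approx(1.0)

    def test_empty_alignments_error(self):
        with pytest.raises(InputError, match="empty"):
            rcn.depth_summary([], ("c1", 1, 100))

    def test_zero_coverage_region_warns(self, caplog):
        reads = [_read("r1", "c2", 1, "A" * 100)]
        with caplog.at_level("WARNING", logger="symbgc.repeat_copy_number"):
            summary = rcn.depth_summary(reads, ("c1", 1, 100))
        assert summary.mean_depth == 0.0
        assert summary.ci95 == (0.0, 0.0)

    def test_bgc_region_three_times_host(self, default_bundle):
        host = [c for c in default_bundle.contigs if c.id != "bgc"]
        bgc = next(c for c in default_bundle.contigs if c.id == "bgc")
        host_depth = rcn.host_reference_depth(default_bundle.alignments, host)
        summary = rcn.depth_summary(default_bundle.alignments, ("bgc", 1, bgc.length))
        assert summary.mean_depth / host_depth == pytest.approx(3.0, abs=0.25)
        lo, hi = summary.ci95
        assert lo <= summary.mean_depth <= hi


class TestEstimateCopyNumber:
    def test_printed_coverage_pair_one(self):
        ratio, copies = rcn.estimate_copy_number(400.165, 135.16)
        assert copies == 3
        assert ratio == pytest.approx(2.961, abs=5e-4)

    def test_printed_coverage_pair_two(self):
        ratio, copies = rcn.estimate_copy_number(159.02, 48.24)
        assert copies == 3
        assert ratio == pytest.approx(3.296, abs=5e-4)

    def test_identity(self):
        assert rcn.estimate_copy_number(50, 50) == (1.0, 1)

    def test_minimum_one_copy(self):
        assert rcn.estimate_copy_number(1.0, 50.0)[1] == 1

    def test_half_rounds_away_from_zero(self):
        assert rcn.estimate_copy_number(125, 50)[1] == 3

    def test_scale_invariance(self):
        for k in (0.5, 1.0, 2.2, 3.7):
            for x in (1e-3, 1.0, 57.3):
                ratio, copies = rcn.estimate_copy_number(k * x, x)
                assert ratio == pytest.approx(k)
                assert copies == max(1, int(np.floor(k + 0.5)))

    def test_zero_genome_depth_errors(self):
        with pytest.raises(InputError):
            rcn.estimate_copy_number(10, 0)


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------


class TestCountJunctions:
    def test_default_scenario_partner_counts(self, default_bundle):
        bundle = default_bundle
        summary = rcn.count_junctions(
            bundle.pairs, bundle.graph, "bgc", bundle.contigs,
            insert_mean=bundle.config.insert_mean,
        )
        assert len(summary.end3.partners) == 3
        assert len(summary.end5.partners) == 2
        assert {p.contig_id for p in summary.end5.partners} == set(
            bundle.truth.flanks_5p
        )
        assert {p.contig_id for p in summary.end3.partners} == set(
            bundle.truth.flanks_3p
        )
        assert all(p.graph_confirmed for p in summary.end5.partners)
        assert all(p.graph_confirmed for p in summary.end3.partners)
        (internal,) = summary.internal
        assert internal.partner in bundle.truth.flanks_internal
        assert internal.terminus == "5p"
        lead = bundle.config.leading_segment_length
        assert abs(internal.median_offset - lead) <= bundle.config.insert_mean

    def test_single_copy_scenario_one_partner_per_end(self):
        bundle = build_scenario(tiny_scenario_config(bgc_copy_number=1))
        summary = rcn.count_junctions(
            bundle.pairs, bundle.graph, "bgc", bundle.contigs,
            insert_mean=bundle.config.insert_mean,
        )
        assert len(summary.end5.partners) == 1
        assert len(summary.end3.partners) == 1
        assert summary.internal == []

    def test_partner_counts_non_increasing_in_min_support(self, small_bundle):
        counts = []
        for support in (1, 3, 10, 50):
            summary = rcn.count_junctions(
                small_bundle.pairs, None, "bgc", small_bundle.contigs,
                insert_mean=small_bundle.config.insert_mean, min_support=support,
            )
            counts.append(len(summary.end5.partners) + len(summary.end3.partners))
        assert counts == sorted(counts, reverse=True)

    def test_min_support_above_total_zero_partners(self, small_bundle):
        summary = rcn.count_junctions(
            small_bundle.pairs, None, "bgc", small_bundle.contigs,
            insert_mean=small_bundle.config.insert_mean, min_support=10**6,
        )
        assert summary.end5.partners == [] and summary.end3.partners == []

    def test_no_alignments_on_focus_warns(self, caplog):
        contigs = [Contig("c1", "A" * 500), Contig("focus", "A" * 500)]
        reads = [_read("r1", "c1", 1, "A" * 100)]
        from symbgc.sequence_io import pair_reads

        with caplog.at_level("WARNING", logger="symbgc.repeat_copy_number"):
            summary = rcn.count_junctions(pair_reads(reads), None, "focus", contigs)
        assert summary.end5.partners == []


# ---------------------------------------------------------------------------
# repeat model
# ---------------------------------------------------------------------------


class TestRepeatModel:
    def test_default_scenario_segments(self, default_bundle):
        bundle = default_bundle
        host = [c for c in bundle.contigs if c.id != "bgc"]
        bgc = next(c for c in bundle.contigs if c.id == "bgc")
        host_depth = rcn.host_reference_depth(bundle.alignments, host)
        model = rcn.infer_repeat_model(
            bundle.alignments, bundle.pairs, bgc, bundle.contigs, bundle.graph,
            host_depth, insert_mean=bundle.config.insert_mean,
        )
        assert model.consistent
        assert [s.copy_number for s in model.segments] == [2, 3]
        lead_seg = model.segments[0]
        lead = bundle.config.leading_segment_length
        assert abs(lead_seg.span[1] - lead) <= bundle.config.insert_mean

    def test_uniform_single_copy_one_segment(self):
        bundle = build_scenario(tiny_scenario_config(bgc_copy_number=1))
        host = [c for c in bundle.contigs if c.id != "bgc"]
        bgc = next(c for c in bundle.contigs if c.id == "bgc")
        host_depth = rcn.host_reference_depth(bundle.alignments, host)
        model = rcn.infer_repeat_model(
            bundle.alignments, bundle.pairs, bgc, bundle.contigs, bundle.graph,
            host_depth, insert_mean=bundle.config.insert_mean,
        )
        assert len(model.segments) == 1
        assert model.segments[0].copy_number == 1

    def test_inconsistency_flagged_not_fixed(self):
        junctions = rcn.JunctionSummary(
            focus="bgc",
            end5=rcn.JunctionEvidence(("bgc", "5p"), [rcn.PartnerSupport("a", 5)]),
            end3=rcn.JunctionEvidence(
                ("bgc", "3p"),
                [rcn.PartnerSupport("b", 5), rcn.PartnerSupport("c", 5)],
            ),
        )
        model = rcn.reconcile_repeat_model(
            [("seg1", (1, 10_000), 3.0)], junctions
        )
        assert model.segments[0].copy_number == 3  # depth wins, not silently fixed
        assert model.inconsistencies  # but the conflict is reported

    def test_short_segment_merged(self, caplog):
        junctions = rcn.JunctionSummary(
            focus="bgc",
            end5=rcn.JunctionEvidence(("bgc", "5p")),
            end3=rcn.JunctionEvidence(("bgc", "3p")),
            internal=[rcn.InternalAttachment("x", 5, "5p", 100.0)],
        )
        with caplog.at_level("WARNING", logger="symbgc.repeat_copy_number"):
            spans = rcn.split_segments(10_000, junctions, min_segment=1_000)
        assert spans == [(1, 10_000)]

    def test_parameter_recovery_over_seeded_scenarios(self):
        # 50 scenarios with copy numbers 1..4 at depth >= 30
        correct = 0
        total = 0
        for seed in range(50):
            copies = 1 + seed % 4
            config = tiny_scenario_config(
                seed=100 + seed,
                bgc_copy_number=copies,
                n_host_contigs=max(8, 2 * copies),
            )
            bundle = build_scenario(config)
            host = [c for c in bundle.contigs if c.id != "bgc"]
            bgc = next(c for c in bundle.contigs if c.id == "bgc")
            host_depth = rcn.host_reference_depth(bundle.alignments, host)
            summary = rcn.depth_summary(bundle.alignments, ("bgc", 1, bgc.length))
            _, inferred = rcn.estimate_copy_number(summary.mean_depth, host_depth)
            total += 1
            correct += inferred == copies
        assert correct / total >= 0.95


# ---------------------------------------------------------------------------
# pileup variants
# ---------------------------------------------------------------------------


class TestPileupVariants:
    def test_default_scenario_recovers_all_variants(self, default_bundle):
        bundle = default_bundle
        bgc = next(c for c in bundle.contigs if c.id == "bgc")
        calls = rcn.pileup_variants(bundle.alignments, bgc, 3)
        assert len(calls) == len(bundle.truth.variants) == 5
        truth_by_pos = sorted(bundle.truth.variants, key=lambda v: v.position)
        calls_sorted = sorted(calls, key=lambda c: c.position)
        for truth, call in zip(truth_by_pos, calls_sorted):
            assert abs(call.position - truth.position) <= 2
            assert call.vtype == truth.vtype
            assert call.alt == truth.alt
            assert call.est_copies == len(truth.carrier_copies)

    def test_alt_fraction_one_third(self, default_bundle):
        bgc = next(c for c in default_bundle.contigs if c.id == "bgc")
        calls = rcn.pileup_variants(default_bundle.alignments, bgc, 3)
        for call in calls:
            assert call.alt_fraction == pytest.approx(1 / 3, abs=0.12)
            assert call.est_copies == 1

    def test_copies_below_two_errors(self, small_bundle):
        bgc = next(c for c in small_bundle.contigs if c.id == "bgc")
        with pytest.raises(InputError):
            rcn.pileup_variants(small_bundle.alignments, bgc, 1)

    def test_false_positive_control_without_variants(self):
        # error-free reads and no injected variants: no calls expected
        clean_runs = 0
        n_seeds = 25
        for seed in range(n_seeds):
            config = tiny_scenario_config(
                seed=500 + seed, insertion_specs=[], snp_specs=[]
            )
            bundle = build_scenario(config)
            assert bundle.truth.variants == []
            bgc = next(c for c in bundle.contigs if c.id == "bgc")
            calls = rcn.pileup_variants(bundle.alignments, bgc, 3)
            clean_runs += not calls
        assert clean_runs / n_seeds >= 0.95

    def test_mismatch_tolerant_merging(self):
        assert rcn._edit_distance_leq1("ACGT", "ACGT")
        assert rcn._edit_distance_leq1("ACGT", "ACTT")
        assert rcn._edit_distance_leq1("ACGT", "ACGTA")
        assert not rcn._edit_distance_leq1("ACGT", "TTTT")

    def test_variants_detected_with_sequencing_errors(self):
        config = tiny_scenario_config(seed=3, error_rate=0.002, depth=40)
        bundle = build_scenario(config)
        bgc = next(c for c in bundle.contigs if c.id == "bgc")
        calls = rcn.pileup_variants(
            bundle.alignments, bgc, 3, mismatch_tolerant=True
        )
        called_pos = {c.position for c in calls}
        for truth in bundle.truth.variants:
            assert any(abs(p - truth.position) <= 2 for p in called_pos)
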