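"""Transcript classification against GenBank ORF annotation."""

import numpy as np
import pytest

from chipsad import (
    AnnotationParams,
    OrfFeature,
    SignalArea,
    SimulationConfig,
    annotate_all,
    classify_sas,
    orf_overlap_fraction,
    read_genbank_orfs,
    simulate_annotation,
)

MIRROR = {"utr5": "utr3", "utr3": "utr5"}


def sas(start, end, strand="+", replicon="chr"):
    return SignalArea("e1", replicon, strand, start, end, 2.0, n_probes=5)


def orf(tag, start, end, strand="+", replicon="chr"):
    return OrfFeature(tag, replicon, strand, start, end)


class TestGenbankParsing:
    def test_round_trip_via_fixture(self, tmp_path):
        fx = simulate_annotation(SimulationConfig(seed=0), "one_per_class")
        path = tmp_path / "toy.gbk"
        fx.write_genbank(path)
        orfs = read_genbank_orfs(path)
        assert [(o.locus_tag, o.strand, o.start, o.end) for o in orfs] == [
            (o.locus_tag, o.strand, o.start, o.end) for o in fx.orfs
        ]

    def test_complement_location(self, tmp_path):
        fx = simulate_annotation(SimulationConfig(seed=0), "one_per_class")
        path = tmp_path / "toy.gbk"
        fx.write_genbank(path)
        minus = [o for o in read_genbank_orfs(path) if o.strand == "-"]
        assert minus and all(o.start <= o.end for o in minus)

    def test_missing_file_errors(self):
        with pytest.raises((FileNotFoundError, ValueError)):
            read_genbank_orfs("/nonexistent/x.gbk")


class TestOverlapFraction:
    def test_partial_overlap_inclusive_arithmetic(self):
        # [100,200] x [150,250]: 51 shared bases over a 101 bp ORF
        assert orf_overlap_fraction(sas(100, 200), orf("a", 150, 250)) == (
            pytest.approx(51 / 101)
        )

    def test_disjoint_zero(self):
        assert orf_overlap_fraction(sas(1, 50), orf("a", 100, 200)) == 0.0

    def test_containment_one(self):
        assert orf_overlap_fraction(sas(50, 400), orf("a", 100, 200)) == 1.0

    def test_matches_per_base_count(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s1, s2 = sorted(rng.integers(1, 2000, 2))
            o1, o2 = sorted(rng.integers(1, 2000, 2))
            o = orf("a", int(o1), int(o2) + 1)
            a = sas(int(s1), int(s2) + 1)
            per_base = len(
                set(range(a.start, a.end + 1)) & set(range(o.start, o.end + 1))
            )
            assert orf_overlap_fraction(a, o) == pytest.approx(
                per_base / o.length
            )


class TestClassifier:
    def test_two_cooriented_orfs_operon(self):
        result = classify_sas(
            sas(950, 2350), [orf("a", 1000, 1600), orf("b", 1700, 2300)]
        )
        assert result.transcript_class == "operon"
        assert result.supporting_orfs == ["a", "b"]

    def test_opposite_strand_antisense(self):
        result = classify_sas(sas(100, 200), [orf("a", 50, 250, strand="-")])
        assert result.transcript_class == "antisense"

    def test_short_orphan_intergenic(self):
        result = classify_sas(sas(1000, 1499), [orf("a", 5000, 6000)])
        assert result.transcript_class == "intergenic"
        assert "long" not in result.flags

    def test_long_orphan_flagged(self):
        result = classify_sas(sas(1000, 2000), [orf("a", 5000, 6000)])
        assert result.transcript_class == "intergenic"
        assert "long" in result.flags

    def test_sense_orf_with_upstream_extension_utr5(self):
        result = classify_sas(sas(800, 2020), [orf("a", 1000, 2000)])
        assert result.transcript_class == "utr5"

    def test_minus_strand_upstream_is_high_coordinates(self):
        result = classify_sas(
            sas(990, 2300, strand="-"), [orf("a", 1000, 2000, strand="-")]
        )
        assert result.transcript_class == "utr5"

    def test_downstream_extension_utr3(self):
        result = classify_sas(sas(990, 2300), [orf("a", 1000, 2000)])
        assert result.transcript_class == "utr3"

    def test_convergent_pair_tight_gap_overlapping_utr(self):
        result = classify_sas(
            sas(1300, 1900),
            [orf("a", 1000, 1600), orf("b", 1621, 2200, strand="-")],
        )
        assert result.transcript_class == "overlapping_utr"

    def test_convergent_pair_wide_gap_not_overlapping_utr(self):
        result = classify_sas(
            sas(1300, 1900),
            [orf("a", 1000, 1600), orf("b", 1700, 2200, strand="-")],
        )
        assert result.transcript_class != "overlapping_utr"

    def test_tight_orf_match(self):
        result = classify_sas(sas(995, 2010), [orf("a", 1000, 2000)])
        assert result.transcript_class == "orf"
        assert any(step == "orf:yes" for step in result.rule_trace)

    def test_subthreshold_contact_falls_back_antisense(self):
        # 10% sense overlap qualifies nothing; the catch-all applies
        result = classify_sas(sas(1900, 2040), [orf("a", 1000, 2000)])
        assert result.transcript_class == "antisense"
        assert "subthreshold_overlap" in result.flags

    def test_translation_invariance(self):
        orfs = [orf("a", 1000, 1600), orf("b", 1700, 2300)]
        a = classify_sas(sas(950, 2350), orfs)
        shift = 12345
        orfs_shifted = [
            orf(o.locus_tag, o.start + shift, o.end + shift, o.strand)
            for o in orfs
        ]
        b = classify_sas(sas(950 + shift, 2350 + shift), orfs_shifted)
        assert a.transcript_class == b.transcript_class


def _mirror_sas(s, L):
    return SignalArea(
        s.experiment_id, s.replicon, "-" if s.strand == "+" else "+",
        L + 1 - s.end, L + 1 - s.start, s.pseudomedian_M, s.n_probes,
    )


def _mirror_orf(o, L):
    return OrfFeature(
        o.locus_tag, o.replicon, "-" if o.strand == "+" else "+",
        L + 1 - o.end, L + 1 - o.start,
    )


def _flip_sas(s):
    return SignalArea(
        s.experiment_id, s.replicon, "-" if s.strand == "+" else "+",
        s.start, s.end, s.pseudomedian_M, s.n_probes,
    )


def _flip_orf(o):
    return OrfFeature(
        o.locus_tag, o.replicon, "-" if o.strand == "+" else "+", o.start, o.end
    )


class TestMirrorSymmetry:
    """Orientation symmetries of the rule set.

    Reflecting coordinates while flipping every strand preserves 5'/3'
    biology, so all classes are fixed; flipping strands alone turns an
    upstream extension into a downstream one, swapping utr5 and utr3 and
    leaving every other class unchanged.
    """

    @pytest.mark.parametrize("seed", range(25))
    def test_full_mirror_fixes_all_classes(self, seed):
        fx = simulate_annotation(SimulationConfig(seed=seed), "random")
        L = fx.genome_length
        for s in fx.sas:
            fwd = classify_sas(s, fx.orfs).transcript_class
            rev = classify_sas(
                _mirror_sas(s, L), [_mirror_orf(o, L) for o in fx.orfs]
            ).transcript_class
            assert rev == fwd

    @pytest.mark.parametrize("seed", range(25))
    def test_strand_flip_swaps_utr_classes(self, seed):
        fx = simulate_annotation(SimulationConfig(seed=seed), "random")
        for s in fx.sas:
            fwd = classify_sas(s, fx.orfs).transcript_class
            flipped = classify_sas(
                _flip_sas(s), [_flip_orf(o) for o in fx.orfs]
            ).transcript_class
            assert flipped == MIRROR.get(fwd, fwd)


class TestAnnotateAll:
    def test_empty_input(self):
        classified, summary = annotate_all([], [])
        assert classified == [] and summary.sum() == 0

    def test_one_per_class_summary(self):
        fx = simulate_annotation(SimulationConfig(seed=3), "one_per_class")
        classified, summary = annotate_all(fx.sas, fx.orfs)
        assert [c.display_class for c in classified] == fx.expected_labels
        for label in fx.expected_labels:
            assert summary[label] == 1

    def test_counts_sum_to_input(self):
        fx = simulate_annotation(SimulationConfig(seed=9), "random")
        _, summary = annotate_all(fx.sas, fx.orfs)
        assert int(summary.sum()) == len(fx.sas)

    def test_random_scenario_labels_match(self):
        for seed in range(10):
            fx = simulate_annotation(SimulationConfig(seed=seed), "random")
            classified, _ = annotate_all(fx.sas, fx.orfs)
            assert [c.display_class for c in classified] == fx.expected_labels

    def test_published_thresholds_are_defaults(self):
        p = AnnotationParams()
        assert p.min_orf_overlap_frac == 0.30
        assert p.overlapping_utr_max_intergenic == 30
        assert p.utr_max_gap == 30
        assert p.intergenic_max_len == 800
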