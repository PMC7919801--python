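"""Contig liftover, scaffold cuts, RBH filtering, map-expansion correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsakit.annotate import FeatureRecord
from bsakit.liftover import (
    ContigPlacement,
    Rejection,
    correct_genetic_lengths,
    cut_scaffold,
    invert_placements,
    lift_feature,
    map_expansion_factor,
    rbh_pairs,
    read_placements_agp,
)


def _placement(orientation="+"):
    return ContigPlacement(
        contig_id="ctg1",
        source_scaffold="src1",
        source_start=1,
        source_end=500_000,
        target_scaffold="chr1",
        target_start=2_001,
        target_end=502_000,
        orientation=orientation,
    )


class TestLiftFeature:
    def test_forward_offset(self):
        f = FeatureRecord("f", "gene", "src1", 10_000, 10_999, "+")
        out = lift_feature(f, [_placement("+")])
        assert (out.chrom, out.start, out.end, out.strand) == ("chr1", 12_000, 12_999, "+")

    def test_reverse_reflection_flips_strand_preserves_length(self):
        f = FeatureRecord("f", "gene", "src1", 10_000, 10_999, "+")
        out = lift_feature(f, [_placement("-")])
        assert (out.start, out.end, out.strand) == (491_002, 492_001, "-")
        assert out.end - out.start == f.end - f.start

    def test_boundary_spanning_feature_rejected_as_split(self):
        f = FeatureRecord("f", "gene", "src1", 499_900, 500_100, "+")
        out = lift_feature(f, [_placement("+")])
        assert isinstance(out, Rejection) and out.reason == "split"

    def test_unplaced_scaffold_rejected(self):
        f = FeatureRecord("f", "gene", "elsewhere", 100, 200, "+")
        out = lift_feature(f, [_placement("+")])
        assert isinstance(out, Rejection) and out.reason == "unplaced"

    def test_round_trip_identity_on_random_fixtures(self):
        """lift then inverse-lift is the identity; length always preserved."""
        rng = np.random.default_rng(10)
        placements = []
        cursor = 1
        for i in range(20):
            length = int(rng.integers(10_000, 100_000))
            placements.append(
                ContigPlacement(
                    contig_id=f"ctg{i}",
                    source_scaffold="src",
                    source_start=cursor,
                    source_end=cursor + length - 1,
                    target_scaffold=f"t{i % 4}",
                    target_start=200_000 * i + 1,
                    target_end=200_000 * i + length,
                    orientation="+-"[int(rng.integers(2))],
                )
            )
            cursor += length
        inverse = invert_placements(placements)
        accepted = 0
        for j in range(300):
            start = int(rng.integers(1, cursor - 500))
            f = FeatureRecord(
                f"f{j}", "gene", "src", start, start + int(rng.integers(1, 500)),
                "+-"[int(rng.integers(2))],
            )
            out = lift_feature(f, placements)
            if isinstance(out, Rejection):
                continue
            accepted += 1
            assert out.end - out.start == f.end - f.start
            back = lift_feature(out, inverse)
            assert back == f
        assert accepted > 100


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    start=st.integers(1, 499_000),
    length=st.integers(0, 999),
    orientation=st.sampled_from("+-"),
    strand=st.sampled_from("+-"),
)
def test_lift_round_trip_property(start, length, orientation, strand):
    """Any fully-contained feature survives lift + inverse-lift unchanged."""
    placement = _placement(orientation)
    f = FeatureRecord("f", "gene", "src1", start, min(start + length, 500_000), strand)
    out = lift_feature(f, [placement])
    assert not isinstance(out, Rejection)
    assert out.end - out.start == f.end - f.start
    assert lift_feature(out, invert_placements([placement])) == f


class TestCutScaffold:
    def test_nix_breakpoint_fragments(self):
        (f1, f2), _, _ = cut_scaffold("scaffold_3.129", 5_000_000, 2_225_968)
        assert f1.length == 2_225_968
        assert f2.length == 2_774_032
        assert f1.length + f2.length == 5_000_000

    def test_boundary_cut(self):
        (f1, f2), _, _ = cut_scaffold("s", 1_000, 999)
        assert (f1.length, f2.length) == (999, 1)

    def test_lengths_conserved_for_random_cuts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            L = int(rng.integers(2, 10_000_000))
            c = int(rng.integers(1, L))
            (f1, f2), _, _ = cut_scaffold("s", L, c)
            assert f1.length + f2.length == L

    def test_features_reindexed_and_cut_rejected(self):
        feats = [
            FeatureRecord("left", "gene", "s", 10, 20, "+"),
            FeatureRecord("span", "gene", "s", 95, 105, "+"),
            FeatureRecord("right", "gene", "s", 150, 160, "-"),
            FeatureRecord("other", "gene", "s2", 1, 5, "+"),
        ]
        (f1, f2), lifted, rejected = cut_scaffold("s", 1_000, 100, feats)
        by_id = {f.feature_id: f for f in lifted}
        assert by_id["left"].chrom == "s.1" and by_id["left"].start == 10
        assert by_id["right"].chrom == "s.2"
        assert (by_id["right"].start, by_id["right"].end) == (50, 60)
        assert by_id["other"].chrom == "s2"
        assert [r.reason for r in rejected] == ["cut"]

    def test_cut_outside_range_errors(self):
        for bad in (0, 1_000, -5):
            with pytest.raises(ValueError):
                cut_scaffold("s", 1_000, bad)


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["query", "subject", "evalue", "pident", "qcov", "bitscore"]
    )


class TestRbh:
    def test_mutual_best_kept(self):
        ab = _hits([("a1", "b1", 1e-30, 90.0, 60.0, 500.0)])
        ba = _hits([("b1", "a1", 1e-30, 90.0, 60.0, 500.0)])
        assert rbh_pairs(ab, ba) == [("a1", "b1")]

    @pytest.mark.parametrize(
        "evalue, pident, qcov, kept",
        [
            (1e-30, 90.0, 60.0, True),
            (1e-30, 80.0, 60.0, False),  # identity below 85
            (1e-10, 90.0, 60.0, False),  # e-value above 1e-20
            (1e-30, 90.0, 40.0, False),  # coverage below 50
        ],
    )
    def test_threshold_filters(self, evalue, pident, qcov, kept):
        ab = _hits([("a1", "b1", evalue, pident, qcov, 500.0)])
        ba = _hits([("b1", "a1", 1e-30, 90.0, 60.0, 500.0)])
        assert (rbh_pairs(ab, ba) == [("a1", "b1")]) is kept

    def test_non_reciprocal_dropped(self):
        ab = _hits([("a1", "b1", 1e-30, 90.0, 60.0, 500.0)])
        ba = _hits([("b1", "a2", 1e-30, 90.0, 60.0, 900.0)])
        assert rbh_pairs(ab, ba) == []

    def test_ties_break_lexicographically(self):
        ab = _hits(
            [
                ("a1", "b2", 1e-30, 90.0, 60.0, 500.0),
                ("a1", "b1", 1e-30, 90.0, 60.0, 500.0),
            ]
        )
        ba = _hits([("b1", "a1", 1e-30, 90.0, 60.0, 500.0)])
        assert rbh_pairs(ab, ba) == [("a1", "b1")]

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        queries = [f"a{i}" for i in range(40)]
        subjects = [f"b{i}" for i in range(40)]

        def random_hits(qs, ss, n):
            return _hits(
                [
                    (
                        qs[int(rng.integers(len(qs)))],
                        ss[int(rng.integers(len(ss)))],
                        10.0 ** -rng.integers(10, 40),
                        float(rng.integers(70, 100)),
                        float(rng.integers(30, 100)),
                        float(rng.integers(100, 1_000)),
                    )
                    for _ in range(n)
                ]
            )

        ab, ba = random_hits(queries, subjects, 600), random_hits(subjects, queries, 600)

        def oracle_best(hits):
            best = {}
            for r in hits.itertuples(index=False):
                if r.evalue > 1e-20 or r.pident < 85 or r.qcov < 50:
                    continue
                cur = best.get(r.query)
                if (
                    cur is None
                    or r.bitscore > cur[0]
                    or (r.bitscore == cur[0] and r.subject < cur[1])
                ):
                    best[r.query] = (r.bitscore, r.subject)
            return {q: s for q, (_, s) in best.items()}

        b_ab, b_ba = oracle_best(ab), oracle_best(ba)
        expected = sorted(
            (q, s) for q, s in b_ab.items() if b_ba.get(s) == q
        )
        assert rbh_pairs(ab, ba) == expected

    def test_empty_inputs(self):
        assert rbh_pairs(_hits([]), _hits([])) == []


class TestMapCorrection:
    @pytest.mark.parametrize("k, factor", [(7, 6), (2, 1), (3, 2)])
    def test_expansion_factor(self, k, factor):
        assert map_expansion_factor(k) == factor

    def test_pre_intercross_generation_errors(self):
        with pytest.raises(ValueError):
            map_expansion_factor(1)

    def test_f3_factor_matches_lineage_simulation(self, single_big_chrom):
        """Two mapped meioses per F3-transmitted gamete (simulated oracle)."""
        from bsakit.sim import breed_intercross, founder_pair, make_gamete

        rng = np.random.default_rng(13)
        gens = breed_intercross(
            single_big_chrom, founder_pair(single_big_chrom), 2, 400, rng
        )
        f1, f2 = gens[0], gens[1]

        def mean_lineage(parents, n=4_000):
            return np.mean(
                [
                    make_gamete(parents[rng.integers(len(parents))], single_big_chrom, rng)[
                        "1"
                    ].lineage_crossovers
                    for _ in range(n)
                ]
            )

        ratio = mean_lineage(f2) / mean_lineage(f1)
        assert ratio == pytest.approx(map_expansion_factor(3), abs=0.25)

    def test_correct_genetic_lengths(self):
        out = correct_genetic_lengths([300.0, 290.0, 310.0], 6)
        assert out.corrected_cm == pytest.approx((50.0, 290 / 6, 310 / 6))
        assert out.lower_bound is True
        ident = correct_genetic_lengths([42.0], 1)
        assert ident.corrected_cm == (42.0,)

    def test_invalid_lengths_or_factor(self):
        with pytest.raises(ValueError):
            correct_genetic_lengths([10.0], 0.5)
        with pytest.raises(ValueError):
            correct_genetic_lengths([-1.0], 2)


class TestAgpReader:
    def test_component_lines_parsed_and_gaps_skipped(self, tmp_path, caplog):
        agp = tmp_path / "p.agp"
        agp.write_text(
            "# header\n"
            "chr1\t1\t500000\t1\tW\tctg1\t1\t500000\t+\n"
            "chr1\t500001\t500100\t2\tN\t100\tscaffold\tyes\tmap\n"
            "chr1\t500101\t600100\t3\tW\tctg2\t1\t100000\t?\n"
        )
        placements = read_placements_agp(agp)
        assert len(placements) == 2
        assert placements[0].target_scaffold == "chr1"
        assert placements[0].source_scaffold == "ctg1"
        assert placements[1].orientation == "+"  # '?' coerced with warning

    def test_malformed_line_reports_position(self, tmp_path):
        agp = tmp_path / "bad.agp"
        agp.write_text("chr1\t1\t10\n")
        with pytest.raises(ValueError, match="line 1"):
            read_placements_agp(agp)
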