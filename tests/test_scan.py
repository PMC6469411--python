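from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pevk.scan import (
    FIRST_LANDMARK,
    LAST_LANDMARK,
    CandidateRegion,
    ScanParams,
    find_pevk_exons,
    landmark_identity,
    merge_windows,
    pevk_ratio,
    resolve_frames,
    resolve_splice_bounds,
    scan_windows,
    trim_to_region,
)
from pevk.scan import PevkExon
from pevk.sequence_io import GenomicSequence, translate_frame
from pevk.synthetic import SyntheticTitinSpec, generate_titin

from scan_oracle import oracle_exons


def _ft(aa, frame=0):
    from pevk.sequence_io import FrameTranslation

    return FrameTranslation(frame=frame, aa_seq=aa, origin="t")


class TestPevkRatio:
    @pytest.mark.parametrize(
        "aa,expected",
        [
            ("PEVK", 1.0),
            ("LLLLLLLLLL", 0.0),
            (FIRST_LANDMARK, 19 / 27),
            (LAST_LANDMARK, 13 / 15),
        ],
    )
    def test_values(self, aa, expected):
        # independent per-residue tally as cross-check
        tally = sum(Counter(aa)[c] for c in "PEVKA") / len(aa)
        assert pevk_ratio(aa) == pytest.approx(expected)
        assert pevk_ratio(aa) == pytest.approx(tally)

    def test_x_and_stop_are_non_pevk(self):
        assert pevk_ratio("PX*K") == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pevk_ratio("")


class TestScanWindows:
    def test_single_full_window(self):
        assert scan_windows(_ft("PPPPPPPPPP"), ScanParams()) == [(0, 10)]

    def test_best_window_below_threshold(self):
        assert scan_windows(_ft("PPPPPLLLLLLLLLL"), ScanParams()) == []

    def test_only_first_window_passes(self):
        assert scan_windows(_ft("PPPPPPLLLLLLLLL"), ScanParams()) == [(0, 10)]

    def test_threshold_is_inclusive(self):
        # 27/50 = 0.54 exactly
        aa = "P" * 27 + "L" * 23
        assert scan_windows(_ft(aa), ScanParams(window_len=50)) == [(0, 50)]

    @given(st.text(alphabet="PEVKALIST", min_size=10, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_enumeration(self, aa):
        params = ScanParams()
        expected = [
            (i, i + 10)
            for i in range(len(aa) - 9)
            if sum(c in "PEVKA" for c in aa[i : i + 10]) / 10 >= 0.54
        ]
        assert scan_windows(_ft(aa), params) == expected


class TestMergeWindows:
    def test_overlapping_merge(self):
        assert [
            (c.aa_start, c.aa_end) for c in merge_windows([(0, 10), (1, 11)], _ft("P" * 20))
        ] == [(0, 11)]

    def test_disjoint_stay_separate(self):
        cands = merge_windows([(0, 10), (20, 30)], _ft("P" * 40))
        assert [(c.aa_start, c.aa_end) for c in cands] == [(0, 10), (20, 30)]

    def test_abutting_not_merged(self):
        cands = merge_windows([(0, 10), (10, 20)], _ft("P" * 30))
        assert [(c.aa_start, c.aa_end) for c in cands] == [(0, 10), (10, 20)]

    def test_nt_interval_attached(self):
        (c,) = merge_windows([(2, 12)], _ft("P" * 20, frame=1))
        assert (c.nt_start, c.nt_end) == (7, 37)


def _candidate_for(genome, lo, hi):
    frame = lo % 3
    aa_lo = (lo - frame) // 3
    aa_hi = (hi - frame) // 3
    return CandidateRegion(frame, aa_lo, aa_hi, lo, hi)


# 36 nt encoding PEVKPEVKPEVK with no internal AG/GT
E36 = "CCTGAAGTTAAA" * 3


class TestResolveSpliceBounds:
    def test_planted_unique_pair(self):
        g = GenomicSequence("g", "C" * 40 + "AG" + E36 + "GT" + "C" * 40)
        exon = resolve_splice_bounds(_candidate_for(g, 42, 78), g, ScanParams())
        assert (exon.start, exon.end) == (42, 78)
        assert exon.nt_seq == E36
        # oracle: the admissible pair is unique
        accs = [s for s in range(2, len(g)) if g.residues[s - 2 : s] == "AG"]
        dons = [e for e in range(len(g) - 1) if g.residues[e : e + 2] == "GT"]
        admissible = [
            (s, e) for s in accs for e in dons if e - s >= 36 and s < 78 and e > 42
        ]
        assert admissible == [(42, 78)]

    def test_minimum_distance_rule(self):
        g = GenomicSequence(
            "g", "C" * 40 + "AG" + E36 + "GT" + "CCCC" + "GT" + "C" * 40
        )
        exon = resolve_splice_bounds(_candidate_for(g, 42, 78), g, ScanParams())
        assert (exon.start, exon.end) == (42, 78)

    def test_no_acceptor_within_flank_discards(self):
        g = GenomicSequence("g", "C" * 40 + E36 + "GT" + "C" * 40)
        assert resolve_splice_bounds(_candidate_for(g, 42, 76), g, ScanParams()) is None

    def test_flank_clipped_at_sequence_ends(self):
        g = GenomicSequence("g", "AG" + E36 + "GT")
        exon = resolve_splice_bounds(_candidate_for(g, 3, 36), g, ScanParams())
        assert (exon.start, exon.end) == (2, 38)


def _exon(start, end, frame, ratio):
    return PevkExon(start, end, frame, "A" * (end - start), "K" * ((end - start) // 3), ratio)


class TestResolveFrames:
    def test_identical_across_frames_collapsed(self):
        out = resolve_frames([_exon(0, 30, 0, 0.8), _exon(0, 30, 1, 0.8)])
        assert len(out) == 1 and out[0].frame == 0

    def test_highest_ratio_wins(self):
        out = resolve_frames([_exon(0, 30, 0, 0.7), _exon(10, 40, 2, 0.9)])
        assert len(out) == 1 and out[0].frame == 2

    def test_disjoint_kept_sorted(self):
        out = resolve_frames([_exon(50, 80, 1, 0.9), _exon(0, 30, 0, 0.7)])
        assert [(x.start, x.end) for x in out] == [(0, 30), (50, 80)]


class TestFindPevkExons:
    def test_recovers_planted_exons_exactly(self, small_sim):
        _, genome, truth = small_sim
        exons = find_pevk_exons(genome)
        assert [(x.start, x.end) for x in exons] == truth.intervals()

    def test_all_intron_genome_empty(self):
        from pevk.synthetic import _intron
        import numpy as np

        g = GenomicSequence("introns", _intron(np.random.default_rng(0), 3000))
        assert len(find_pevk_exons(g)) == 0

    def test_low_ratio_exon_absent_at_default_threshold(self):
        # plant an exon at PEVK ratio 0.40 whose codons (K=AAA, F=TTT,
        # I=ATT) keep every reading frame below threshold; it must never
        # seed a candidate at min_ratio 0.54
        from pevk.synthetic import _intron
        import numpy as np

        aa = ("KFI" * 7)[:20] + "K"  # 8 K over 21 aa ~ 0.38
        codon = {"K": "AAA", "F": "TTT", "I": "ATT"}
        nt = "".join(codon[c] for c in aa)
        rng = np.random.default_rng(1)
        g = GenomicSequence("low", _intron(rng, 300) + "AG" + nt + "GT" + _intron(rng, 300))
        for ft in (translate_frame(g, f) for f in (0, 1, 2)):
            assert scan_windows(ft, ScanParams()) == []
        assert len(find_pevk_exons(g)) == 0

    def test_equals_brute_force_oracle_on_short_sequences(self):
        params = ScanParams()
        for seed in range(5):
            spec = SyntheticTitinSpec(
                n_exons=(3, 2, 0),
                intron_len={"N": (80, 140), "CA": (80, 120), "CB": (80, 120)},
                n_decoys=1,
                n_runs=0,
                flank_len=80,
                seed=seed,
            )
            genome, _ = generate_titin(spec)
            assert genome.length <= 2000
            ours = [(x.start, x.end) for x in find_pevk_exons(genome, params)]
            assert ours == oracle_exons(genome, params)

    def test_determinism(self, small_sim):
        _, genome, _ = small_sim
        a = find_pevk_exons(genome)
        b = find_pevk_exons(genome)
        assert [(x.start, x.end, x.frame, x.nt_seq, x.aa_seq, x.ratio) for x in a] == [
            (x.start, x.end, x.frame, x.nt_seq, x.aa_seq, x.ratio) for x in b
        ]

    def test_splice_law_and_seed_law(self, default_sim, default_exons):
        _, genome, _ = default_sim
        params = ScanParams()
        assert len(default_exons) > 0
        for x in default_exons:
            assert genome.residues[x.start - 2 : x.start] == "AG"
            assert genome.residues[x.end : x.end + 2] == "GT"
            assert x.source_candidate is not None
            # the seeding candidate contains >= 1 above-threshold window
            ft = translate_frame(genome, x.source_candidate.frame)
            c = x.source_candidate
            best = max(
                pevk_ratio(ft.aa_seq[i : i + params.window_len])
                for i in range(c.aa_start, c.aa_end - params.window_len + 1)
            )
            assert best >= params.min_ratio

    def test_monotone_in_min_ratio(self, small_sim):
        _, genome, _ = small_sim
        counts = [
            len(find_pevk_exons(genome, ScanParams(min_ratio=r)))
            for r in (0.45, 0.54, 0.65, 0.75, 0.85, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)


class TestTrimToRegion:
    def test_trims_to_landmarks(self, default_sim, default_exons):
        _, _, truth = default_sim
        trimmed = trim_to_region(default_exons)
        assert len(trimmed) == len(default_exons)  # landmarks are first/last
        assert not trimmed.warnings
        # drop the landmark exons and the trim must warn
        inner = default_exons
        from pevk.scan import ExonSet

        no_marks = ExonSet(inner.origin, inner.params, inner.exons[1:-1])
        untrimmed = trim_to_region(no_marks)
        assert len(untrimmed) == len(no_marks)
        assert untrimmed.warnings

    def test_landmark_with_two_mismatches_recognized(self):
        mutated = "QQ" + FIRST_LANDMARK[2:]
        assert landmark_identity(mutated, FIRST_LANDMARK) >= 25 / 27
        assert landmark_identity(mutated, FIRST_LANDMARK) >= 0.8

    def test_identity_of_exact_match(self):
        assert landmark_identity("XX" + LAST_LANDMARK + "YY", LAST_LANDMARK) == 1.0
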