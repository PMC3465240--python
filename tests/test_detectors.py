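"""Compositional regions, poly-A tracts, repeats, track import, screening."""

from __future__ import annotations

import numpy as np
import pytest

from crmsearch.core import InputError, Sequence, revcomp
from crmsearch.detectors import (CompositionThresholds, composition_thresholds,
                                 detect_composition_regions, detect_poly_a,
                                 detect_repeats, gc_fraction, import_track,
                                 repeats_to_instances, screen_feature)

from conftest import inst, make_set, random_dna
import oracles


class TestCompositionThresholds:
    def test_three_sigma_bounds(self):
        # a positive set with per-sequence GC mean 0.488 and SD 0.0289
        # discriminates at 0.401 (low) and 0.575 (high)
        thr = CompositionThresholds.from_stats(0.488, 0.0289)
        assert round(thr.low, 3) == 0.401
        assert round(thr.high, 3) == 0.575

    def test_computed_from_sequences(self):
        # GC fractions 0.25, 0.5, 0.75 -> mean 0.5, sample SD 0.25
        sset = make_set("pos", [("a", "ACTT"), ("b", "ACGT"), ("c", "ACGG")])
        thr = composition_thresholds(sset, min_len=2)
        assert thr.gc_mean == pytest.approx(0.5)
        assert thr.gc_sd == pytest.approx(0.25)
        assert thr.low == pytest.approx(-0.25)

    def test_zero_sd_collapses_bounds(self):
        thr = CompositionThresholds.from_stats(0.5, 0.0)
        assert thr.low == thr.high == 0.5

    def test_single_sequence_rejected(self):
        with pytest.raises(InputError):
            composition_thresholds(make_set("pos", [("a", "ACGT")]))


class TestCompositionRegions:
    THR = CompositionThresholds.from_stats(0.488, 0.0289)

    def test_pure_at_block(self):
        seq = Sequence(id="s", residues="A" * 200)
        (reg,) = detect_composition_regions(seq, self.THR)
        assert (reg.feature, reg.start, reg.end) == ("at_rich", 0, 200)

    def test_pure_gc_block(self):
        seq = Sequence(id="s", residues="GC" * 100)
        (reg,) = detect_composition_regions(seq, self.THR)
        assert (reg.feature, reg.start, reg.end) == ("gc_rich", 0, 200)

    def test_short_sequence_empty(self):
        assert detect_composition_regions(
            Sequence(id="s", residues="ACGT"), self.THR) == []

    def test_matches_window_oracle(self, rng):
        thr = CompositionThresholds.from_stats(0.5, 0.05, min_len=20)
        for _ in range(30):
            # blocky sequences so qualifying regions actually occur
            parts = []
            for _ in range(int(rng.integers(2, 6))):
                gc = float(rng.choice([0.1, 0.5, 0.9]))
                parts.append(random_dna(rng, int(rng.integers(10, 60)), gc=gc))
            residues = "".join(parts)
            got = {(r.feature, r.start, r.end) for r in
                   detect_composition_regions(Sequence(id="s", residues=residues), thr)}
            want = oracles.brute_composition_regions(residues, thr.low,
                                                     thr.high, 20)
            want_set = {(cls, s, e) for cls, ivs in want.items()
                        for s, e in ivs}
            assert got == want_set

    def test_reverse_complement_mirrors_regions(self, rng):
        thr = CompositionThresholds.from_stats(0.5, 0.05, min_len=20)
        residues = "".join(
            random_dna(rng, 40, gc=float(g)) for g in (0.1, 0.5, 0.95, 0.5))
        n = len(residues)
        fwd = detect_composition_regions(Sequence(id="s", residues=residues), thr)
        rev = detect_composition_regions(
            Sequence(id="s", residues=revcomp(residues)), thr)
        mirrored = {(r.feature, n - r.end, n - r.start) for r in rev}
        assert {(r.feature, r.start, r.end) for r in fwd} == mirrored


class TestPolyA:
    def test_eight_mer_rule(self):
        for residues, expected in (("AAAAAAAA", True), ("AAATAAAA", True),
                                   ("AATTAAAA", False)):
            hits = detect_poly_a(Sequence(id="s", residues="G" + residues + "G"))
            assert bool(hits) is expected

    def test_merged_tracts(self):
        seq = Sequence(id="s", residues="GG" + "A" * 12 + "GG")
        raw = detect_poly_a(seq)
        # windows 1..7: the flanking G windows carry exactly one mismatch
        assert [(h.start, h.end) for h in raw] == [(i, i + 8) for i in range(1, 8)]
        (tract,) = detect_poly_a(seq, merge=True)
        assert (tract.start, tract.end) == (1, 15)

    def test_matches_window_oracle(self, rng):
        for _ in range(30):
            residues = random_dna(rng, 60, gc=0.2)  # A/T rich
            got = [(h.start, h.end) for h in
                   detect_poly_a(Sequence(id="s", residues=residues))]
            assert got == oracles.brute_poly_a(residues, 8, 1)

    def test_parameter_validation(self):
        with pytest.raises(InputError):
            detect_poly_a(Sequence(id="s", residues="ACGT"), k=4, max_mismatch=4)


class TestRepeats:
    def test_spec_direct_repeat(self):
        arm = "ACGTACGTAC"
        seq = Sequence(id="s", residues=arm + "N" * 20 + arm)
        reps = detect_repeats(seq)
        direct = [r for r in reps if r.kind == "direct"]
        assert [(r.arm1, r.arm2) for r in direct] == [((0, 10), (30, 40))]
        (fi,) = repeats_to_instances(seq, direct)
        assert fi.feature == "direct_repeat_neutral"
        assert (fi.start, fi.end) == (0, 40)

    def test_gc_rich_arm_classification(self):
        arm = "GGGGGCCCCC"
        seq = Sequence(id="s", residues=arm + "ATATATATAT" + arm)
        reps = [r for r in detect_repeats(seq) if r.kind == "direct"]
        insts = repeats_to_instances(seq, reps)
        assert any(i.feature == "direct_repeat_rich" for i in insts)

    def test_inverted_repeat(self):
        arm = "ACCGTTAGCA"
        seq = Sequence(id="s", residues=arm + "T" * 15 + revcomp(arm))
        reps = detect_repeats(seq)
        inv = [r for r in reps if r.kind == "inverted"]
        assert ((0, 10), (25, 35)) in [(r.arm1, r.arm2) for r in inv]

    def test_spacer_limit(self, rng):
        arm = "ACGTTGCAGG"
        spacer = random_dna(rng, 40)
        seq = Sequence(id="s", residues=arm + spacer + arm)
        planted = ((0, 10), (50, 60))
        tight = [(r.arm1, r.arm2) for r in detect_repeats(seq, max_spacer=39)]
        loose = [(r.arm1, r.arm2) for r in detect_repeats(seq, max_spacer=40)]
        assert planted not in tight
        assert planted in loose

    def test_matches_quadratic_oracle(self, rng):
        # two-letter alphabet on short sequences so repeats are plentiful
        for _ in range(20):
            residues = random_dna(rng, int(rng.integers(30, 90)), alphabet="AC")
            got = {(r.kind, r.arm1, r.arm2)
                   for r in detect_repeats(Sequence(id="s", residues=residues),
                                           min_arm=6, max_spacer=500)}
            want = oracles.brute_repeats(residues, 6, 500)
            assert got == want


class TestTrackImport:
    def test_bed_roundtrip(self, tmp_path):
        from crmsearch.io import write_bed

        instances = [inst("p1", 0, 10, "tss", "+", 0.9),
                     inst("p1", 40, 55, "tss", "-", 0.5),
                     inst("p2", 5, 9, "tss")]
        path = tmp_path / "t.bed"
        write_bed(instances, path)
        assert len(path.read_text().splitlines()) == 3
        back = import_track(str(path))
        assert [(i.seq, i.start, i.end, i.strand) for i in back] == \
            [(i.seq, i.start, i.end, i.strand) for i in instances]

    def test_gff3_coordinate_convention(self, tmp_path):
        path = tmp_path / "t.gff3"
        path.write_text("##gff-version 3\n"
                        "p1\tsidd\tregion\t101\t160\t.\t+\t.\tID=x\n")
        (i,) = import_track(str(path))
        assert (i.start, i.end, i.feature) == (100, 160, "sidd")

    def test_gff3_roundtrip_identity(self, tmp_path, rng):
        from crmsearch.io import write_gff3

        instances = [inst(f"p{int(rng.integers(3))}", s := int(rng.integers(90)),
                          s + int(rng.integers(1, 10)), "f", "+-"[int(rng.integers(2))])
                     for _ in range(20)]
        path = tmp_path / "t.gff3"
        write_gff3(instances, path)
        back = import_track(str(path))
        assert sorted((i.seq, i.start, i.end, i.strand) for i in back) == \
            sorted((i.seq, i.start, i.end, i.strand) for i in instances)

    def test_unknown_sequence_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "t.bed"
        path.write_text("p1\t0\t10\tf\np9\t0\t10\tf\n")
        with caplog.at_level("WARNING"):
            back = import_track(str(path), known_ids={"p1"})
        assert [i.seq for i in back] == ["p1"]
        assert "p9" in caplog.text

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("p1\t0\n")
        with pytest.raises(InputError):
            import_track(str(path))


class TestScreening:
    def test_poly_a_like_feature_passes_default_screen(self):
        # C+ = 0.77, C- = 0.47: inside the default boundary conditions
        pos = make_set("pos", [(f"p{i}", "A" * 100) for i in range(13)])
        neg = make_set("neg", [(f"n{i}", "A" * 300) for i in range(100)])
        instances = ([inst(f"p{i}", 0, 8, "poly_a") for i in range(10)]
                     + [inst(f"n{i}", 0, 8, "poly_a") for i in range(47)])
        accepted, stats = screen_feature(instances, pos, neg)
        assert accepted
        assert f"{stats.c_pos:.2f}" == "0.77" and f"{stats.c_neg:.2f}" == "0.47"

    def test_unspecific_feature_fails(self):
        pos = make_set("pos", [(f"p{i}", "A" * 100) for i in range(4)])
        neg = make_set("neg", [(f"n{i}", "A" * 100) for i in range(4)])
        instances = ([inst(f"p{i}", 0, 8, "x") for i in range(4)]
                     + [inst(f"n{i}", 0, 8, "x") for i in range(4)])
        accepted, _ = screen_feature(instances, pos, neg)
        assert not accepted

    def test_gc_fraction_ignores_n(self):
        assert gc_fraction("GCNN") == 1.0
        assert gc_fraction("NN") == 0.0

    def test_track_score_dispersion(self):
        from crmsearch.detectors import track_score_dispersion

        insts = [inst("p1", 0, 10, "sidd", score=s)
                 for s in (0.1, 0.2, 0.3, 0.4)]
        assert track_score_dispersion(insts) == pytest.approx(
            np.std([0.1, 0.2, 0.3, 0.4], ddof=1))
        assert track_score_dispersion(insts[:1]) is None
        unscored = [inst("p1", 0, 10, "tss")]
        assert track_score_dispersion(unscored) is None
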