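import random

import pytest
from hypothesis import given, settings, strategies as st

from helpers import rle_compress, sliding_edit_distance
from nanobarcoder.align import levenshtein, revcomp
from nanobarcoder.demux import (DemuxConfig, Read, assign_tag_from_flank,
                                compress_homopolymers, demultiplex,
                                extract_and_assign_tag, find_primer,
                                length_filter, split_ligated)
from nanobarcoder.simulate import HCO2198, LCO1490, amplicon
from nanobarcoder.tags import build_mutant_index


class TestLengthFilter:
    def test_boundaries(self):
        reads = [Read("a", "A" * 735), Read("b", "A" * 599),
                 Read("c", "A" * 600)]
        kept, stats = length_filter(reads, 600)
        assert [r.id for r in kept] == ["a", "c"]
        assert stats == {"total": 3, "kept": 2, "removed": 1}

    def test_empty_input(self):
        kept, stats = length_filter([], 600)
        assert kept == [] and stats["total"] == 0


class TestFindPrimer:
    def test_exact_primer_at_read_start(self):
        read = Read("r", LCO1490 + "ACGT" * 50)
        hit = find_primer(read, LCO1490)
        assert hit.errors == 0 and hit.strand == "+"
        assert (hit.start, hit.end) == (0, len(LCO1490))

    def test_two_substitutions_at_offset_position_matches_oracle(self):
        rng = random.Random(1)
        prefix = "".join(rng.choice("ACGT") for _ in range(13))
        mutated = list(LCO1490)
        mutated[3] = "C" if mutated[3] != "C" else "G"
        mutated[10] = "C" if mutated[10] != "C" else "G"
        read = Read("r", prefix + "".join(mutated) + "T" * 600)
        hit = find_primer(read, LCO1490)
        assert hit.errors == 2
        errs, end = sliding_edit_distance(LCO1490, read.sequence[:100])
        assert errs == 2 and hit.end == end

    def test_reverse_strand_hit_near_read_end(self):
        read = Read("r", "ACGT" * 160 + revcomp(LCO1490))
        hit = find_primer(read, LCO1490)
        assert hit.strand == "-" and hit.end == len(read.sequence)

    def test_random_sequence_has_no_hit(self):
        rng = random.Random(2)
        read = Read("r", "".join(rng.choice("ACGT") for _ in range(700)))
        assert find_primer(read, LCO1490, max_errors=4) is None


class TestCompressHomopolymers:
    def test_run_truncated(self):
        assert compress_homopolymers("AAAAAG") == "AAAG"

    def test_no_long_run_unchanged(self):
        assert compress_homopolymers("ACGTACGT") == "ACGTACGT"

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT", max_size=40),
           st.integers(min_value=1, max_value=5))
    def test_matches_rle_oracle(self, seq, max_run):
        assert compress_homopolymers(seq, max_run) == rle_compress(seq, max_run)


@pytest.fixture(scope="module")
def fwd_index(small_tagsets):
    return build_mutant_index(small_tagsets[0])


class TestTagAssignment:
    def test_exact_tag_in_flank(self, small_tagsets, fwd_index):
        tag = small_tagsets[0].tags[0]
        flank = "ACGTACG" + tag.sequence  # 7 upstream nt + tag
        assert assign_tag_from_flank(flank, fwd_index) == tag

    def test_tag_with_homopolymer_run_error_recovered(self, small_tagsets,
                                                      fwd_index):
        # nanopore run-length errors extend existing homopolymers: blow a
        # doubled base up to a 5-run; compression truncates it back to 3,
        # leaving the tag within the 2-edit tolerance
        tag = next(t for t in small_tagsets[0].tags
                   if any(a == b for a, b in zip(t.sequence, t.sequence[1:])))
        s = tag.sequence
        i = next(i for i in range(len(s) - 1) if s[i] == s[i + 1])
        broken = s[:i] + s[i] * 3 + s[i:]  # run of 2 -> run of 5
        assert assign_tag_from_flank("CTACGTA" + broken, fwd_index) == tag

    def test_unmatchable_flank_returns_none(self, fwd_index):
        assert assign_tag_from_flank("GCGCGCGCGCGCGCGCGCGC", fwd_index) is None

    def test_extract_left_and_right_flanks(self, small_tagsets):
        fwd, rev = small_tagsets
        ftag, rtag = fwd.tags[0], rev.tags[0]
        seq = (ftag.sequence + LCO1490 + "ACGT" * 160
               + revcomp(HCO2198) + revcomp(rtag.sequence))
        read = Read("r", seq)
        fhit = find_primer(read, LCO1490)
        rhit = find_primer(read, HCO2198)
        fi = build_mutant_index(fwd)
        ri = build_mutant_index(rev)
        assert extract_and_assign_tag(read, fhit, fi, side="left") == ftag
        assert extract_and_assign_tag(read, rhit, ri, side="right") == rtag


class TestSplitLigated:
    def test_normal_read_passes_through(self):
        r = Read("r", "A" * 735)
        subs, flagged = split_ligated(r, LCO1490, HCO2198)
        assert subs == [r] and not flagged

    def test_error_free_dimer_splits_into_two_products(self, mini_run):
        t1, t2 = mini_run["truth"][0], mini_run["truth"][1]
        dimer = Read("d", amplicon(t1) + amplicon(t2))
        assert len(dimer) == 1470
        subs, flagged = split_ligated(dimer, LCO1490, HCO2198)
        assert len(subs) == 2 and not flagged
        assert subs[0].sequence == amplicon(t1)
        assert subs[1].sequence == amplicon(t2)

    def test_overlong_read_flagged_unsplit(self):
        r = Read("r", "A" * 2500)
        subs, flagged = split_ligated(r, LCO1490, HCO2198)
        assert subs == [r] and flagged


class TestDemultiplex:
    def test_zero_error_reads_fully_recovered(self, zero_error_run):
        zr = zero_error_run
        fi = build_mutant_index(zr["fwd"])
        ri = build_mutant_index(zr["rev"])
        bins, summary = demultiplex(zr["reads"], LCO1490, HCO2198, fi, ri,
                                    zr["layout"])
        assert set(summary.status) == {"assigned"}
        man = dict(zip(zr["manifest"].read_id, zr["manifest"].specimen_id))
        for specimen, b in bins.items():
            for r in b.reads:
                assert man[r.id] == specimen
        assert sum(b.coverage for b in bins.values()) == len(zr["reads"])

    def test_trimmed_reads_are_forward_template_region(self, zero_error_run):
        zr = zero_error_run
        fi = build_mutant_index(zr["fwd"])
        ri = build_mutant_index(zr["rev"])
        bins, _ = demultiplex(zr["reads"], LCO1490, HCO2198, fi, ri,
                              zr["layout"])
        templates = {t.specimen_id: t.template for t in zr["truth"]}
        for specimen, b in bins.items():
            for r in b.reads:
                assert r.sequence == templates[specimen]

    def test_conservation_of_read_units(self, mini_run):
        mr = mini_run
        fi = build_mutant_index(mr["fwd"])
        ri = build_mutant_index(mr["rev"])
        bins, summary = demultiplex(mr["reads"], LCO1490, HCO2198, fi, ri,
                                    mr["layout"])
        counts = summary.status.value_counts().to_dict()
        assert sum(counts.values()) == len(summary)
        assert counts.get("assigned", 0) == \
            sum(b.coverage for b in bins.values())
        # every read unit lands in exactly one category
        assert summary.read_id.is_unique

    def test_invariant_under_reverse_complement(self, mini_run):
        mr = mini_run
        fi = build_mutant_index(mr["fwd"])
        ri = build_mutant_index(mr["rev"])
        subset = mr["reads"][:80]
        flipped = [Read(r.id, revcomp(r.sequence)) for r in subset]
        b1, s1 = demultiplex(subset, LCO1490, HCO2198, fi, ri, mr["layout"])
        b2, s2 = demultiplex(flipped, LCO1490, HCO2198, fi, ri, mr["layout"])
        a1 = dict(zip(s1.read_id, s1.specimen_id))
        a2 = dict(zip(s2.read_id, s2.specimen_id))
        assert a1 == a2

    def test_misassignment_into_unused_combinations_is_rare(self, mini_run):
        mr = mini_run
        fi = build_mutant_index(mr["fwd"])
        ri = build_mutant_index(mr["rev"])
        _, summary = demultiplex(mr["reads"], LCO1490, HCO2198, fi, ri,
                                 mr["layout"])
        man = mr["manifest"].set_index("read_id")
        demuxed = summary[summary.status.isin(["assigned",
                                               "unused_combination"])]
        mis = 0
        for r in demuxed.itertuples():
            base = r.read_id.split("/")[0]
            if r.status == "unused_combination" and \
                    man.loc[base, "category"] != "unused_combo":
                mis += 1
        assert mis / max(1, len(demuxed)) < 0.01

    def test_read_with_single_resolvable_tag_unassigned(self, small_tagsets):
        fwd, rev = small_tagsets
        ftag = fwd.tags[0]
        # reverse flank carries no valid tag
        seq = (ftag.sequence + LCO1490 + "ACGT" * 160
               + revcomp(HCO2198) + "GCGCGCGCGCGCG")
        fi, ri = build_mutant_index(fwd), build_mutant_index(rev)
        import pandas as pd
        layout = pd.DataFrame([{"plate": "P1", "well": "A1",
                                "specimen_id": "s1",
                                "fwd_tag": ftag.sequence,
                                "rev_tag": rev.tags[0].sequence,
                                "is_negative": False}])
        bins, summary = demultiplex([Read("r", seq)], LCO1490, HCO2198,
                                    fi, ri, layout)
        assert not bins
        assert summary.status.tolist() == ["tag_unresolved"]


def brute_force_assign(read, fwd_tags, rev_tags, cfg=DemuxConfig()):
    """Oracle: orient by best primer, then try every tag at every flank
    offset/length with direct edit distance <= 2."""
    from nanobarcoder.align import infix_search

    seq = read.sequence.upper()
    hf = infix_search(LCO1490, seq[:100], cfg.primer_max_errors)
    hr = infix_search(HCO2198, seq[:100], cfg.primer_max_errors)
    if hr is not None and (hf is None or hr[2] < hf[2]):
        seq = revcomp(seq)
    oriented = Read(read.id, seq)
    fhit = find_primer(oriented, LCO1490, "f")
    rhit = find_primer(oriented, HCO2198, "r")
    if fhit is None or fhit.strand != "+" or rhit is None or rhit.strand != "-":
        return None

    def resolve(flank, tags):
        comp = compress_homopolymers(flank)
        found = []
        for start in range(len(comp) - 1, -1, -1):
            for length in range(11, 16):
                w = comp[start:start + length]
                if len(w) < length:
                    continue
                within = [t for t in tags if levenshtein(w, t) <= 2]
                if len(within) == 1 and within[0] not in found:
                    found.append(within[0])
        return found[0] if len(found) == 1 else None

    f = resolve(seq[max(0, fhit.start - 20):fhit.start], fwd_tags)
    r = resolve(revcomp(seq[rhit.end:rhit.end + 20]), rev_tags)
    if f is None or r is None:
        return None
    return (f, r)


def test_oracle_equivalence_with_brute_force(mini_run):
    """Bin assignment equals the brute-force all-tags/all-offsets method."""
    mr = mini_run
    fwd_tags = mr["fwd"].sequences
    rev_tags = mr["rev"].sequences
    fi = build_mutant_index(mr["fwd"])
    ri = build_mutant_index(mr["rev"])
    pair_to_specimen = {(r.fwd_tag, r.rev_tag): r.specimen_id
                        for r in mr["layout"].itertuples()}
    reads = [r for r in mr["reads"] if len(r) < 1300][:400]
    _, summary = demultiplex(reads, LCO1490, HCO2198, fi, ri, mr["layout"],
                             DemuxConfig(split_dimers=False))
    got = dict(zip(summary.read_id, summary.specimen_id))
    status = dict(zip(summary.read_id, summary.status))
    for read in reads:
        expect = brute_force_assign(read, fwd_tags, rev_tags)
        if expect is None:
            assert status[read.id] in ("no_primer_pair", "tag_unresolved")
        else:
            specimen = pair_to_specimen.get(expect)
            if specimen is None:
                assert status[read.id] == "unused_combination"
            else:
                assert got[read.id] == specimen
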