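import numpy as np

from nanobarcoder.consensus import Barcode
from nanobarcoder.correct import (CorrectionParams, aa_correct,
                                  choose_reference, consolidate,
                                  count_stops, detect_frame,
                                  final_translation_check, translate)
from nanobarcoder.qc import per_base_accuracy
from nanobarcoder.simulate import ClusterSpec, make_templates


class TestDetectFrame:
    def test_example_barcode_has_stop_free_frame(self, example_barcode):
        ann = detect_frame(example_barcode)
        assert ann.stops == 0
        assert (ann.frame, ann.strand) == (0, "+")
        assert ann.translatable

    def test_frameshift_introduces_stops(self, example_barcode):
        # a mid-sequence deletion leaves half the barcode out of frame in
        # every fixed frame, so stops appear downstream
        mid = len(example_barcode) // 2
        shifted = example_barcode[:mid] + example_barcode[mid + 1:]
        ann = detect_frame(shifted)
        assert ann.stops >= 1

    def test_all_n_is_untranslatable(self):
        ann = detect_frame("N" * 120)
        assert not ann.translatable

    def test_reverse_strand_detected(self, example_barcode):
        from nanobarcoder.align import revcomp
        ann = detect_frame(revcomp(example_barcode))
        assert ann.strand == "-" and ann.stops == 0


class TestAaCorrect:
    def test_indel_free_barcode_unchanged(self, example_barcode):
        bc = Barcode("s", example_barcode, "draft", 10)
        out = aa_correct(bc, example_barcode)
        assert not out.rejected
        assert out.barcode.sequence == example_barcode
        assert out.barcode.stage == "draft_corrected"

    def test_single_deletion_repaired_over_many_cases(self, example_barcode):
        """A 1-nt deletion anywhere is repaired to within 1 nt of truth."""
        rng = np.random.default_rng(12)
        truth = example_barcode
        params = CorrectionParams(namino=2)
        for _ in range(100):
            pos = int(rng.integers(30, len(truth) - 30))
            broken = truth[:pos] + truth[pos + 1:]
            out = aa_correct(Barcode("s", broken, "draft", 5), truth, params)
            assert not out.rejected
            fixed = out.barcode.sequence
            assert len(fixed) == len(truth)
            # frame restored; the rare residual stop is masked by the
            # final translation check
            checked, _ = final_translation_check(out.barcode)
            assert count_stops(checked.sequence) == 0
            rec = per_base_accuracy(fixed, truth)
            assert rec.identity >= (len(truth) - 2) / len(truth)

    def test_single_insertion_repaired(self, example_barcode):
        rng = np.random.default_rng(13)
        truth = example_barcode
        for _ in range(40):
            pos = int(rng.integers(30, len(truth) - 30))
            base = "ACGT"[int(rng.integers(4))]
            broken = truth[:pos] + base + truth[pos:]
            out = aa_correct(Barcode("s", broken, "draft", 5), truth)
            assert not out.rejected
            assert len(out.barcode.sequence) == len(truth)
            assert count_stops(out.barcode.sequence) == 0

    def test_five_consecutive_insertions_rejected(self, example_barcode):
        broken = example_barcode[:200] + "ACGTA" + example_barcode[200:]
        out = aa_correct(Barcode("s", broken, "draft", 5), example_barcode)
        assert out.rejected and out.reason == "consecutive_indels"

    def test_four_consecutive_indels_still_corrected(self, example_barcode):
        broken = example_barcode[:200] + example_barcode[204:]
        out = aa_correct(Barcode("s", broken, "draft", 5), example_barcode)
        assert not out.rejected
        assert len(out.barcode.sequence) == len(example_barcode)

    def test_never_leaves_frameshift(self, example_barcode):
        """Output length offset is consistent with the reference frame."""
        rng = np.random.default_rng(3)
        truth = example_barcode
        for _ in range(30):
            s = truth
            for _ in range(int(rng.integers(1, 4))):
                p = int(rng.integers(30, len(s) - 30))
                if rng.random() < 0.5:
                    s = s[:p] + s[p + 1:]
                else:
                    s = s[:p] + "ACGT"[int(rng.integers(4))] + s[p:]
            out = aa_correct(Barcode("s", s, "draft", 5), truth)
            if out.rejected:
                continue
            assert len(out.barcode.sequence) % 3 == len(truth) % 3
            assert count_stops(out.barcode.sequence) <= count_stops(truth) + 1


class TestChooseReference:
    def test_best_match_selected_leave_one_out(self):
        spec = ClusterSpec(n_species=2, specimens_per_species=3)
        templates, labels = make_templates(spec, seed=7)
        lib = {f"t{i}": t for i, t in enumerate(templates)}
        got = choose_reference(templates[0], lib, exclude="t0")
        assert got is not None
        # the chosen reference is a conspecific (distance < 2%)
        name, seq = got
        assert labels[int(name[1:])] == labels[0]

    def test_below_identity_cutoff_returns_none(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        assert choose_reference(a, {"b": b}, min_identity=0.9) is None


class TestFinalTranslationCheck:
    def test_stop_free_barcode_unchanged(self, example_barcode):
        bc = Barcode("s", example_barcode, "draft_corrected", 5)
        out, count = final_translation_check(bc)
        assert out.sequence == example_barcode and count == 0

    def test_single_stop_codon_masked(self):
        seq = "ATGGCT" + "TAA" + "GCTGCT"
        out, count = final_translation_check(Barcode("s", seq, "draft", 5))
        assert count == 1
        assert out.sequence == "ATGGCT" + "NNN" + "GCTGCT"

    def test_two_stops_masked_and_counted(self):
        seq = "ATG" + "TAG" + "GCT" + "TAA" + "GCT"
        out, count = final_translation_check(Barcode("s", seq, "draft", 5))
        assert count == 2
        assert out.sequence.count("N") == 6


class TestConsolidate:
    def test_identical_inputs_pass_through(self, example_barcode):
        a = Barcode("s", example_barcode, "draft_corrected", 5)
        b = Barcode("s", example_barcode, "polished_corrected", 7)
        out = consolidate(a, b)
        assert not out.rejected
        assert out.barcode.sequence == example_barcode
        assert out.barcode.stage == "consolidated"

    def test_substitution_conflict_becomes_n(self, example_barcode):
        s2 = list(example_barcode)
        s2[100] = "G" if s2[100] != "G" else "A"
        a = Barcode("s", example_barcode, "draft_corrected", 5)
        b = Barcode("s", "".join(s2), "polished_corrected", 5)
        out = consolidate(a, b)
        assert not out.rejected
        assert out.barcode.sequence[100] == "N"
        assert out.barcode.sequence.count("N") == 1

    def test_ambiguity_defers_to_determined_base(self, example_barcode):
        s2 = list(example_barcode)
        s2[50] = "N"
        a = Barcode("s", "".join(s2), "draft_corrected", 5)
        b = Barcode("s", example_barcode, "polished_corrected", 5)
        out = consolidate(a, b)
        assert out.barcode.sequence == example_barcode

    def test_length_difference_forcing_gap_rejected(self, example_barcode):
        a = Barcode("s", example_barcode, "draft_corrected", 5)
        b = Barcode("s", example_barcode[:300] + example_barcode[303:],
                    "polished_corrected", 5)
        out = consolidate(a, b)
        assert out.rejected and out.reason == "indel_conflict"

    def test_idempotent_on_agreement(self, example_barcode):
        a = Barcode("s", example_barcode, "draft_corrected", 5)
        out = consolidate(a, a)
        assert out.barcode.sequence == a.sequence

    def test_single_track_passes_with_flag(self, example_barcode):
        a = Barcode("s", example_barcode, "draft_corrected", 5)
        out = consolidate(a, None)
        assert not out.rejected
        assert "single_track" in out.barcode.flags


def test_namino_recovery_sweep(example_barcode):
    """All window sizes repair frameshifts to well above the uncorrected
    baseline, and the default (2) is within 0.1% of both alternatives;
    with conservative edits (delete insertions, insert N) the window size
    has little residual effect."""
    rng = np.random.default_rng(21)
    truth = example_barcode
    acc = {1: [], 2: [], 3: []}
    cases = []
    for _ in range(200):
        s = truth
        for _ in range(int(rng.integers(1, 3))):
            p = int(rng.integers(30, len(s) - 30))
            if rng.random() < 0.6:
                s = s[:p] + s[p + 1:]
            else:
                s = s[:p] + "ACGT"[int(rng.integers(4))] + s[p:]
        cases.append(s)
    for namino in (1, 2, 3):
        params = CorrectionParams(namino=namino)
        for s in cases:
            out = aa_correct(Barcode("s", s, "draft", 5), truth, params)
            if out.rejected:
                continue
            acc[namino].append(per_base_accuracy(out.barcode.sequence,
                                                 truth).identity)
    m = {k: float(np.mean(v)) for k, v in acc.items()}
    baseline = float(np.mean([per_base_accuracy(s, truth).identity
                              for s in cases]))
    for namino in (1, 2, 3):
        assert m[namino] > baseline
    assert m[2] >= m[1] - 0.001
    assert m[2] >= m[3] - 0.001
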