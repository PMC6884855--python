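"""Amino-acid-guided correction of residual indel errors in COI barcodes.

Protein-coding barcodes must translate without stop codons, which makes
frameshifts detectable and repairable: the barcode is aligned to a
homologous reference of known reading frame, and at every alignment indel
the candidate repairs (delete the inserted bases, or insert N — never a
guessed base) are scored by amino-acid identity to the reference
translation over a window of `namino` codons on each side of the indel.
Barcodes with five or more consecutive indels are considered
irrecoverable and rejected. A final translation check replaces any
remaining in-frame stop codon by NNN. The two corrected consensus tracks
(draft-based and polish-based) are then consolidated by strict consensus;
if their alignment requires gaps even at an elevated gap-opening penalty,
the barcode is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .align import global_alignment, levenshtein
from .consensus import Barcode

INVERTEBRATE_MITO_TABLE = 5
DEFAULT_NAMINO = 2
DEFAULT_MAX_CONSECUTIVE_INDELS = 5
DEFAULT_MIN_REFERENCE_IDENTITY = 0.70
DEFAULT_CONSOLIDATE_GAP_OPEN = 3.0
UNTRANSLATABLE_STOPS = 10


@dataclass
class CorrectionParams:
    namino: int = DEFAULT_NAMINO
    max_consecutive_indels: int = DEFAULT_MAX_CONSECUTIVE_INDELS
    table: int = INVERTEBRATE_MITO_TABLE

    def __post_init__(self):
        if self.namino not in (1, 2, 3):
            raise ValueError("namino must be 1, 2 or 3")


@dataclass
class FrameAnnotation:
    frame: int
    strand: str
    stops: int
    translatable: bool = True


@dataclass
class CorrectionOutcome:
    barcode: Barcode | None
    rejected: bool = False
    reason: str = ""
    n_edits: int = 0
    n_stops_masked: int = 0


def translate(seq: str, table: int = INVERTEBRATE_MITO_TABLE,
              frame: int = 0) -> str:
    s = seq.upper()[frame:]
    s = s[:len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate(table=table))


def count_stops(seq: str, table: int = INVERTEBRATE_MITO_TABLE,
                frame: int = 0) -> int:
    return translate(seq, table, frame).count("*")


def detect_frame(seq: str, table: int = INVERTEBRATE_MITO_TABLE
                 ) -> FrameAnnotation:
    """Reading frame and strand minimizing stop codons.

    Ties break toward frame 0 on the + strand. The sequence is flagged
    untranslatable when even the best frame has more than 10 stops, or
    when ambiguities leave fewer than half of the codons with a determined
    amino acid (e.g. an all-N input).
    """
    if len(seq) < 30:
        raise ValueError("sequence too short for frame detection")
    best = None
    rc = str(Seq(seq.upper()).reverse_complement())
    for strand, s in (("+", seq.upper()), ("-", rc)):
        for frame in range(3):
            aa = translate(s, table, frame)
            stops = aa.count("*")
            cand = (stops, 0 if strand == "+" else 1, frame)
            if best is None or cand < best:
                best = cand
                determined = 1 - aa.count("X") / max(1, len(aa))
                ann = FrameAnnotation(frame, strand, stops)
                ann.translatable = (stops <= UNTRANSLATABLE_STOPS
                                    and determined >= 0.5)
    return ann


def choose_reference(query: str, library: dict[str, str],
                     min_identity: float = DEFAULT_MIN_REFERENCE_IDENTITY,
                     exclude: str | None = None) -> tuple[str, str] | None:
    """Best homologous reference by global identity; None below cutoff."""
    best_id, best = None, -1.0
    for name, seq in library.items():
        if name == exclude:
            continue
        aln_len = max(len(query), len(seq))
        if aln_len == 0:
            continue
        ident = 1 - levenshtein(query.upper(), seq.upper()) / aln_len
        if ident > best:
            best, best_id = ident, name
    if best_id is None or best < min_identity:
        return None
    return best_id, library[best_id]


def _indel_events(qa: str, ra: str):
    """Maximal runs of gapped alignment columns, as
    (q_consumed_before, r_consumed_before, n_ins, n_del, run_len)."""
    events = []
    qi = ri = col = 0
    n = len(qa)
    while col < n:
        if qa[col] == "-" or ra[col] == "-":
            q0, r0 = qi, ri
            n_ins = n_del = run = 0
            while col < n and (qa[col] == "-" or ra[col] == "-"):
                if ra[col] == "-":
                    n_ins += 1
                    qi += 1
                else:
                    n_del += 1
                    ri += 1
                run += 1
                col += 1
            events.append((q0, r0, n_ins, n_del, run))
        else:
            qi += 1
            ri += 1
            col += 1
    return events


def _max_indel_run(qa: str, ra: str) -> int:
    """Longest stretch of indel columns, merging gap runs separated by a
    single matched column (alignment paths may split a contiguous block of
    inserted bases around one coincidental match)."""
    best = cur = 0
    pending_match = False
    for x, y in zip(qa, ra):
        if x == "-" or y == "-":
            cur += 1
            best = max(best, cur)
            pending_match = False
        elif not pending_match and cur > 0:
            pending_match = True  # one match does not break the run
        else:
            cur = 0
            pending_match = False
    return best


def _window_score(corrected: str, reference: str, ref_frame: int,
                  r_event: int, offset: int, namino: int, table: int) -> float:
    """Amino-acid identity to the reference over namino codons on each side
    of the event. `offset` maps corrected coordinates to reference
    coordinates (ref_pos = corrected_pos + offset) local to the event."""
    c_event = max(0, (r_event - ref_frame)) // 3
    n_codons = (len(reference) - ref_frame) // 3
    c_lo = max(0, c_event - namino)
    c_hi = min(n_codons - 1, c_event + namino)
    if c_hi < c_lo:
        return 0.0
    rs = ref_frame + 3 * c_lo
    length = 3 * (c_hi - c_lo + 1)
    qs = rs - offset
    if qs < 0 or qs + length > len(corrected):
        # clip to full codons available in the query
        while qs < 0:
            qs += 3
            rs += 3
            length -= 3
        while length > 0 and qs + length > len(corrected):
            length -= 3
        if length <= 0:
            return 0.0
    ref_aa = translate(reference[rs:rs + length], table)
    qry_aa = translate(corrected[qs:qs + length], table)
    if not ref_aa:
        return 0.0
    matches = sum(a == b for a, b in zip(qry_aa, ref_aa))
    return matches / len(ref_aa)


def aa_correct(barcode: Barcode, reference: str,
               params: CorrectionParams | None = None,
               ref_frame: int = 0) -> CorrectionOutcome:
    """Repair frameshifts in a consensus barcode against a homologous
    reference.

    Insertions relative to the reference are repaired by deleting the
    inserted bases; deletions by inserting N (a base is never guessed).
    The exact repair position is chosen among candidates within namino
    codons of the alignment indel by maximizing amino-acid identity to the
    reference translation (ties: leftmost). Rejects the barcode iff the
    alignment contains a run of >= max_consecutive_indels indel columns.
    """
    params = params or CorrectionParams()
    seq = barcode.sequence.upper()
    reference = reference.upper()
    qa, ra, _ = global_alignment(seq, reference)
    events = _indel_events(qa, ra)
    if _max_indel_run(qa, ra) >= params.max_consecutive_indels:
        return CorrectionOutcome(None, rejected=True,
                                 reason="consecutive_indels")
    work = seq
    n_edits = 0
    window = params.namino * 3
    for q0, r0, n_ins, n_del, _ in reversed(events):
        net = n_ins - n_del
        if net == 0:
            continue
        offset = r0 - q0  # local corrected->reference offset after repair
        candidates = range(max(0, q0 - window),
                           min(len(work) - max(net, 0), q0 + window) + 1)
        best_q, best_score = None, -1.0
        for q in candidates:
            if net > 0:
                cand = work[:q] + work[q + net:]
            else:
                cand = work[:q] + "N" * (-net) + work[q:]
            score = _window_score(cand, reference, ref_frame, r0, offset,
                                  params.namino, params.table)
            if score > best_score:
                best_score, best_q = score, q
        q = best_q if best_q is not None else q0
        if net > 0:
            work = work[:q] + work[q + net:]
        else:
            work = work[:q] + "N" * (-net) + work[q:]
        n_edits += 1

    stage = ("draft_corrected" if barcode.stage == "draft"
             else "polished_corrected")
    out = Barcode(barcode.specimen_id, work, stage, barcode.coverage,
                  flags=list(barcode.flags))
    return CorrectionOutcome(out, n_edits=n_edits)


def final_translation_check(barcode: Barcode, frame: int = 0,
                            table: int = INVERTEBRATE_MITO_TABLE
                            ) -> tuple[Barcode, int]:
    """Replace every remaining in-frame stop codon by NNN; returns the
    checked barcode and the replacement count."""
    seq = list(barcode.sequence.upper())
    n = len(seq)
    count = 0
    for i in range(frame, n - 2, 3):
        codon = "".join(seq[i:i + 3])
        if translate(codon, table) == "*":
            seq[i:i + 3] = ["N", "N", "N"]
            count += 1
    out = Barcode(barcode.specimen_id, "".join(seq), barcode.stage,
                  barcode.coverage, flags=list(barcode.flags))
    return out, count


def consolidate(a: Barcode | None, b: Barcode | None,
                gap_open: float = DEFAULT_CONSOLIDATE_GAP_OPEN
                ) -> CorrectionOutcome:
    """Strict consensus of the two corrected barcode tracks.

    Both inputs are translatable, so their pairwise alignment at an
    elevated gap-opening penalty should be gap-free; if any gap remains
    the barcode is rejected. Per position: agreement keeps the base, a
    substitution conflict becomes N, and N in one track defers to the
    other track's base. A single available track passes through flagged.
    """
    if a is None and b is None:
        return CorrectionOutcome(None, rejected=True, reason="no_input")
    if a is None or b is None:
        src = a or b
        out = Barcode(src.specimen_id, src.sequence, "consolidated",
                      src.coverage, flags=src.flags + ["single_track"])
        return CorrectionOutcome(out)
    sa, sb = a.sequence.upper(), b.sequence.upper()
    if sa == sb:
        return CorrectionOutcome(Barcode(a.specimen_id, sa, "consolidated",
                                         max(a.coverage, b.coverage)))
    from Bio.Align import PairwiseAligner
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -1
    aln = aligner.align(sa, sb)[0]
    qa, ta = str(aln[0]), str(aln[1])
    if "-" in qa or "-" in ta:
        return CorrectionOutcome(None, rejected=True, reason="indel_conflict")
    out = []
    for x, y in zip(qa, ta):
        if x == y:
            out.append(x)
        elif x == "N":
            out.append(y)
        elif y == "N":
            out.append(x)
        else:
            out.append("N")
    bc = Barcode(a.specimen_id, "".join(out), "consolidated",
                 max(a.coverage, b.coverage))
    return CorrectionOutcome(bc)
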