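"""Error-tolerant demultiplexing of tagged 1D nanopore amplicon reads.

Each read is assigned to a specimen by (1) locating the tagged PCR primers
within the first/last 100 bp, (2) extracting a 20-bp flank outward of each
primer, compressing homopolymer runs > 3 nt (nanopore's characteristic
run-length errors), and (3) looking up every 13-nt window of the
compressed flank in a precomputed mutant index that tolerates up to 2 tag
errors of any type. Both tags must resolve uniquely for a read to be
binned. Reads of 1300-2000 nt are first split in two, since two amplicons
occasionally ligate during library preparation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import infix_search, revcomp
from .tags import MutantIndex, Tag

DEFAULT_MIN_LEN = 600
DEFAULT_PRIMER_WINDOW = 100
DEFAULT_PRIMER_MAX_ERRORS = 6
DEFAULT_FLANK = 20
DEFAULT_COMPRESS_RUN = 3
SPLIT_MIN_LEN = 1300
SPLIT_MAX_LEN = 2000
SPLIT_SEARCH_FROM = 650
TAG_LENGTH = 13


@dataclass
class Read:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrimerHit:
    primer: str         # primer name
    strand: str         # "+" | "-"
    start: int          # 0-based half-open on the read
    end: int
    errors: int


@dataclass
class DemuxBin:
    specimen_id: str
    reads: list[Read] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        return len(self.reads)


@dataclass
class DemuxConfig:
    min_len: int = DEFAULT_MIN_LEN
    primer_window: int = DEFAULT_PRIMER_WINDOW
    primer_max_errors: int = DEFAULT_PRIMER_MAX_ERRORS
    flank: int = DEFAULT_FLANK
    compress_run: int = DEFAULT_COMPRESS_RUN
    split_dimers: bool = True


def length_filter(reads: list[Read], min_len: int = DEFAULT_MIN_LEN
                  ) -> tuple[list[Read], dict]:
    """Drop reads shorter than `min_len` (default 600 nt, well below the
    735-nt tagged product)."""
    kept = [r for r in reads if len(r) >= min_len]
    stats = {"total": len(reads), "kept": len(kept),
             "removed": len(reads) - len(kept)}
    return kept, stats


def find_primer(read: Read | str, primer: str, primer_name: str = "primer",
                window: int = DEFAULT_PRIMER_WINDOW,
                max_errors: int = DEFAULT_PRIMER_MAX_ERRORS) -> PrimerHit | None:
    """Best semi-global occurrence of the primer near either read end.

    The forward-strand primer is searched in the first `window` bp, its
    reverse complement in the last `window` bp; the better hit wins. IUPAC
    degeneracies in the primer match their expansions. Returns None if the
    best hit has more than `max_errors` edits.
    """
    seq = read.sequence if isinstance(read, Read) else read
    seq = seq.upper()
    hits = []
    head = seq[:window]
    h = infix_search(primer, head, max_errors)
    if h:
        hits.append(PrimerHit(primer_name, "+", h[0], h[1], h[2]))
    tail_off = max(0, len(seq) - window)
    tail = seq[tail_off:]
    h = infix_search(revcomp(primer), tail, max_errors)
    if h:
        hits.append(PrimerHit(primer_name, "-", tail_off + h[0],
                              tail_off + h[1], h[2]))
    if not hits:
        return None
    return min(hits, key=lambda x: x.errors)


def compress_homopolymers(seq: str, max_run: int = DEFAULT_COMPRESS_RUN) -> str:
    """Truncate every homopolymer run longer than `max_run` to `max_run`."""
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    out = []
    run = 0
    prev = None
    for c in seq:
        run = run + 1 if c == prev else 1
        if run <= max_run:
            out.append(c)
        prev = c
    return "".join(out)


def assign_tag_from_flank(flank: str, index: MutantIndex,
                          max_run: int = DEFAULT_COMPRESS_RUN) -> Tag | None:
    """Resolve the tag carried by a primer-adjacent flank.

    The flank must be oriented so the tag reads in index orientation with
    the primer to its right. After homopolymer compression every window of
    a length the index can resolve (13 +/- max_errors nt, so indel-hit
    tags are still found) is looked up; windows closest to the primer are
    tried first. A unique resolved tag is returned; None if nothing
    matches or two windows resolve to different tags.
    """
    comp = compress_homopolymers(flank.upper(), max_run)
    found: list[Tag] = []
    lengths = range(TAG_LENGTH - index.max_errors,
                    TAG_LENGTH + index.max_errors + 1)
    for start in range(len(comp) - 1, -1, -1):
        for length in lengths:
            if start + length > len(comp):
                continue
            tag = index.lookup(comp[start:start + length])
            if tag is not None and tag not in found:
                found.append(tag)
    if len(found) == 1:
        return found[0]
    return None


def extract_and_assign_tag(read: Read | str, hit: PrimerHit,
                           index: MutantIndex, flank: int = DEFAULT_FLANK,
                           side: str = "left",
                           max_run: int = DEFAULT_COMPRESS_RUN) -> Tag | None:
    """Extract the `flank` bp outward of a primer hit and resolve its tag.

    side="left": flank upstream of the hit, read as-is (forward tag).
    side="right": flank downstream, reverse-complemented before lookup
    (the reverse tag appears reverse-complemented on the forward strand).
    """
    seq = (read.sequence if isinstance(read, Read) else read).upper()
    if side == "left":
        fl = seq[max(0, hit.start - flank):hit.start]
    elif side == "right":
        fl = revcomp(seq[hit.end:hit.end + flank])
    else:
        raise ValueError("side must be 'left' or 'right'")
    if len(fl) < TAG_LENGTH - index.max_errors:
        return None
    return assign_tag_from_flank(fl, index, max_run)


def split_ligated(read: Read, fwd_primer: str, rev_primer: str,
                  max_errors: int = DEFAULT_PRIMER_MAX_ERRORS
                  ) -> tuple[list[Read], bool]:
    """Split a ligated double-amplicon read into its two products.

    Reads < 1300 nt pass through; reads in [1300, 2000) are searched for
    the start of a second product (either primer, literal orientation)
    after position 650 and split 13 nt upstream of that primer so the
    second product keeps its tag; reads >= 2000 nt pass through flagged
    (only two-product reads are handled).
    """
    n = len(read)
    if n < SPLIT_MIN_LEN:
        return [read], False
    if n >= SPLIT_MAX_LEN:
        return [read], True
    tail = read.sequence[SPLIT_SEARCH_FROM:]
    best = None
    for primer in (fwd_primer, rev_primer):
        h = infix_search(primer, tail, max_errors)
        if h and (best is None or h[2] < best[2]):
            best = h
    if best is None:
        return [read], True
    cut = max(0, SPLIT_SEARCH_FROM + best[0] - TAG_LENGTH)
    if cut == 0 or cut >= n:
        return [read], True
    return [Read(f"{read.id}/1", read.sequence[:cut]),
            Read(f"{read.id}/2", read.sequence[cut:])], False


def _demux_one(read: Read, fwd_primer: str, rev_primer: str,
               fwd_index: MutantIndex, rev_index: MutantIndex,
               cfg: DemuxConfig) -> tuple[str, Tag, Tag, Read] | str:
    """Assign one (sub)read. Returns (status, fwd_tag, rev_tag, trimmed
    oriented read) on success, else a failure reason string."""
    seq = read.sequence.upper()
    # orient: the forward primer sits at the start of a forward-strand read,
    # the reverse primer at the start of a reverse-strand read
    hf = infix_search(fwd_primer, seq[:cfg.primer_window], cfg.primer_max_errors)
    hr = infix_search(rev_primer, seq[:cfg.primer_window], cfg.primer_max_errors)
    if hr is not None and (hf is None or hr[2] < hf[2]):
        seq = revcomp(seq)
    oriented = Read(read.id, seq)
    fhit = find_primer(oriented, fwd_primer, "fwd", cfg.primer_window,
                       cfg.primer_max_errors)
    rhit = find_primer(oriented, rev_primer, "rev", cfg.primer_window,
                       cfg.primer_max_errors)
    if fhit is None or fhit.strand != "+" or rhit is None or rhit.strand != "-":
        return "no_primer_pair"
    ftag = extract_and_assign_tag(oriented, fhit, fwd_index, cfg.flank,
                                  side="left", max_run=cfg.compress_run)
    rtag = extract_and_assign_tag(oriented, rhit, rev_index, cfg.flank,
                                  side="right", max_run=cfg.compress_run)
    if ftag is None or rtag is None:
        return "tag_unresolved"
    trimmed = Read(read.id, seq[fhit.end:rhit.start])
    return ("ok", ftag, rtag, trimmed)


def demultiplex(reads: list[Read], fwd_primer: str, rev_primer: str,
                fwd_index: MutantIndex, rev_index: MutantIndex,
                layout: pd.DataFrame, cfg: DemuxConfig | None = None
                ) -> tuple[dict[str, DemuxBin], pd.DataFrame]:
    """Demultiplex a read set against a plate layout.

    Layout columns: specimen_id, fwd_tag, rev_tag (tag sequences). Reads
    resolving to a tag pair absent from the layout are counted separately
    as unused-combination reads — on real data that count estimates the
    demultiplexing error rate. Bin reads are stored primer-trimmed and
    oriented to the forward strand. Returns (bins, summary) where summary
    is one row per read unit (post length-filter, post splitting).
    """
    cfg = cfg or DemuxConfig()
    pair_to_specimen = {(r.fwd_tag, r.rev_tag): r.specimen_id
                        for r in layout.itertuples()}
    kept, _ = length_filter(reads, cfg.min_len)
    units: list[Read] = []
    for r in kept:
        if cfg.split_dimers:
            subs, _ = split_ligated(r, fwd_primer, rev_primer,
                                    cfg.primer_max_errors)
            units.extend(subs)
        else:
            units.append(r)

    bins: dict[str, DemuxBin] = {}
    records = []
    for unit in units:
        res = _demux_one(unit, fwd_primer, rev_primer, fwd_index, rev_index, cfg)
        if isinstance(res, str):
            records.append({"read_id": unit.id, "status": res,
                            "specimen_id": ""})
            continue
        _, ftag, rtag, trimmed = res
        key = (ftag.sequence, rtag.sequence)
        specimen = pair_to_specimen.get(key)
        if specimen is None:
            records.append({"read_id": unit.id, "status": "unused_combination",
                            "specimen_id": f"{ftag.tag_id}+{rtag.tag_id}"})
            continue
        bins.setdefault(specimen, DemuxBin(specimen)).reads.append(trimmed)
        records.append({"read_id": unit.id, "status": "assigned",
                        "specimen_id": specimen})
    return bins, pd.DataFrame(records)


def demux_summary_table(bins: dict[str, DemuxBin],
                        summary: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen coverage table plus global status counts."""
    rows = [{"specimen_id": s, "coverage": b.coverage}
            for s, b in sorted(bins.items())]
    return pd.DataFrame(rows)
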