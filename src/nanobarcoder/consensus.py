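"""Per-specimen consensus barcode calling.

A draft barcode is called from a random subsample of up to 100 reads per
bin: the reads are multiply aligned with zero gap-opening cost so that
indel and substitution evidence stays staggered, and a >= 50% per-column
majority rule is applied (columns where gaps dominate emit nothing; a
modal base below 50% emits N). The draft is then polished by re-aligning
every bin read to it, discarding reads above 15% divergence, and re-voting
the columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import alignment_divergence, center_star_msa
from .demux import DemuxBin, Read

DEFAULT_SUBSAMPLE = 100
DEFAULT_MIN_COV = 5
DEFAULT_MAX_AMBIGUITY = 0.01
DEFAULT_MAX_DIVERGENCE = 0.15

STAGES = ("draft", "polished", "draft_corrected", "polished_corrected",
          "consolidated")


@dataclass
class Barcode:
    specimen_id: str
    sequence: str
    stage: str = "draft"
    coverage: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def ambiguity_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return self.sequence.upper().count("N") / len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ColumnProfile:
    index: int
    counts: Counter
    depth: int


def subsample(bin_: DemuxBin, n: int = DEFAULT_SUBSAMPLE,
              seed: int = 0) -> list[Read]:
    """Uniform subsample of min(n, coverage) reads without replacement,
    reproducible per seed."""
    if bin_.coverage <= n:
        return list(bin_.reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(bin_.coverage, size=n, replace=False)
    return [bin_.reads[i] for i in sorted(idx)]


def align_bin(reads: list[str], center_index: int | None = None) -> list[str]:
    """Multiple alignment of bin reads (zero gap-opening cost, center-star
    progressive heuristic; identical reads align gap-free)."""
    if not reads:
        raise ValueError("empty bin")
    return center_star_msa(reads, center_index)


def column_profiles(msa: list[str]) -> list[ColumnProfile]:
    width = len(msa[0])
    profiles = []
    for j in range(width):
        counts = Counter(row[j] for row in msa)
        profiles.append(ColumnProfile(j, counts, sum(counts.values())))
    return profiles


def majority_consensus(msa: list[str], specimen_id: str = "",
                       min_cov: int = DEFAULT_MIN_COV,
                       stage: str = "draft") -> Barcode | None:
    """Per-column >= 50% majority consensus.

    Depth counts every row including gap characters. A column whose gap
    frequency is >= 50% of depth emits nothing; otherwise the modal base
    is emitted if it reaches >= 50% of depth (ties at exactly 50% call the
    base), and N is emitted when no base reaches 50% or two bases tie for
    the mode. Bins with fewer than `min_cov` reads yield no barcode.
    """
    if len(msa) < min_cov:
        return None
    out = []
    for prof in column_profiles(msa):
        depth = prof.depth
        gaps = prof.counts.get("-", 0)
        if gaps * 2 >= depth:
            continue
        base_counts = [(c, n) for c, n in prof.counts.items() if c != "-"]
        base_counts.sort(key=lambda x: -x[1])
        top, top_n = base_counts[0]
        tie = len(base_counts) > 1 and base_counts[1][1] == top_n
        if top_n * 2 >= depth and not tie and top in "ACGT":
            out.append(top)
        else:
            out.append("N")
    return Barcode(specimen_id=specimen_id, sequence="".join(out),
                   stage=stage, coverage=len(msa))


def call_draft(bin_: DemuxBin, n_subsample: int = DEFAULT_SUBSAMPLE,
               min_cov: int = DEFAULT_MIN_COV, seed: int = 0) -> Barcode | None:
    """Subsample, align and vote; reported coverage is the full bin size."""
    if bin_.coverage < min_cov:
        return None
    reads = subsample(bin_, n_subsample, seed)
    msa = align_bin([r.sequence for r in reads])
    bc = majority_consensus(msa, bin_.specimen_id, min_cov)
    if bc is not None:
        bc.coverage = bin_.coverage
    return bc


def filter_draft(barcode: Barcode,
                 max_ambiguity: float = DEFAULT_MAX_AMBIGUITY) -> bool:
    """Accept a preliminary barcode iff its N fraction is below the cap
    (default < 1% ambiguous bases)."""
    return barcode.ambiguity_fraction < max_ambiguity


def polish(draft: Barcode, bin_: DemuxBin,
           max_divergence: float = DEFAULT_MAX_DIVERGENCE) -> Barcode:
    """Re-align every bin read to the draft and re-vote the columns.

    Reads whose divergence to the draft exceeds `max_divergence` (default
    0.15, sized for 1D nanopore error rates) are excluded. If every read
    is excluded, the draft is returned flagged as unpolishable.
    """
    included = [r.sequence for r in bin_.reads
                if alignment_divergence(r.sequence.upper(),
                                        draft.sequence) <= max_divergence]
    if not included:
        out = Barcode(draft.specimen_id, draft.sequence, "polished",
                      draft.coverage, flags=["polish_failed"])
        return out
    msa = center_star_msa([draft.sequence] + included, center_index=0)
    bc = majority_consensus(msa[1:], draft.specimen_id, min_cov=1,
                            stage="polished")
    bc.coverage = draft.coverage
    return bc
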