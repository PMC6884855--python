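"""Design and validation of 13-nt demultiplexing tags.

Tags are appended to the PCR primers so that every specimen in a pooled
nanopore run carries a unique (forward, reverse) tag pair. Because 1D
nanopore reads are indel-rich, tag sets are screened with a full edit
distance (any combination of insertions/deletions/substitutions), not just
Hamming distance, and homopolymeric tags are excluded. Demultiplexing then
tolerates up to `max_errors` (default 2) tag errors via a precomputed
lookup of every reachable mutant string.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .align import levenshtein

DNA = "ACGT"
DEFAULT_TAG_LENGTH = 13
DEFAULT_MIN_EDIT = 3
DEFAULT_EXCLUDED_MOTIF = "GG"
DEFAULT_MAX_HOMOPOLYMER = 2


@dataclass(frozen=True)
class Tag:
    """A single demultiplexing tag tied to one primer side."""

    sequence: str
    role: str  # "forward" | "reverse"
    tag_id: str = ""
    deprecated: bool = False

    def __post_init__(self):
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward/reverse, got {self.role!r}")
        if any(c not in DNA for c in self.sequence):
            raise ValueError(f"tag {self.sequence!r} not over A/C/G/T")


@dataclass
class TagSet:
    """A validated set of tags with its achieved minimum pairwise distance."""

    tags: list[Tag]
    min_pairwise_edit: int = 0
    excluded_motif: str = DEFAULT_EXCLUDED_MOTIF

    def __post_init__(self):
        seqs = [t.sequence for t in self.tags]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate tag sequences")
        self.min_pairwise_edit = min_pairwise_distance(seqs)

    @property
    def sequences(self) -> list[str]:
        return [t.sequence for t in self.tags]

    def __len__(self) -> int:
        return len(self.tags)


@dataclass
class MutantIndex:
    """Lookup from every string within `max_errors` edits of a tag back to
    that tag. Strings reachable from two or more tags are ambiguous: they
    are kept out of the map and listed in `collisions`."""

    index: dict[str, Tag] = field(default_factory=dict)
    max_errors: int = 2
    collisions: set[str] = field(default_factory=set)

    def lookup(self, seq: str) -> Tag | None:
        return self.index.get(seq)

    def __len__(self) -> int:
        return len(self.index)


def min_pairwise_distance(seqs: list[str]) -> int:
    if len(seqs) < 2:
        return 0
    return min(levenshtein(a, b) for a, b in itertools.combinations(seqs, 2))


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = None
    for c in seq:
        run = run + 1 if c == prev else 1
        best = max(best, run)
        prev = c
    return best


def generate_candidates(n: int, length: int = DEFAULT_TAG_LENGTH,
                        min_dist: int = 6, seed: int = 0,
                        max_attempts_per_tag: int = 50000) -> list[str]:
    """Rejection-sample `n` tags of `length` nt, all pairwise at Hamming
    distance >= min_dist (Hamming lower-bounds Levenshtein for equal-length
    strings, and is what a first-pass tag generator screens).

    Deterministic for a fixed seed. Raises if the constraint cannot be met
    within the attempt budget (e.g. an infeasible n for short tags).
    """
    import numpy as np

    if n < 1:
        raise ValueError("n must be >= 1")
    if length < min_dist:
        raise ValueError("length must be >= min_dist")
    rng = np.random.default_rng(seed)
    placed = np.empty((n, length), dtype=np.uint8)
    k = 0
    attempts = 0
    while k < n:
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        attempts += 1
        if k == 0 or int((placed[:k] != cand).sum(axis=1).min()) >= min_dist:
            placed[k] = cand
            k += 1
            attempts = 0
        elif attempts > max_attempts_per_tag:
            raise RuntimeError(
                f"could not place tag {k + 1}/{n} at min_dist="
                f"{min_dist} within {max_attempts_per_tag} attempts")
    return ["".join(DNA[b] for b in row) for row in placed]


def filter_tagset(candidates: list[str], excluded_motif: str = DEFAULT_EXCLUDED_MOTIF,
                  min_edit: int = DEFAULT_MIN_EDIT,
                  max_homopolymer: int = DEFAULT_MAX_HOMOPOLYMER,
                  role: str = "forward") -> TagSet:
    """Apply the tag-set screens: drop homopolymeric candidates (runs longer
    than `max_homopolymer`), drop candidates ending in `excluded_motif`
    (which would extend the primer start), then recursively eliminate until
    every pair differs by >= `min_edit` edits of any type.

    Recursive elimination drops, at each round, the candidate involved in
    the largest number of sub-threshold pairs (ties broken lexicographically).
    """
    kept = [c.upper() for c in candidates]
    kept = [c for c in kept if max_homopolymer_run(c) <= max_homopolymer]
    if excluded_motif:
        kept = [c for c in kept if not c.endswith(excluded_motif.upper())]
    # dedupe, preserving order
    kept = list(dict.fromkeys(kept))

    while True:
        bad_pairs = [(a, b) for a, b in itertools.combinations(kept, 2)
                     if levenshtein(a, b) < min_edit]
        if not bad_pairs:
            break
        counts: dict[str, int] = {}
        for a, b in bad_pairs:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = max(counts, key=lambda s: (counts[s], s))
        kept.remove(worst)

    tags = [Tag(sequence=s, role=role, tag_id=f"{role[0].upper()}{i + 1:02d}")
            for i, s in enumerate(kept)]
    return TagSet(tags=tags, excluded_motif=excluded_motif)


def _mutants_1(seq: str):
    """All strings one edit away from seq (plus seq itself is NOT included)."""
    for i in range(len(seq)):
        for b in DNA:
            if b != seq[i]:
                yield seq[:i] + b + seq[i + 1:]      # substitution
        yield seq[:i] + seq[i + 1:]                   # deletion
        for b in DNA:
            yield seq[:i] + b + seq[i:]               # insertion
    for b in DNA:
        yield seq + b                                 # append


def build_mutant_index(tagset: TagSet, max_errors: int = 2) -> MutantIndex:
    """Enumerate every string within `max_errors` edits of every tag.

    A mutant reachable from two different tags is ambiguous and excluded
    from the map (recorded in the collision list); each original tag always
    maps to itself.
    """
    origin: dict[str, set[str]] = {}
    by_seq = {t.sequence: t for t in tagset.tags}
    for tag in tagset.tags:
        frontier = {tag.sequence}
        seen = {tag.sequence}
        for _ in range(max_errors):
            nxt = set()
            for s in frontier:
                for m in _mutants_1(s):
                    if m not in seen:
                        nxt.add(m)
            seen |= nxt
            frontier = nxt
        for m in seen:
            origin.setdefault(m, set()).add(tag.sequence)

    index: dict[str, Tag] = {}
    collisions: set[str] = set()
    for mutant, sources in origin.items():
        if len(sources) == 1:
            index[mutant] = by_seq[next(iter(sources))]
        else:
            collisions.add(mutant)
    # originals always resolve to themselves, even if reachable from others
    for seq, tag in by_seq.items():
        index[seq] = tag
        collisions.discard(seq)
    return MutantIndex(index=index, max_errors=max_errors, collisions=collisions)


def read_tag_file(path) -> TagSet:
    """Read a tag TSV with columns tag_id, role, sequence (optional column
    `deprecated`)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    tags = []
    for _, row in df.iterrows():
        dep = str(row.get("deprecated", "")).lower() in ("1", "true", "yes")
        tags.append(Tag(sequence=row["sequence"].upper(), role=row["role"],
                        tag_id=row["tag_id"], deprecated=dep))
    return TagSet(tags=tags)


def write_tag_file(tagset: TagSet, path) -> None:
    rows = [{"tag_id": t.tag_id, "role": t.role, "sequence": t.sequence,
             "deprecated": t.deprecated} for t in tagset.tags]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
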