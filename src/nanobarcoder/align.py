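"""Shared pairwise and multiple alignment primitives.

All pairwise alignment here is unit-cost (substitution 1, gap 1 per base,
no gap-opening cost), computed with edlib. This cost model is deliberate:
nanopore errors are indel-rich, and a zero gap-opening cost keeps indel and
substitution evidence staggered across columns instead of collapsing runs
of errors into single gapped blocks.
"""

from __future__ import annotations

import re
from typing import Sequence

import edlib

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_equalities(pattern: str) -> list[tuple[str, str]]:
    """edlib additionalEqualities pairs so degenerate pattern symbols match
    their expansions (W matches A and T, etc.)."""
    pairs = []
    for sym in set(pattern.upper()):
        for base in IUPAC.get(sym, ""):
            if base != sym:
                pairs.append((sym, base))
    return pairs


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def expand_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def global_alignment(query: str, target: str) -> tuple[str, str, int]:
    """Unit-cost global alignment of two sequences.

    Returns (aligned_query, aligned_target, edit_distance) with '-' gaps.
    edlib CIGAR convention: I consumes query, D consumes target.
    """
    if not query and not target:
        return "", "", 0
    if not query:
        return "-" * len(target), target, len(target)
    if not target:
        return query, "-" * len(query), len(query)
    res = edlib.align(query, target, mode="NW", task="path")
    qa, ta = [], []
    qi = ti = 0
    for n, op in expand_cigar(res["cigar"]):
        if op in ("=", "X", "M"):
            qa.append(query[qi:qi + n])
            ta.append(target[ti:ti + n])
            qi += n
            ti += n
        elif op == "I":
            qa.append(query[qi:qi + n])
            ta.append("-" * n)
            qi += n
        elif op == "D":
            qa.append("-" * n)
            ta.append(target[ti:ti + n])
            ti += n
    return "".join(qa), "".join(ta), res["editDistance"]


def infix_search(pattern: str, text: str, max_errors: int = -1,
                 degenerate: bool = True) -> tuple[int, int, int] | None:
    """Best occurrence of `pattern` fully aligned inside `text`
    (semi-global / infix mode). Returns (start, end, errors) with 0-based
    half-open coordinates, or None if the best hit exceeds max_errors."""
    if not pattern or not text:
        return None
    extra = iupac_equalities(pattern) if degenerate else None
    res = edlib.align(pattern.upper(), text.upper(), mode="HW",
                      task="locations", k=max_errors,
                      additionalEqualities=extra)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def alignment_divergence(a: str, b: str) -> float:
    """Edit distance normalised by global alignment length."""
    if not a and not b:
        return 0.0
    dist = levenshtein(a, b)
    # alignment length = max possible matched columns + net gaps;
    # use the exact aligned length from the path only when needed
    aln_len = max(len(a), len(b))
    return dist / aln_len


def center_star_msa(reads: Sequence[str], center_index: int | None = None
                    ) -> list[str]:
    """Multiple alignment by the center-star heuristic.

    Each read is globally aligned to the center (longest read by default);
    insertions relative to the center are merged into shared columns. All
    pairwise steps use the unit-cost model, so identical reads align
    without gaps and isolated indels stay in their own columns.
    """
    reads = [r.upper() for r in reads]
    if not reads:
        raise ValueError("cannot align an empty set of reads")
    if len(reads) == 1:
        return [reads[0]]
    if center_index is None:
        center_index = max(range(len(reads)), key=lambda i: len(reads[i]))
    center = reads[center_index]

    # per read: list over center positions 0..len(center) of inserted bases
    # *before* that center position; plus the base aligned at each position.
    n = len(center)
    ins_before: list[list[str]] = []
    at_pos: list[list[str]] = []
    for read in reads:
        qa, ta, _ = global_alignment(read, center)
        pre = [""] * (n + 1)
        body = [""] * n
        ci = 0
        for qc, tc in zip(qa, ta):
            if tc == "-":
                pre[ci] += qc
            else:
                body[ci] = qc  # may be '-'
                ci += 1
        ins_before.append(pre)
        at_pos.append(body)

    max_ins = [max(len(pre[i]) for pre in ins_before) for i in range(n + 1)]
    rows = []
    for pre, body in zip(ins_before, at_pos):
        parts = []
        for i in range(n):
            parts.append(pre[i].ljust(max_ins[i], "-"))
            parts.append(body[i])
        parts.append(pre[n].ljust(max_ins[n], "-"))
        rows.append("".join(parts))
    return rows
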