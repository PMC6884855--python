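"""Independent oracles used by the tests (deliberately naive)."""

from __future__ import annotations

import re
from collections import Counter


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


def rle_compress(seq: str, max_run: int) -> str:
    """Regex run-length-based homopolymer truncation."""
    return re.sub(r"(.)\1{%d,}" % max_run, lambda m: m.group(1) * max_run, seq)


def column_vote(msa: list[str]) -> str:
    """Independent per-column >= 50% majority vote over an MSA."""
    out = []
    for col in zip(*msa):
        counts = Counter(col)
        depth = len(col)
        if counts.get("-", 0) * 2 >= depth:
            continue
        bases = [(c, n) for c, n in counts.items() if c != "-"]
        bases.sort(key=lambda x: (-x[1], x[0]))
        top, top_n = bases[0]
        tie = len(bases) > 1 and bases[1][1] == top_n
        out.append(top if (top_n * 2 >= depth and not tie and top in "ACGT")
                   else "N")
    return "".join(out)


def connected_components(ids: list[str], dist, threshold: float
                         ) -> set[frozenset]:
    """Clusters as connected components of the graph {d < threshold},
    via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if dist(a, b) < threshold:
                g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


def sliding_edit_distance(pattern: str, text: str) -> tuple[int, int]:
    """Best (errors, end) of pattern inside text by brute-force DP over all
    end positions (semi-global: pattern global, text local)."""
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)  # free start in text
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (pattern[i - 1] != text[j - 1]))
        prev = cur
    best_j = min(range(n + 1), key=lambda j: prev[j])
    return prev[best_j], best_j
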