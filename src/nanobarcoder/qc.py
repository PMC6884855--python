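"""Quality control of nanopore barcodes against short-read references.

Covers per-base accuracy assessment against reference (e.g. Illumina)
barcodes with a >3% divergence exclusion rule, trimming full-length
barcodes to the 313-nt fragment covered by the degenerate internal
primers, estimating the demultiplexing error rate from reads falling into
unused tag combinations, screening barcodes against a labelled reference
library for contamination, calling reference barcodes from short-read
sets by the dominant-sequence rule, and flagging putative
paralogs/contamination from secondary signal shared across clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .align import global_alignment, infix_search, revcomp
from .consensus import Barcode

M1COLINTF = "GGWACWGGWTGAACWGTWTAYCCYCC"
JGHCO2198 = "TANACYTCNGGRTGNCCRAARAAYCA"
ILLUMINA_FRAGMENT_LENGTH = 313

DEFAULT_MAX_DIVERGENCE = 0.03
DEFAULT_CONTAMINATION_IDENTITY = 0.95
DEFAULT_TOP_HITS = 100


@dataclass
class AccuracyRecord:
    specimen_id: str
    overlap: int           # aligned columns with a base on both sides
    identity: float        # matches / compared sites (indels count, N not)
    ambiguity_fraction: float
    divergence: float      # 1 - identity, N ignored
    excluded: bool         # divergence > 3%


@dataclass
class ShortReadSet:
    specimen_id: str
    counts: Counter  # unique merged sequence -> read count

    def total(self) -> int:
        return sum(self.counts.values())


def per_base_accuracy(query: Barcode | str, reference: str,
                      specimen_id: str = "",
                      max_divergence: float = DEFAULT_MAX_DIVERGENCE
                      ) -> AccuracyRecord:
    """Align a barcode to its reference and compute per-base identity.

    Internal indels count as errors (they are real consensus errors on
    protein-coding sequence); terminal overhangs do not. N in the query is
    counted as ambiguity, not as error: columns where either side carries
    an N are left out of the comparison. Records with divergence above
    `max_divergence` (default 3%) are excluded from accuracy averaging —
    on real data such outliers reflect wet-lab artefacts rather than
    consensus error.
    """
    if isinstance(query, Barcode):
        specimen_id = specimen_id or query.specimen_id
        qseq = query.sequence
    else:
        qseq = query
    qa, ra, _ = global_alignment(qseq.upper(), reference.upper())
    # trim terminal gap overhangs on either side
    start, end = 0, len(qa)
    while start < end and (qa[start] == "-" or ra[start] == "-"):
        start += 1
    while end > start and (qa[end - 1] == "-" or ra[end - 1] == "-"):
        end -= 1
    compared = matches = n_amb = overlap = 0
    for x, y in zip(qa[start:end], ra[start:end]):
        if x == "N" or y == "N":
            n_amb += x == "N"
            overlap += x != "-" and y != "-"
            continue
        if x != "-" and y != "-":
            overlap += 1
        compared += 1
        matches += x == y
    if compared == 0:
        raise ValueError("no comparable overlap between query and reference")
    identity = matches / compared
    divergence = 1 - identity
    return AccuracyRecord(specimen_id, overlap, identity,
                          n_amb / max(1, overlap), divergence,
                          excluded=divergence > max_divergence)


def trim_to_reference(barcode: Barcode | str,
                      fwd_primer: str = M1COLINTF,
                      rev_primer: str = JGHCO2198,
                      fragment_length: int = ILLUMINA_FRAGMENT_LENGTH,
                      max_errors: int = 5) -> str | None:
    """Trim a full-length barcode to the fragment the internal primers
    amplify (default: the 313-nt fragment between m1COlintF and
    jgHCO2198). The region starts at the end of the forward internal
    primer site and ends at the reverse primer site, or after
    `fragment_length` nt when the reverse site lies outside the barcode.
    Returns None (flagged) if the forward site is absent.
    """
    seq = (barcode.sequence if isinstance(barcode, Barcode) else barcode).upper()
    fwd = infix_search(fwd_primer, seq, max_errors)
    if fwd is None:
        return None
    start = fwd[1]
    rev = infix_search(revcomp(rev_primer), seq[start:], max_errors)
    end = start + rev[0] if rev is not None else min(len(seq),
                                                    start + fragment_length)
    if end <= start:
        return None
    return seq[start:end]


def demux_error_from_unused(summary: pd.DataFrame, layout: pd.DataFrame,
                            n_total_combinations: int | None = None) -> dict:
    """Demultiplexing error estimated from reads assigned to tag
    combinations absent from the layout.

    `summary` is the per-read table from demultiplex(); rate = unused /
    (assigned + unused). When the layout uses every combination the rate
    is not estimable and reported as None.
    """
    n_unused = int((summary.status == "unused_combination").sum())
    n_assigned = int((summary.status == "assigned").sum())
    per_tag = Counter()
    for combo in summary.loc[summary.status == "unused_combination",
                             "specimen_id"]:
        for tag_id in str(combo).split("+"):
            per_tag[tag_id] += 1
    if n_total_combinations is None:
        n_total_combinations = layout.attrs.get("n_total_combinations")
    estimable = (n_total_combinations is None
                 or n_total_combinations > len(layout))
    denom = n_assigned + n_unused
    return {
        "rate": (n_unused / denom) if (denom and estimable) else
                (0.0 if estimable else None),
        "n_unused": n_unused,
        "n_demultiplexed": denom,
        "per_tag": dict(per_tag),
        "estimable": estimable,
    }


def _identity(a: str, b: str) -> float:
    qa, ta, dist = global_alignment(a.upper(), b.upper())
    return 1 - dist / len(qa) if qa else 0.0


def contamination_screen(barcode: Barcode | str, library: dict[str, str],
                         taxa: dict[str, str], target_taxon: str,
                         identity_cutoff: float = DEFAULT_CONTAMINATION_IDENTITY,
                         top_k: int = DEFAULT_TOP_HITS) -> str:
    """Screen a barcode against a labelled reference library.

    Returns "remove" if the best match is a non-target taxon at identity
    >= cutoff (default 95%), "inspect" if no hit reaches the cutoff and no
    target-taxon sequence appears among the top `top_k` matches, else
    "keep".
    """
    if not library:
        raise ValueError("empty reference library")
    seq = (barcode.sequence if isinstance(barcode, Barcode) else barcode)
    scored = sorted(((name, _identity(seq, ref)) for name, ref in library.items()),
                    key=lambda x: -x[1])
    best_name, best_ident = scored[0]
    if best_ident >= identity_cutoff:
        return "remove" if taxa.get(best_name) != target_taxon else "keep"
    top = scored[:top_k]
    if not any(taxa.get(name) == target_taxon for name, _ in top):
        return "inspect"
    return "keep"


def reference_caller(srs: ShortReadSet, set_cov_min: int = 50,
                     seq_cov_min: int = 10, dominance: float = 5.0
                     ) -> str | None:
    """Call a reference barcode from a demultiplexed short-read set.

    The most common unique sequence is accepted iff the set has more than
    `set_cov_min` total reads, the sequence itself more than `seq_cov_min`
    reads, and it is at least `dominance` times as common as the runner-up.
    """
    if not srs.counts:
        return None
    if srs.total() <= set_cov_min:
        return None
    ranked = srs.counts.most_common()
    top_seq, top_n = ranked[0]
    if top_n <= seq_cov_min:
        return None
    if len(ranked) > 1 and top_n < dominance * ranked[1][1]:
        return None
    return top_seq


def secondary_signal_check(short_read_sets: dict[str, ShortReadSet],
                           barcodes: dict[str, str],
                           clusters: dict[str, str],
                           min_count: int = 10,
                           min_identity: float = 0.99,
                           min_length: int = 300) -> pd.DataFrame:
    """Flag putative paralogs/contamination from secondary signal.

    For every unique non-dominant sequence with >= `min_count` reads in a
    specimen's short-read set, report matches to the barcode of a
    different cluster at >= `min_identity` identity over >= `min_length`
    aligned nt. Cluster pairs supported by secondary signal from >= 2
    source specimens are flagged (paralogy more likely than sporadic
    contamination). Columns: source_cluster, target_cluster, n_specimens,
    flagged.
    """
    hits = []
    for spec_id, srs in short_read_sets.items():
        if spec_id not in clusters:
            continue
        own = barcodes.get(spec_id, "")
        ranked = srs.counts.most_common()
        secondary = [s for s, n in ranked[1:] if n >= min_count]
        for sec in secondary:
            for other_id, bc in barcodes.items():
                if other_id == spec_id:
                    continue
                if clusters.get(other_id) == clusters[spec_id]:
                    continue
                qa, ta, dist = global_alignment(sec.upper(), bc.upper())
                aligned = sum(1 for x, y in zip(qa, ta)
                              if x != "-" and y != "-")
                if aligned < min_length:
                    continue
                ident = sum(1 for x, y in zip(qa, ta)
                            if x == y and x != "-") / aligned
                if ident >= min_identity and (not own or sec != own.upper()):
                    hits.append({"source_specimen": spec_id,
                                 "source_cluster": clusters[spec_id],
                                 "target_cluster": clusters[other_id],
                                 "identity": ident, "aligned": aligned})
    if not hits:
        return pd.DataFrame(columns=["source_cluster", "target_cluster",
                                     "n_specimens", "flagged"])
    df = pd.DataFrame(hits)
    agg = (df.groupby(["source_cluster", "target_cluster"])["source_specimen"]
           .nunique().reset_index(name="n_specimens"))
    agg["flagged"] = agg.n_specimens >= 2
    return agg
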