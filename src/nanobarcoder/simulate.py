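"""Synthetic tagged-amplicon nanopore read sets with known ground truth.

The generator emulates the data a pooled 1D amplicon run produces: each
specimen's 658-nt COI barcode is flanked by the tagged Folmer primers
(total product 735 nt with 13-nt tags), reads come off either strand, and
errors are dominated by indels with extra indel pressure inside
homopolymer runs. Library anomalies that a real run shows are modelled
explicitly: ligated double-amplicon reads, reads carrying tag pairs absent
from the plate layout, and low-level cross-contamination between wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import revcomp

LCO1490 = "GGTCAACAAATCATAAAGATATTGG"
HCO2198 = "TAAACTTCAGGGTGACCAAAAAATCA"

#: invertebrate mitochondrial stop codons (translation table 5)
STOP_CODONS = ("TAA", "TAG")

DNA = "ACGT"
BARCODE_LENGTH = 658


@dataclass
class ErrorModel:
    """Per-base nanopore error rates applied independently per position."""

    sub_rate: float = 0.048
    ins_rate: float = 0.036
    del_rate: float = 0.036
    homopolymer_indel_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass
class SpecimenTruth:
    specimen_id: str
    plate: str
    well: str
    fwd_tag: str
    rev_tag: str
    template: str
    coverage: int
    species: str = ""

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass
class ClusterSpec:
    """Divergence structure of the simulated community."""

    n_species: int = 10
    specimens_per_species: int = 5
    intra_max: float = 0.01   # max pairwise p-distance within a species
    inter_min: float = 0.08   # min pairwise p-distance between species

    def __post_init__(self):
        if self.intra_max >= self.inter_min:
            raise ValueError("intra_max must be < inter_min")


@dataclass
class AnomalySpec:
    fraction_ligated_dimers: float = 0.0
    fraction_unused_tag_reads: float = 0.0
    fraction_cross_contaminating_reads: float = 0.0
    negatives: list = field(default_factory=list)

    def __post_init__(self):
        for f in (self.fraction_ligated_dimers, self.fraction_unused_tag_reads,
                  self.fraction_cross_contaminating_reads):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")


def random_coding_template(rng: np.random.Generator,
                           length: int = BARCODE_LENGTH) -> str:
    """Random DNA of `length` nt translatable in frame 0 without stops."""
    n_codons = length // 3
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(DNA), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    tail = "".join(rng.choice(list(DNA), size=length - 3 * n_codons))
    return "".join(codons) + tail


def _mutate_sites(seq: str, sites: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute each listed site with a different base, never creating an
    in-frame (frame 0) stop codon."""
    out = list(seq)
    for pos in sites:
        pos = int(pos)
        choices = [b for b in DNA if b != out[pos]]
        rng.shuffle(choices)
        placed = False
        for b in choices:
            out[pos] = b
            cs = pos - pos % 3
            codon = "".join(out[cs:cs + 3])
            if len(codon) < 3 or codon not in STOP_CODONS:
                placed = True
                break
        if not placed:
            out[pos] = seq[pos]  # no stop-free substitution at this site
    return "".join(out)


def has_stop(seq: str, frame: int = 0) -> bool:
    s = seq[frame:]
    return any(s[i:i + 3] in STOP_CODONS for i in range(0, len(s) - 2, 3))


def make_templates(spec: ClusterSpec, seed: int = 0,
                   root: str | None = None,
                   length: int = BARCODE_LENGTH) -> tuple[list[str], list[str]]:
    """Generate one template per specimen under the divergence structure.

    Species ancestors mutate the root at disjoint site blocks, so every
    between-species pair is at least `inter_min` apart; specimens mutate
    their ancestor by at most `intra_max`/2, so within-species pairs stay
    below `intra_max`. Returns (templates, species labels), both ordered
    specimen-major.
    """
    rng = np.random.default_rng(seed)
    if root is None:
        root = random_coding_template(rng, length)
    else:
        root = root.upper()
        length = len(root)
        if has_stop(root):
            raise ValueError("root template contains in-frame stop codons")

    half_inter = spec.inter_min / 2
    n_sites_per_species = int(np.ceil((half_inter + spec.intra_max) * length))
    need = n_sites_per_species * spec.n_species
    if need > length:
        raise ValueError("divergence structure infeasible for template length")
    all_sites = rng.permutation(length)
    templates: list[str] = []
    species_labels: list[str] = []
    for si in range(spec.n_species):
        block = all_sites[si * n_sites_per_species:(si + 1) * n_sites_per_species]
        ancestor = _mutate_sites(root, block, rng)
        n_intra_max = int(spec.intra_max / 2 * length)
        for mi in range(spec.specimens_per_species):
            k = int(rng.integers(0, n_intra_max + 1))
            sites = rng.choice(length, size=k, replace=False)
            templates.append(_mutate_sites(ancestor, sites, rng))
            species_labels.append(f"SP{si + 1:03d}")
    return templates, species_labels


def default_layout(n_specimens: int, fwd_tags: list[str], rev_tags: list[str],
                   plate: str = "P1", negatives: list[str] | None = None
                   ) -> pd.DataFrame:
    """Row-major 96-well layout assigning tag pairs to specimens.

    Tag pairing is combinatorial: forward tag = column block, reverse tag =
    row block, mirroring dual-index plate tagging. Wells listed in
    `negatives` get a specimen_id but no template downstream.
    """
    rows = "ABCDEFGH"
    records = []
    idx = 0
    negatives = set(negatives or [])
    for well_i in range(96):
        if idx >= n_specimens:
            break
        r, c = divmod(well_i, 12)
        well = f"{rows[r]}{c + 1}"
        fwd = fwd_tags[well_i % len(fwd_tags)]
        rev = rev_tags[(well_i // len(fwd_tags)) % len(rev_tags)]
        records.append({
            "plate": plate, "well": well,
            "specimen_id": f"{plate}_{well}",
            "fwd_tag": fwd, "rev_tag": rev,
            "is_negative": well in negatives,
        })
        idx += 1
    df = pd.DataFrame(records)
    pairs = list(zip(df.fwd_tag, df.rev_tag))
    if len(set(pairs)) != len(pairs):
        raise ValueError("layout assigns a tag pair twice")
    return df


def build_truth(layout: pd.DataFrame, templates: list[str],
                species: list[str], coverages: list[int]) -> list[SpecimenTruth]:
    specimens = layout[~layout.is_negative].reset_index(drop=True)
    if len(specimens) != len(templates):
        raise ValueError("one template per non-negative well required")
    out = []
    for i, row in specimens.iterrows():
        out.append(SpecimenTruth(
            specimen_id=row.specimen_id, plate=row.plate, well=row.well,
            fwd_tag=row.fwd_tag, rev_tag=row.rev_tag,
            template=templates[i], coverage=int(coverages[i]),
            species=species[i]))
    return out


def lognormal_coverages(n: int, rng: np.random.Generator,
                        median: float = 45.0, sigma: float = 0.6,
                        min_coverage: int = 0) -> list[int]:
    cov = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    return [max(min_coverage, int(round(c))) for c in cov]


def amplicon(truth: SpecimenTruth) -> str:
    """Forward-strand tagged product: tagF + LCO + barcode + rc(HCO) + rc(tagR)."""
    return (truth.fwd_tag + LCO1490 + truth.template
            + revcomp(HCO2198) + revcomp(truth.rev_tag))


def inject_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion errors.

    Indel rates are multiplied inside homopolymer runs of length >= 3,
    emulating nanopore's run-length errors.
    """
    n = len(seq)
    if n == 0:
        return seq
    # mark positions inside runs >= 3
    in_run = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 3:
            in_run[i:j] = True
        i = j
    mult = np.where(in_run, model.homopolymer_indel_multiplier, 1.0)
    del_p = np.minimum(model.del_rate * mult, 0.95)
    ins_p = np.minimum(model.ins_rate * mult, 0.95)
    u_del = rng.random(n)
    u_ins = rng.random(n)
    u_sub = rng.random(n)
    out = []
    bases = list(DNA)
    for i, c in enumerate(seq):
        if u_ins[i] < ins_p[i]:
            out.append(bases[int(rng.integers(4))])
        if u_del[i] < del_p[i]:
            continue
        if u_sub[i] < model.sub_rate:
            c = bases[(bases.index(c) + 1 + int(rng.integers(3))) % 4] \
                if c in bases else bases[int(rng.integers(4))]
        out.append(c)
    return "".join(out)


def simulate_reads(truth: list[SpecimenTruth], layout: pd.DataFrame,
                   model: ErrorModel, anomalies: AnomalySpec | None = None,
                   all_fwd_tags: list[str] | None = None,
                   all_rev_tags: list[str] | None = None,
                   ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one read set.

    Returns (reads, manifest): reads as (read_id, sequence), manifest as a
    DataFrame with the true origin and category of every read. Read count =
    sum of true coverages plus anomaly reads. Deterministic per model seed.
    """
    anomalies = anomalies or AnomalySpec()
    rng = np.random.default_rng(model.seed)
    reads: list[tuple[str, str]] = []
    records = []
    by_id = {t.specimen_id: t for t in truth}

    def emit(seq: str, specimen_id: str, category: str,
             specimen_id2: str = ""):
        rid = f"read{len(reads) + 1:06d}"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        else:
            strand = "+"
        reads.append((rid, inject_errors(seq, model, rng)))
        records.append({"read_id": rid, "specimen_id": specimen_id,
                        "specimen_id2": specimen_id2,
                        "category": category, "strand": strand})

    for t in truth:
        for _ in range(t.coverage):
            emit(amplicon(t), t.specimen_id, "normal")

    n_normal = len(reads)
    ids = [t.specimen_id for t in truth if t.coverage > 0]

    n_dimer = int(round(anomalies.fraction_ligated_dimers * n_normal))
    for _ in range(n_dimer):
        a, b = rng.choice(ids, size=2)
        emit(amplicon(by_id[a]) + amplicon(by_id[b]), a, "dimer",
             specimen_id2=b)

    n_cross = int(round(anomalies.fraction_cross_contaminating_reads * n_normal))
    for _ in range(n_cross):
        src, host = rng.choice(ids, size=2, replace=False)
        h, s = by_id[host], by_id[src]
        seq = (h.fwd_tag + LCO1490 + s.template
               + revcomp(HCO2198) + revcomp(h.rev_tag))
        emit(seq, host, "cross_contamination")

    n_unused = int(round(anomalies.fraction_unused_tag_reads * n_normal))
    if n_unused and all_fwd_tags and all_rev_tags:
        used = set(zip(layout.fwd_tag, layout.rev_tag))
        unused = [(f, r) for f in all_fwd_tags for r in all_rev_tags
                  if (f, r) not in used]
        for _ in range(n_unused):
            f, r = unused[int(rng.integers(len(unused)))]
            t = by_id[ids[int(rng.integers(len(ids)))]]
            seq = f + LCO1490 + t.template + revcomp(HCO2198) + revcomp(r)
            emit(seq, "unused_combination", "unused_combo")

    manifest = pd.DataFrame(records)
    return reads, manifest
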