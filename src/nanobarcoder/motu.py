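"""mOTU delimitation, partition congruence, and species richness.

Barcodes are clustered into molecular operational taxonomic units
(mOTUs) by objective clustering — single-linkage agglomeration of
uncorrected p-distances, equivalent to connected components of the graph
whose edges join specimens at distance < threshold. Congruence between
two partitions is the match ratio 2*N_match/(N1+N2), where N_match counts
clusters with identical member sets. Species richness is estimated with
the classical Chao1 formula S_obs + F1^2/(2*F2) (bias-corrected fallback
when no doubletons exist), with rarefied accumulation curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import center_star_msa


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, fractions in [0, 1]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v


@dataclass
class ClusterPartition:
    threshold: float
    clusters: list[frozenset]

    def __post_init__(self):
        all_ids = [i for c in self.clusters for i in c]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("clusters overlap")

    @property
    def universe(self) -> frozenset:
        return frozenset(i for c in self.clusters for i in c)

    def assignment(self) -> dict[str, int]:
        return {i: k for k, c in enumerate(self.clusters) for i in c}

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class MatchStats:
    n_match: int
    n1: int
    n2: int

    @property
    def ratio(self) -> float:
        return 2 * self.n_match / (self.n1 + self.n2)


@dataclass
class RichnessInput:
    s_obs: int
    f1: int
    f2: int
    abundances: list[int] = field(default_factory=list)

    @classmethod
    def from_partition(cls, partition: ClusterPartition) -> "RichnessInput":
        ab = sorted((len(c) for c in partition.clusters), reverse=True)
        return cls(s_obs=len(ab), f1=sum(a == 1 for a in ab),
                   f2=sum(a == 2 for a in ab), abundances=ab)


def pairwise_pdistance(a: str, b: str) -> float:
    """Uncorrected p-distance between two aligned equal-length sequences,
    with pairwise deletion: sites with N or a gap on either side are
    excluded from the comparison."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    compared = diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        diffs += x != y
    if compared == 0:
        raise ValueError("no comparable sites")
    return diffs / compared


def distance_matrix(sequences: dict[str, str], aligned: bool = False
                    ) -> DistanceMatrix:
    """All-pairs p-distance matrix; unaligned input is multiply aligned
    first (zero gap-opening cost)."""
    ids = list(sequences)
    seqs = [sequences[i] for i in ids]
    if not aligned or len({len(s) for s in seqs}) > 1:
        seqs = center_star_msa(seqs) if len(seqs) > 1 else seqs
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_pdistance(seqs[i], seqs[j])
    return DistanceMatrix(ids, m)


def objective_cluster(dm: DistanceMatrix, threshold: float) -> ClusterPartition:
    """Single-linkage clustering at a strict threshold: two specimens share
    a cluster iff connected by a chain of pairwise distances < threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n = len(dm.ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dm.values[i, j] < threshold:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(dm.ids[i])
    clusters = sorted((frozenset(g) for g in groups.values()),
                      key=lambda c: sorted(c)[0])
    return ClusterPartition(threshold, clusters)


def match_ratio(p1: ClusterPartition, p2: ClusterPartition) -> MatchStats:
    """Congruence of two partitions over the same specimens:
    2*N_match/(N1+N2), N_match counting identical clusters."""
    if p1.universe != p2.universe:
        raise ValueError("partitions cover different specimen sets")
    s1, s2 = set(p1.clusters), set(p2.clusters)
    return MatchStats(n_match=len(s1 & s2), n1=len(s1), n2=len(s2))


def congruence_threshold_scan(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
                              base_threshold: float = 0.03,
                              grid: np.ndarray | None = None) -> pd.DataFrame:
    """For each cluster incongruent between the two datasets at the base
    threshold, the smallest grid threshold (default 1-10% in 0.1% steps)
    at which both clusterings agree on its members; 'never' if none."""
    if grid is None:
        grid = np.round(np.arange(0.010, 0.1001, 0.001), 4)
    pa = objective_cluster(dm_a, base_threshold)
    pb = objective_cluster(dm_b, base_threshold)
    shared = set(pa.clusters) & set(pb.clusters)
    incongruent = [c for c in pa.clusters if c not in shared]
    rows = []
    for cluster in incongruent:
        found = None
        for t in grid:
            ca = objective_cluster(dm_a, float(t))
            cb = objective_cluster(dm_b, float(t))
            if cluster in (set(ca.clusters) & set(cb.clusters)):
                found = float(t)
                break
        rows.append({"cluster": ",".join(sorted(cluster)),
                     "congruent_at": found if found is not None else "never"})
    return pd.DataFrame(rows, columns=["cluster", "congruent_at"])


def export_for_ptp(sequences: dict[str, str], outdir) -> None:
    """Hook for tree-based delimitation with external tools.

    Writes the multiple alignment (FASTA) plus a recipe file with the
    commands a user would run (tree inference, then PTP); tree-based
    delimitation itself is not re-implemented here.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = list(sequences)
    seqs = [sequences[i] for i in ids]
    if len(seqs) > 1 and len({len(s) for s in seqs}) > 1:
        seqs = center_star_msa(seqs)
    with open(outdir / "alignment.fasta", "w") as fh:
        for name, seq in zip(ids, seqs):
            fh.write(f">{name}\n{seq}\n")
    (outdir / "RECIPE.txt").write_text(
        "# Tree-based mOTU delimitation (external tools)\n"
        "fasttree -nt -gtr alignment.fasta > barcodes.nwk\n"
        "# then run PTP/mPTP on barcodes.nwk, e.g.:\n"
        "# mptp --ml --multi --tree_file barcodes.nwk --output_file ptp_out\n")


def chao1(r: RichnessInput) -> dict:
    """Classical Chao1 richness estimate.

    S_obs + F1^2/(2*F2) when doubletons exist; bias-corrected fallback
    S_obs + F1*(F1-1)/2 when F2 = 0. Also reports the coefficient of
    variation of the abundance distribution.
    """
    if r.f2 > 0:
        est = r.s_obs + r.f1 ** 2 / (2 * r.f2)
        variant = "classical"
    else:
        est = r.s_obs + r.f1 * (r.f1 - 1) / 2
        variant = "bias_corrected"
    cv = None
    if r.abundances:
        ab = np.asarray(r.abundances, dtype=float)
        cv = float(ab.std(ddof=1) / ab.mean()) if len(ab) > 1 and ab.mean() > 0 else 0.0
    return {"estimate": float(est), "variant": variant, "s_obs": r.s_obs,
            "f1": r.f1, "f2": r.f2, "cv": cv}


def accumulation_curve(assignment: dict[str, str], reps: int = 100,
                       seed: int = 0, sizes: list[int] | None = None
                       ) -> pd.DataFrame:
    """Rarefied accumulation of mOTU richness.

    Specimens are subsampled without replacement at each size over `reps`
    randomizations; mean observed richness, singleton/doubleton counts and
    the Chao1 mean are reported per size. Reproducible per seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    specimens = list(assignment)
    labels = np.array([assignment[s] for s in specimens])
    n = len(specimens)
    if sizes is None:
        step = max(1, n // 20)
        sizes = list(range(step, n + 1, step))
        if sizes[-1] != n:
            sizes.append(n)
    rows = []
    for size in sizes:
        s_vals, f1_vals, f2_vals, chao_vals = [], [], [], []
        for _ in range(reps):
            idx = rng.choice(n, size=size, replace=False)
            counts = pd.Series(labels[idx]).value_counts()
            s = len(counts)
            f1 = int((counts == 1).sum())
            f2 = int((counts == 2).sum())
            est = chao1(RichnessInput(s, f1, f2))["estimate"]
            s_vals.append(s)
            f1_vals.append(f1)
            f2_vals.append(f2)
            chao_vals.append(est)
        rows.append({"size": size, "s_mean": float(np.mean(s_vals)),
                     "singleton_mean": float(np.mean(f1_vals)),
                     "doubleton_mean": float(np.mean(f2_vals)),
                     "chao1_mean": float(np.mean(chao_vals))})
    return pd.DataFrame(rows)
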