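"""Desk-scale validation study on simulated reads with known truth.

Runs the full pipeline under one fixed set of study conditions — 50
specimens (10 species x 5), 12% total read error with a 60% indel share,
demultiplexed coverage of at least ~20x, a 10x8 dual-tag layout with 50
of 80 combinations in use, plus ligated-dimer / unused-tag /
cross-contamination anomalies — and measures demultiplexing accuracy,
per-stage barcode accuracy against the true templates, and the
congruence of the recovered mOTUs with the simulated species partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motu import (ClusterPartition, RichnessInput, chao1, distance_matrix,
                   match_ratio, objective_cluster)
from .demux import Read
from .pipeline import design_tagset, run_read_pipeline
from .qc import demux_error_from_unused, per_base_accuracy
from .simulate import (AnomalySpec, ClusterSpec, ErrorModel, HCO2198,
                       LCO1490, build_truth, default_layout,
                       lognormal_coverages, make_templates, simulate_reads)


@dataclass
class StudyConditions:
    n_species: int = 10
    specimens_per_species: int = 5
    intra_max: float = 0.01
    inter_min: float = 0.08
    total_error: float = 0.12
    indel_share: float = 0.6
    # true per-specimen read counts; only ~35-40% of 1D reads demultiplex
    # (both tags must resolve), so the median is sized to leave every bin
    # with >= ~20x demultiplexed coverage
    coverage_median: float = 150.0
    coverage_sigma: float = 0.35
    coverage_min: int = 60
    n_fwd_tags: int = 10
    n_rev_tags: int = 8
    fraction_dimers: float = 0.02
    fraction_unused: float = 0.01
    fraction_cross: float = 0.005

    @property
    def n_specimens(self) -> int:
        return self.n_species * self.specimens_per_species


@dataclass
class StudyResult:
    metrics: dict = field(default_factory=dict)
    stages: object = None
    truth: list = None


def run_study(seed: int = 1, conditions: StudyConditions | None = None
              ) -> StudyResult:
    cond = conditions or StudyConditions()
    rng = np.random.default_rng(seed)

    fwd = design_tagset(cond.n_fwd_tags, "forward", int(rng.integers(2 ** 31)))
    rev = design_tagset(cond.n_rev_tags, "reverse", int(rng.integers(2 ** 31)),
                        excluded_motif="")
    spec = ClusterSpec(cond.n_species, cond.specimens_per_species,
                       cond.intra_max, cond.inter_min)
    templates, species = make_templates(spec, int(rng.integers(2 ** 31)))
    layout = default_layout(cond.n_specimens, fwd.sequences, rev.sequences)
    coverages = lognormal_coverages(cond.n_specimens, rng,
                                    cond.coverage_median, cond.coverage_sigma,
                                    cond.coverage_min)
    truth = build_truth(layout, templates, species, coverages)
    model = ErrorModel(
        sub_rate=cond.total_error * (1 - cond.indel_share),
        ins_rate=cond.total_error * cond.indel_share / 2,
        del_rate=cond.total_error * cond.indel_share / 2,
        seed=int(rng.integers(2 ** 31)))
    anomalies = AnomalySpec(cond.fraction_dimers, cond.fraction_unused,
                            cond.fraction_cross)
    raw, manifest = simulate_reads(truth, layout, model, anomalies,
                                   fwd.sequences, rev.sequences)
    reads = [Read(r, s) for r, s in raw]
    library = {t.specimen_id: t.template for t in truth}

    stages, bins, summary = run_read_pipeline(
        reads, LCO1490, HCO2198, fwd, rev, layout, library,
        seed=int(rng.integers(2 ** 31)), leave_one_out=True)

    m: dict = {}

    # --- demultiplexing accuracy against the truth manifest -------------
    man = manifest.set_index("read_id")
    assigned = summary[summary.status == "assigned"]
    n_correct = 0
    for r in assigned.itertuples():
        base = r.read_id.split("/")[0]
        row = man.loc[base]
        ok = r.specimen_id == row.specimen_id or \
            r.specimen_id == row.specimen_id2
        n_correct += ok
    m["n_reads"] = len(reads)
    m["n_demultiplexed"] = int(len(assigned))
    m["demux_correct_pct"] = 100 * n_correct / max(1, len(assigned))

    unused = summary[summary.status == "unused_combination"]
    n_misassigned_unused = sum(
        man.loc[r.read_id.split("/")[0], "category"] != "unused_combo"
        for r in unused.itertuples())
    n_demuxed = len(assigned) + len(unused)
    m["misassigned_unused_pct"] = 100 * n_misassigned_unused / max(1, n_demuxed)
    m["unused_combination_pct"] = 100 * demux_error_from_unused(
        summary, layout, cond.n_fwd_tags * cond.n_rev_tags)["rate"]

    # --- per-stage accuracy against true templates ----------------------
    for stage_name, barcodes in stages.stages().items():
        accs, ns = [], []
        for specimen, bc in barcodes.items():
            rec = per_base_accuracy(bc.sequence, library[specimen])
            if not rec.excluded:
                accs.append(rec.identity)
                ns.append(bc.ambiguity_fraction)
        m[f"{stage_name}_n_barcodes"] = len(barcodes)
        m[f"{stage_name}_accuracy_pct"] = 100 * float(np.mean(accs))
        m[f"{stage_name}_mean_n_pct"] = 100 * float(np.mean(ns))

    # --- mOTU recovery ---------------------------------------------------
    consolidated = {s: b.sequence for s, b in stages.consolidated.items()}
    dm = distance_matrix(consolidated)
    species_of = {t.specimen_id: t.species for t in truth}
    true_clusters: dict[str, set] = {}
    for s in consolidated:
        true_clusters.setdefault(species_of[s], set()).add(s)
    true_part = ClusterPartition(0.03, [frozenset(v)
                                        for v in true_clusters.values()])
    for t in (0.02, 0.03, 0.04):
        part = objective_cluster(dm, t)
        m[f"motus_{int(t * 100)}pct"] = len(part)
    part3 = objective_cluster(dm, 0.03)
    m["match_ratio_3pct"] = match_ratio(part3, true_part).ratio
    rich = chao1(RichnessInput.from_partition(part3))
    m["chao1_3pct"] = rich["estimate"]
    m["true_species"] = cond.n_species

    return StudyResult(metrics=m, stages=stages, truth=truth)
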