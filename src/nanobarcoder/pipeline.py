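"""End-to-end orchestration: reads -> bins -> barcodes -> mOTUs.

Chains the per-module operations the way a full run uses them: design or
load tag sets, demultiplex, call draft and polished consensus barcodes,
run the amino-acid correction on both tracks, consolidate, and cluster
the surviving barcodes. Each stage's products are kept so accuracy can be
compared across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import (Barcode, call_draft, filter_draft, polish,
                        DEFAULT_MIN_COV, DEFAULT_SUBSAMPLE)
from .correct import (CorrectionParams, aa_correct, choose_reference,
                      consolidate, final_translation_check)
from .demux import DemuxBin, DemuxConfig, demultiplex
from .tags import (TagSet, build_mutant_index, filter_tagset,
                   generate_candidates)


def design_tagset(n: int, role: str, seed: int, length: int = 13,
                  candidate_min_dist: int = 6, min_edit: int = 3,
                  excluded_motif: str = "GG") -> TagSet:
    """Generate candidates and screen them down to a validated tag set of
    at least `n` tags (raises if the screens leave fewer)."""
    # oversample: the homopolymer/motif/edit screens discard a fraction
    n_cand = max(2 * n, n + 20)
    cands = generate_candidates(n_cand, length, candidate_min_dist, seed)
    ts = filter_tagset(cands, excluded_motif, min_edit, role=role)
    if len(ts) < n:
        raise RuntimeError(f"only {len(ts)} tags survived screening, need {n}")
    return TagSet(tags=ts.tags[:n], excluded_motif=excluded_motif)


@dataclass
class StageBarcodes:
    """Per-specimen barcodes at every pipeline stage."""

    draft: dict[str, Barcode] = field(default_factory=dict)
    polished: dict[str, Barcode] = field(default_factory=dict)
    draft_corrected: dict[str, Barcode] = field(default_factory=dict)
    polished_corrected: dict[str, Barcode] = field(default_factory=dict)
    consolidated: dict[str, Barcode] = field(default_factory=dict)
    rejections: list[dict] = field(default_factory=list)

    def stages(self):
        return {"draft": self.draft, "polished": self.polished,
                "draft_corrected": self.draft_corrected,
                "polished_corrected": self.polished_corrected,
                "consolidated": self.consolidated}


def call_all_barcodes(bins: dict[str, DemuxBin], seed: int = 0,
                      n_subsample: int = DEFAULT_SUBSAMPLE,
                      min_cov: int = DEFAULT_MIN_COV,
                      max_ambiguity: float = 0.01,
                      max_divergence: float = 0.15) -> StageBarcodes:
    """Draft + polished consensus for every bin passing the coverage and
    ambiguity screens."""
    out = StageBarcodes()
    rng = np.random.default_rng(seed)
    for specimen in sorted(bins):
        bin_seed = int(rng.integers(2 ** 31 - 1))
        draft = call_draft(bins[specimen], n_subsample, min_cov, bin_seed)
        if draft is None:
            out.rejections.append({"specimen_id": specimen,
                                   "stage": "draft", "reason": "low_coverage"})
            continue
        if not filter_draft(draft, max_ambiguity):
            out.rejections.append({"specimen_id": specimen, "stage": "draft",
                                   "reason": "ambiguity"})
            continue
        out.draft[specimen] = draft
        out.polished[specimen] = polish(draft, bins[specimen], max_divergence)
    return out


def correct_all_barcodes(stages: StageBarcodes, library: dict[str, str],
                         params: CorrectionParams | None = None,
                         leave_one_out: bool = True) -> StageBarcodes:
    """Amino-acid correction of both consensus tracks + consolidation.

    `library` maps reference name -> sequence; with leave_one_out a
    reference whose name equals the specimen id is never used for that
    specimen (for validation runs where the truth is in the library).
    """
    params = params or CorrectionParams()
    for stage_name, target in (("draft", stages.draft_corrected),
                               ("polished", stages.polished_corrected)):
        source = getattr(stages, stage_name)
        for specimen, bc in source.items():
            ref = choose_reference(bc.sequence, library,
                                   exclude=specimen if leave_one_out else None)
            if ref is None:
                stages.rejections.append({"specimen_id": specimen,
                                          "stage": f"{stage_name}_corrected",
                                          "reason": "no_reference"})
                continue
            outcome = aa_correct(bc, ref[1], params)
            if outcome.rejected:
                stages.rejections.append({"specimen_id": specimen,
                                          "stage": f"{stage_name}_corrected",
                                          "reason": outcome.reason})
                continue
            checked, _ = final_translation_check(outcome.barcode,
                                                 table=params.table)
            target[specimen] = checked
    for specimen in sorted(set(stages.draft_corrected)
                           | set(stages.polished_corrected)):
        res = consolidate(stages.draft_corrected.get(specimen),
                          stages.polished_corrected.get(specimen))
        if res.rejected:
            stages.rejections.append({"specimen_id": specimen,
                                      "stage": "consolidated",
                                      "reason": res.reason})
            continue
        stages.consolidated[specimen] = res.barcode
    return stages


def run_read_pipeline(reads, fwd_primer: str, rev_primer: str,
                      fwd_tagset: TagSet, rev_tagset: TagSet,
                      layout: pd.DataFrame, library: dict[str, str],
                      seed: int = 0, demux_cfg: DemuxConfig | None = None,
                      params: CorrectionParams | None = None,
                      leave_one_out: bool = True
                      ) -> tuple[StageBarcodes, dict[str, DemuxBin], pd.DataFrame]:
    """Full run from raw reads to consolidated barcodes."""
    fwd_index = build_mutant_index(fwd_tagset)
    rev_index = build_mutant_index(rev_tagset)
    bins, summary = demultiplex(reads, fwd_primer, rev_primer,
                                fwd_index, rev_index, layout, demux_cfg)
    stages = call_all_barcodes(bins, seed=seed)
    stages = correct_all_barcodes(stages, library, params, leave_one_out)
    return stages, bins, summary
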