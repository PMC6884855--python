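"""Re-pooling decisions after a first sequencing pass.

Amplicons with low first-pass coverage are worth re-sequencing on a
washed/reused flowcell: specimens are classified as very_low (<= 10x),
low (10x < c <= 50x), problem (flagged by QC regardless of coverage, e.g.
> 1% ambiguous bases or divergence outliers) or ok, and per-plate text
maps mark the wells whose products should be re-pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_VERY_LOW = 10
DEFAULT_LOW = 50

CLASSES = ("very_low", "low", "problem", "ok")
_MARKS = {"very_low": "V", "low": "L", "problem": "!", "ok": "."}

ROWS = "ABCDEFGH"
COLUMNS = list(range(1, 13))


@dataclass
class PlateLayout:
    plate: str
    wells: pd.DataFrame  # columns: well, specimen_id, is_negative

    def __post_init__(self):
        if self.wells.well.duplicated().any():
            raise ValueError("duplicate wells in plate layout")
        if len(self.wells) > 96:
            raise ValueError("more than 96 wells on a plate")


@dataclass
class RepoolSelection:
    classes: dict[str, str] = field(default_factory=dict)  # specimen -> class
    coverages: dict[str, int] = field(default_factory=dict)

    def in_class(self, cls: str) -> list[str]:
        return [s for s, c in self.classes.items() if c == cls]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for c in self.classes.values():
            out[c] += 1
        return out


def classify_coverage(coverages: dict[str, int],
                      qc_flags: dict[str, bool] | None = None,
                      very_low: int = DEFAULT_VERY_LOW,
                      low: int = DEFAULT_LOW) -> RepoolSelection:
    """Classify specimens for re-pooling.

    problem: flagged by QC (ambiguity/divergence), regardless of coverage;
    very_low: coverage <= 10x; low: 10x < coverage <= 50x; else ok.
    Boundaries are inclusive ("<= 10x", "<= 50x").
    """
    qc_flags = qc_flags or {}
    classes = {}
    for specimen, cov in coverages.items():
        if cov < 0:
            raise ValueError("coverage must be >= 0")
        if qc_flags.get(specimen):
            classes[specimen] = "problem"
        elif cov <= very_low:
            classes[specimen] = "very_low"
        elif cov <= low:
            classes[specimen] = "low"
        else:
            classes[specimen] = "ok"
    return RepoolSelection(classes=classes, coverages=dict(coverages))


def plate_maps(layouts: list[PlateLayout], selection: RepoolSelection
               ) -> dict[str, str]:
    """Render one text grid per plate marking wells by re-pool class.

    Marks: V = very_low, L = low, ! = problem, . = ok, (space) = empty
    well, o = negative control. Raises if the selection names a specimen
    absent from every layout.
    """
    known = {sid for lay in layouts for sid in lay.wells.specimen_id}
    missing = set(selection.classes) - known
    if missing:
        raise ValueError(f"specimens not on any plate: {sorted(missing)[:5]}")
    maps = {}
    for lay in layouts:
        by_well = {r.well: r for r in lay.wells.itertuples()}
        lines = ["   " + " ".join(f"{c:>2d}" for c in COLUMNS)]
        for row in ROWS:
            cells = []
            for col in COLUMNS:
                rec = by_well.get(f"{row}{col}")
                if rec is None:
                    cells.append(" ")
                elif getattr(rec, "is_negative", False):
                    cells.append("o")
                else:
                    cls = selection.classes.get(rec.specimen_id)
                    cells.append(_MARKS.get(cls, " "))
            lines.append(f"{row}  " + " ".join(f"{c:>2}" for c in cells))
        maps[lay.plate] = "\n".join(lines)
    return maps


def repool_plan(selection: RepoolSelection,
                include: tuple[str, ...] = ("very_low", "low", "problem")
                ) -> pd.DataFrame:
    rows = [{"specimen_id": s, "class": c,
             "coverage": selection.coverages.get(s, 0),
             "repool": c in include}
            for s, c in sorted(selection.classes.items())]
    return pd.DataFrame(rows)
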