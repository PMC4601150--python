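"""Reader merging, per-kidney summarization, reference resolution and
cohort filtering.

Two readers measure each segment; the merged result is the element-wise
mean of the four absolute measures with the relative reductions recomputed
from the averaged values (keeping MinD/MaxD/Dred internally consistent),
or the single available reader's result when only one judged the segment
measurable.  One result per kidney is then chosen under three approaches:

* ``First``    — the largest Dred among the first segments of all arteries;
* ``Tightest`` — the largest Dred among all segments on that side;
* ``Main``     — the largest Dred within the main artery, the artery with
  the largest maximum diameter.

The functional reference is binary: a positive or negative first-line
result stands, and an intermediate one is resolved by the confirmatory
captopril test.  Cohort filtering drops kidneys lacking any of the three
investigations, kidneys non-measurable on either modality, and kidneys
contralateral to a positive one (the reference cannot inform the
contralateral side), emitting an accounting table of every drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .measure import SegmentSummary, ared, dred

APPROACHES = ("First", "Tightest", "Main")


# --------------------------------------------------------------------------- reader merging
def merge_readers(
    r1: SegmentSummary | None, r2: SegmentSummary | None, mode: str = "recompute"
) -> SegmentSummary:
    """Merge two readers' segment summaries.

    ``recompute`` (default) averages the four absolute measures and derives
    Dred/Ared from the averages; ``average_pct`` averages the readers'
    percentages directly (sensitivity alternative).  With a single reader
    the summary passes through unchanged.
    """
    if mode not in ("recompute", "average_pct"):
        raise ValueError(f"unknown merge mode {mode!r}")
    present = [r for r in (r1, r2) if r is not None and r.measurable]
    if not present:
        return SegmentSummary(measurable=False)
    if len(present) == 1:
        return present[0]
    a, b = present
    min_d = (a.min_d_mm + b.min_d_mm) / 2
    min_a = (a.min_a_mm2 + b.min_a_mm2) / 2
    max_d = (a.max_d_mm + b.max_d_mm) / 2
    max_a = (a.max_a_mm2 + b.max_a_mm2) / 2
    if mode == "recompute":
        d, ar = dred(min_d, max_d), ared(min_a, max_a)
    else:
        d = (a.dred_pct + b.dred_pct) / 2
        ar = (a.ared_pct + b.ared_pct) / 2
    return SegmentSummary(
        min_d_mm=min_d,
        min_a_mm2=min_a,
        max_d_mm=max_d,
        max_a_mm2=max_a,
        dred_pct=d,
        ared_pct=ar,
        fallback_used=a.fallback_used or b.fallback_used,
        measurable=True,
    )


# --------------------------------------------------------------------------- kidney records
@dataclass
class KidneyRecord:
    """All measurements and reference data for one kidney."""

    kidney_id: int
    patient: int
    side: str
    readers: dict[tuple[str, int, int], dict[int, SegmentSummary]] = field(default_factory=dict)
    # key: (modality, artery, segment) -> {reader: summary}
    cer: str | None = None  # "positive" | "intermediate" | "negative"
    ctest: str | None = None  # "positive" | "negative"
    visual_grades: dict[str, int] = field(default_factory=dict)
    has_cta: bool = True
    has_mra: bool = True
    has_reference: bool = True

    def merged(self, modality: str, mode: str = "recompute") -> dict[tuple[int, int], SegmentSummary]:
        out = {}
        for (mod, artery, seg), by_reader in self.readers.items():
            if mod != modality:
                continue
            merged = merge_readers(by_reader.get(1), by_reader.get(2), mode=mode)
            if merged.measurable:
                out[(artery, seg)] = merged
        return out

    def measurable_on(self, modality: str) -> bool:
        return bool(self.merged(modality))

    def resolved_label(self) -> str:
        return resolve_reference(self.cer, self.ctest)


@dataclass
class ApproachResult:
    approach: str
    artery: int
    segment: int
    min_d_mm: float
    min_a_mm2: float
    dred_pct: float
    ared_pct: float


def _main_artery(merged: dict[tuple[int, int], SegmentSummary]) -> int:
    """The artery with the largest maximum diameter in any of its segments;
    ties go to the artery with more measurable segments, then the lower id."""
    per_artery: dict[int, list[SegmentSummary]] = {}
    for (artery, _), summary in merged.items():
        per_artery.setdefault(artery, []).append(summary)
    ranked = sorted(
        per_artery.items(),
        key=lambda kv: (-max(s.max_d_mm for s in kv[1]), -len(kv[1]), kv[0]),
    )
    return ranked[0][0]


def summarize_kidney(
    record: KidneyRecord, approach: str, modality: str, merge_mode: str = "recompute"
) -> ApproachResult | None:
    """One result per kidney: the candidate segment with the largest Dred
    (ties: larger Ared, then segment 1 before 2, then lower artery id).
    Returns None when no candidate segment is measurable."""
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}")
    merged = record.merged(modality, mode=merge_mode)
    if approach == "First":
        candidates = {k: v for k, v in merged.items() if k[1] == 1}
    elif approach == "Tightest":
        candidates = dict(merged)
    else:
        if not merged:
            return None
        main = _main_artery(merged)
        candidates = {k: v for k, v in merged.items() if k[0] == main}
    if not candidates:
        return None
    (artery, seg), best = sorted(
        candidates.items(),
        key=lambda kv: (-kv[1].dred_pct, -kv[1].ared_pct, kv[0][1], kv[0][0]),
    )[0]
    return ApproachResult(
        approach=approach,
        artery=artery,
        segment=seg,
        min_d_mm=best.min_d_mm,
        min_a_mm2=best.min_a_mm2,
        dred_pct=best.dred_pct,
        ared_pct=best.ared_pct,
    )


# --------------------------------------------------------------------------- reference
def resolve_reference(cer: str | None, ctest: str | None) -> str:
    """Binary reference: positive/negative stand, intermediate defers to the
    captopril test."""
    if cer in ("positive", "negative"):
        return cer
    if cer == "intermediate":
        if ctest not in ("positive", "negative"):
            raise ValueError("intermediate first-line result requires a captopril test")
        return ctest
    raise ValueError(f"invalid reference result {cer!r}")


# --------------------------------------------------------------------------- filtering
def filter_cohort(records: list[KidneyRecord]) -> tuple[list[KidneyRecord], pd.DataFrame]:
    """Apply the analysis-set rules and account for every drop.

    1. keep only kidneys of patients with all three investigations;
    2. drop kidneys non-measurable on either modality;
    3. drop kidneys contralateral to a positive kidney — including positives
       that were themselves dropped as non-measurable.
    Solitary kidneys are never dropped by the contralateral rule.
    """
    steps = []

    def account(step: str, before: list, after: list) -> None:
        steps.append(
            {
                "step": step,
                "n_before": len(before),
                "n_dropped": len(before) - len(after),
                "n_after": len(after),
            }
        )

    complete = [r for r in records if r.has_cta and r.has_mra and r.has_reference]
    account("complete_investigations", records, complete)

    measurable = [
        r for r in complete if r.measurable_on("CTA") and r.measurable_on("MRA")
    ]
    account("measurable_both_modalities", complete, measurable)

    positive_sides: set[tuple[int, str]] = {
        (r.patient, r.side)
        for r in complete  # positives dropped as non-measurable still exclude
        if r.has_reference and r.resolved_label() == "positive"
    }
    kept = [
        r
        for r in measurable
        if not any(
            (r.patient, other) in positive_sides
            for other in ("L", "R")
            if other != r.side
        )
    ]
    account("contralateral_to_positive", measurable, kept)
    return kept, pd.DataFrame(steps)


def positive_fraction(records: list[KidneyRecord]) -> tuple[float, int, int]:
    """Percentage (and counts) of reference-positive kidneys in a set."""
    labels = [r.resolved_label() for r in records]
    n_pos = sum(lab == "positive" for lab in labels)
    return 100.0 * n_pos / len(labels), n_pos, len(labels)


# --------------------------------------------------------------------------- measurability
def measurability_stats(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per modality x segment: segments measurable by at least one reader,
    by both readers, and the both-reader percentage (rounded to integer)."""
    rows = []
    for (modality, segment), grp in measurements.groupby(["modality", "segment"]):
        per_seg = grp.groupby(["kidney", "artery"])["measurable"].sum()
        n_any = int((per_seg >= 1).sum())
        n_both = int((per_seg >= 2).sum())
        pct = int(round(100.0 * n_both / n_any)) if n_any else np.nan
        rows.append(
            {
                "modality": modality,
                "segment": segment,
                "n_measurable_any": n_any,
                "n_measurable_both": n_both,
                "pct_both": pct,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- table adapters
def records_from_cohort(cohort: Cohort) -> list[KidneyRecord]:
    """Assemble per-kidney records from the tidy cohort tables."""
    by_kidney = {}
    for _, krow in cohort.kidneys.iterrows():
        by_kidney[int(krow["kidney"])] = KidneyRecord(
            kidney_id=int(krow["kidney"]),
            patient=int(krow["patient"]),
            side=str(krow["side"]),
            cer=krow["cer"],
            ctest=None if pd.isna(krow["ctest"]) else krow["ctest"],
            visual_grades={
                "CTA": int(krow["visual_grade_cta"]),
                "MRA": int(krow["visual_grade_mra"]),
            },
            has_cta=bool(krow.get("has_cta", True)),
            has_mra=bool(krow.get("has_mra", True)),
            has_reference=bool(krow.get("has_reference", True)),
        )
    for row in cohort.measurements.itertuples(index=False):
        rec = by_kidney[int(row.kidney)]
        key = (str(row.modality), int(row.artery), int(row.segment))
        if row.measurable:
            summary = SegmentSummary(
                min_d_mm=float(row.min_d_mm),
                min_a_mm2=float(row.min_a_mm2),
                max_d_mm=float(row.max_d_mm),
                max_a_mm2=float(row.max_a_mm2),
                dred_pct=float(np.clip(row.dred_pct, 0, 100)),
                ared_pct=float(np.clip(row.ared_pct, 0, 100)),
                measurable=True,
            )
            rec.readers.setdefault(key, {})[int(row.reader)] = summary
        else:
            rec.readers.setdefault(key, {})
    return list(by_kidney.values())
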