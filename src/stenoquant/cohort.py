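"""Synthetic two-reader / two-modality measurement cohorts.

Emulates the study design around the morphometric pipeline: each kidney
has one or two renal arteries with up to two measurable segments; each
segment has true MinD/MinA/MaxD/MaxA implied by a true diameter reduction;
two readers measure every segment on both CTA and MRA with additive
Gaussian noise (a shared per-modality deviation plus independent
per-reader error); and each kidney carries a functional reference whose
probability of being positive is a saturating (logistic) function of the
true severity, with a stated fraction of intermediate first-line results
resolved by a confirmatory test.  Everything is driven by one seeded
generator, so a cohort is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

MEASURES = ("min_d", "max_d", "min_a", "max_a")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortSpec:
    """Study-condition parameters of the simulated cohort.

    Defaults emulate the source study's scale: 94 kidneys (47 patients),
    ~17 % of kidneys with an accessory artery, first-segment true Dred
    centred at 45 +/- 25 points, second segments milder, reference positive
    probability saturating around a 60 % diameter reduction, and ~13 % of
    kidneys receiving an intermediate first-line result.
    """

    n_kidneys: int = 94
    arteries_per_kidney: dict[int, float] = field(default_factory=lambda: {1: 0.83, 2: 0.17})
    dred_mean_sd_seg1: tuple[float, float] = (45.0, 25.0)
    dred_mean_sd_seg2: tuple[float, float] = (25.0, 15.0)
    max_d_mean_sd_mm: tuple[float, float] = (5.2, 0.7)
    p_second_segment: float = 0.9
    reader_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"min_d": 0.25, "max_d": 0.30, "min_a": 1.5, "max_a": 2.0}
    )
    modality_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"min_d": 0.35, "max_d": 0.40, "min_a": 2.0, "max_a": 2.5}
    )
    mra_bias: dict[str, float] = field(
        default_factory=lambda: {"min_d": -0.15, "max_d": 0.0, "min_a": -0.8, "max_a": 0.0}
    )
    reference_midpoint_dred: float = 60.0
    reference_slope_dred: float = 6.0  # logistic scale in Dred points
    fraction_intermediate: float = 0.13
    p_reader_missing: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("CTA", 1): 0.04,
            ("CTA", 2): 0.16,
            ("MRA", 1): 0.05,
            ("MRA", 2): 0.20,
        }
    )
    p_kidney_missing: float = 0.02  # whole kidney unmeasurable on one modality
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kidneys <= 0:
            raise ValueError("n_kidneys must be positive")
        if not math.isclose(sum(self.arteries_per_kidney.values()), 1.0, abs_tol=1e-9):
            raise ValueError("arteries_per_kidney probabilities must sum to 1")
        for d in (self.reader_noise_sd, self.modality_noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("noise SDs must be non-negative")
        for p in list(self.p_reader_missing.values()) + [
            self.fraction_intermediate,
            self.p_kidney_missing,
            self.p_second_segment,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class Cohort(NamedTuple):
    measurements: pd.DataFrame  # one row per kidney x artery x segment x reader x modality
    kidneys: pd.DataFrame  # one row per kidney: reference and visual grades


def _visual_grade(dred_pct: float) -> int:
    """Six-grade visual scale: 0 normal, then >10-30, >30-50, >50-70, >70 %,
    5 = occlusion."""
    if dred_pct >= 100.0:
        return 5
    for grade, upper in enumerate((10.0, 30.0, 50.0, 70.0)):
        if dred_pct <= upper:
            return grade
    return 4


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort; identical specs yield identical tables."""
    rng = np.random.default_rng(spec.seed)
    n_counts = sorted(spec.arteries_per_kidney)
    n_probs = [spec.arteries_per_kidney[k] for k in n_counts]

    rows = []
    kidney_rows = []
    for k in range(spec.n_kidneys):
        patient = k // 2
        side = "L" if k % 2 == 0 else "R"
        n_arteries = int(rng.choice(n_counts, p=n_probs))
        kidney_missing = {m: rng.random() < spec.p_kidney_missing for m in ("CTA", "MRA")}
        true_dreds = []
        for artery in range(1, n_arteries + 1):
            size_factor = 1.0 if artery == 1 else 0.75
            max_d1 = float(
                np.clip(rng.normal(*spec.max_d_mean_sd_mm) * size_factor, 3.0, 7.5)
            )
            segments = [(1, max_d1, spec.dred_mean_sd_seg1)]
            if rng.random() < spec.p_second_segment:
                segments.append((2, 0.8 * max_d1, spec.dred_mean_sd_seg2))
            for seg, max_d, (mu, sd) in segments:
                true_dred = float(np.clip(rng.normal(mu, sd), 0.0, 95.0))
                true_dreds.append(true_dred)
                true = {
                    "max_d": max_d,
                    "min_d": max_d * (1.0 - true_dred / 100.0),
                }
                true["max_a"] = math.pi * (true["max_d"] / 2.0) ** 2
                true["min_a"] = math.pi * (true["min_d"] / 2.0) ** 2
                for modality in ("CTA", "MRA"):
                    shared = {
                        m: rng.normal(0.0, spec.modality_noise_sd[m])
                        + (spec.mra_bias[m] if modality == "MRA" else 0.0)
                        for m in MEASURES
                    }
                    for reader in (1, 2):
                        missing = kidney_missing[modality] or (
                            rng.random() < spec.p_reader_missing[(modality, seg)]
                        )
                        meas = {
                            m: max(true[m] + shared[m] + rng.normal(0.0, spec.reader_noise_sd[m]), 0.05)
                            for m in MEASURES
                        }
                        meas["max_d"] = max(meas["max_d"], meas["min_d"])
                        meas["max_a"] = max(meas["max_a"], meas["min_a"])
                        rows.append(
                            {
                                "patient": patient,
                                "kidney": k,
                                "side": side,
                                "artery": artery,
                                "segment": seg,
                                "modality": modality,
                                "reader": reader,
                                "measurable": not missing,
                                "min_d_mm": meas["min_d"] if not missing else np.nan,
                                "min_a_mm2": meas["min_a"] if not missing else np.nan,
                                "max_d_mm": meas["max_d"] if not missing else np.nan,
                                "max_a_mm2": meas["max_a"] if not missing else np.nan,
                                "dred_pct": (1 - meas["min_d"] / meas["max_d"]) * 100
                                if not missing
                                else np.nan,
                                "ared_pct": (1 - meas["min_a"] / meas["max_a"]) * 100
                                if not missing
                                else np.nan,
                                "true_min_d_mm": true["min_d"],
                                "true_max_d_mm": true["max_d"],
                                "true_min_a_mm2": true["min_a"],
                                "true_max_a_mm2": true["max_a"],
                                "true_dred_pct": true_dred,
                            }
                        )
        severity = max(true_dreds)
        p_pos = float(
            _logistic(
                (np.asarray(severity) - spec.reference_midpoint_dred)
                / spec.reference_slope_dred
            )
        )
        if rng.random() < spec.fraction_intermediate:
            cer = "intermediate"
            ctest = "positive" if rng.random() < p_pos else "negative"
        else:
            cer = "positive" if rng.random() < p_pos else "negative"
            ctest = None
        kidney_rows.append(
            {
                "kidney": k,
                "patient": patient,
                "side": side,
                "n_arteries": n_arteries,
                "true_severity_dred_pct": severity,
                "p_positive": p_pos,
                "cer": cer,
                "ctest": ctest,
                "visual_grade_cta": _visual_grade(severity + rng.normal(0, 5)),
                "visual_grade_mra": _visual_grade(severity + rng.normal(0, 5)),
                "has_cta": True,
                "has_mra": True,
                "has_reference": True,
            }
        )
    return Cohort(pd.DataFrame(rows), pd.DataFrame(kidney_rows))
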