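"""Volumetric endpoints, clinical-score tracking, and the cohort report.

The study's imaging endpoints compare the acute lesion volume on
pre-treatment DWI with the residual lesion volume on 1-month FLAIR:

* mismatch (cm^3) = FLAIR_post - DWI_pre; negative means the lesion shrank
* FLAIR/DWI rate  = FLAIR_post / DWI_pre; < 1 means the lesion shrank

Clinical status is tracked on three standard stroke scales — NIHSS
(deficit severity, 0 = none), Barthel Index (activities of daily living,
100 = independent) and modified Rankin Scale (disability grade, 0 = none)
— at baseline, 5 days, 1, 3 and 12 months, with follow-up changes taken
against baseline.  Missing visits propagate as absent, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dosimetry import DoseSummary

VISITS = ("baseline", "day5", "month1", "month3", "month12")
SCALES = ("nihss", "bi", "mrs")
EVOLUTIONS = ("reduced", "grew", "unchanged")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables);
    numpy/python bankers' rounding would differ on exact .5 ties."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def mismatch(dwi_pre_cm3: float, flair_post_cm3: float) -> float:
    """FLAIR-DWI volumetric mismatch (cm^3): post volume minus pre volume."""
    if dwi_pre_cm3 < 0 or flair_post_cm3 < 0:
        raise ValueError("volumes must be non-negative")
    return flair_post_cm3 - dwi_pre_cm3


def flair_dwi_rate(dwi_pre_cm3: float, flair_post_cm3: float) -> float:
    """FLAIR/DWI volume ratio (dimensionless); the report rounds to 2 dp."""
    if dwi_pre_cm3 < 0 or flair_post_cm3 < 0:
        raise ValueError("volumes must be non-negative")
    if dwi_pre_cm3 == 0:
        raise ZeroDivisionError("pre-treatment DWI volume is zero; rate undefined")
    return flair_post_cm3 / dwi_pre_cm3


def classify_evolution(mismatch_cm3: float) -> str:
    """'reduced' for negative mismatch, 'grew' for positive, 'unchanged' at 0."""
    if mismatch_cm3 < 0:
        return "reduced"
    if mismatch_cm3 > 0:
        return "grew"
    return "unchanged"


@dataclass(frozen=True)
class VolumetricsResult:
    dwi_pre_cm3: float
    flair_post_cm3: float
    mismatch_cm3: float
    rate: float
    evolution: str

    def __post_init__(self):
        if self.evolution not in EVOLUTIONS:
            raise ValueError(f"evolution must be one of {EVOLUTIONS}")


def volumetric_endpoints(dwi_pre_cm3: float, flair_post_cm3: float) -> VolumetricsResult:
    """All volumetric endpoints from the two measured volumes."""
    m = mismatch(dwi_pre_cm3, flair_post_cm3)
    return VolumetricsResult(
        dwi_pre_cm3=dwi_pre_cm3, flair_post_cm3=flair_post_cm3,
        mismatch_cm3=m, rate=flair_dwi_rate(dwi_pre_cm3, flair_post_cm3),
        evolution=classify_evolution(m),
    )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: stimulation arm, score trajectories, volumes, dose.

    Score sequences are aligned with :data:`VISITS`; a missing visit is
    ``None``.  ``scores_verified=False`` flags rows whose printed source
    was ambiguous and whose scores should not be asserted against.
    """

    patient_id: int
    stim_minutes: int
    nihss: tuple[Optional[int], ...]
    bi: tuple[Optional[int], ...]
    mrs: tuple[Optional[int], ...]
    volumetrics: VolumetricsResult
    dose: Optional[DoseSummary] = None
    scores_verified: bool = True

    def __post_init__(self):
        for name, seq, lo, hi in (("nihss", self.nihss, 0, None),
                                  ("bi", self.bi, 0, 100),
                                  ("mrs", self.mrs, 0, 6)):
            if len(seq) != len(VISITS):
                raise ValueError(f"{name} must have {len(VISITS)} visit entries")
            for v in seq:
                if v is None:
                    continue
                if v < lo or (hi is not None and v > hi):
                    raise ValueError(f"{name} value {v} outside [{lo}, {hi}]")

    def scores(self, scale: str) -> tuple[Optional[int], ...]:
        if scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
        return getattr(self, scale)


def score_change(record: PatientRecord, scale: str, visit: str) -> Optional[int]:
    """Signed change from baseline at a follow-up visit; None if the visit
    is missing (absence propagates, it is never imputed)."""
    if visit not in VISITS:
        raise ValueError(f"visit must be one of {VISITS}, got {visit!r}")
    seq = record.scores(scale)
    baseline = seq[VISITS.index("baseline")]
    if baseline is None:
        raise ValueError(f"patient {record.patient_id} has no baseline {scale}")
    value = seq[VISITS.index(visit)]
    return None if value is None else value - baseline


def summarize_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient with scores, volumes, endpoints and dose.

    Mismatch and rate are rounded half-away-from-zero to 2 decimals (the
    table convention); distances and fields to 1 decimal.  Missing values
    are left empty.
    """
    if not records:
        raise ValueError("at least one record is required")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate patient_id in cohort: {sorted(ids)}")

    rows = []
    for r in records:
        row: dict = {"patient": r.patient_id, "stim_minutes": r.stim_minutes}
        for scale in SCALES:
            for visit, val in zip(VISITS, r.scores(scale)):
                row[f"{scale}_{visit}"] = val
        v = r.volumetrics
        row.update({
            "dwi_pre_cm3": v.dwi_pre_cm3,
            "flair_post_cm3": v.flair_post_cm3,
            "mismatch_cm3": round_half_up(v.mismatch_cm3, 2),
            "flair_dwi_rate": round_half_up(v.rate, 2),
            "evolution": v.evolution,
        })
        if r.dose is not None:
            row.update({
                "d_min_cm": round_half_up(r.dose.d_min_cm, 1),
                "d_max_cm": round_half_up(r.dose.d_max_cm, 1),
                "b_min_mT": round_half_up(r.dose.b_min_mT, 1),
                "b_max_mT": round_half_up(r.dose.b_max_mT, 1),
                "frac_above_threshold": r.dose.frac_above_threshold,
                "threshold_mT": r.dose.threshold_mT,
            })
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.astype({c: "Int64" for c in df.columns
                      if c.split("_")[0] in SCALES or c in ("patient", "stim_minutes")})


def group_summary(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-stimulation-arm counts of lesion evolution (available cases)."""
    rows = []
    for stim in sorted({r.stim_minutes for r in records}):
        group = [r for r in records if r.stim_minutes == stim]
        evo = [r.volumetrics.evolution for r in group]
        rows.append({
            "stim_minutes": stim,
            "n": len(group),
            "reduced": evo.count("reduced"),
            "grew": evo.count("grew"),
            "unchanged": evo.count("unchanged"),
        })
    return pd.DataFrame(rows)
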