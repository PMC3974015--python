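"""Biodistribution arithmetic: %ID/g and the optical-flux vs activity ratios.

Excised organs are measured twice — gamma counts (activity) and IVIS optical
flux (photons/s).  Activity becomes the standard percent-injected-dose per
gram; both channels are then normalized to the thigh-muscle sample, and the
per-organ ratio of normalized flux to normalized activity isolates how much
Cerenkov light an organ lets out per unit of radioactivity.  Blood is the
extreme case: the most activity (6.2x muscle) but the least light
(0.32x muscle), a light-to-activity ratio of ~0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .physics import GA68, RadionuclideSpec, decay_factor

logger = logging.getLogger("cerevasc")

__all__ = [
    "ORGANS",
    "OrganRecord",
    "CountCalibration",
    "percent_id_per_g",
    "normalize_to_reference",
    "light_activity_ratio",
    "records_to_frame",
    "frame_to_records",
]

#: Controlled organ vocabulary.  Unknown labels are passed through with a
#: warning rather than rejected.
ORGANS = frozenset({
    "blood", "heart", "lungs", "liver", "spleen", "kidneys",
    "intestines", "tumor", "brain", "muscle", "femur",
})


@dataclass(frozen=True)
class OrganRecord:
    """One organ's paired gamma-count and optical-flux measurement.

    Derived fields are ``None`` until filled by the operations below.
    """

    organ: str
    weight_g: float
    counts: float
    flux_ps: float
    elapsed_min: float = 0.0
    pct_id_per_g: float | None = None
    activity_rel_muscle: float | None = None
    flux_rel_muscle: float | None = None

    def __post_init__(self) -> None:
        if self.weight_g <= 0:
            raise ValueError(f"weight_g must be > 0, got {self.weight_g}")
        if self.counts < 0:
            raise ValueError(f"counts must be >= 0, got {self.counts}")
        if self.organ not in ORGANS:
            logger.warning("unknown organ label %r (not in controlled vocabulary)",
                           self.organ)


@dataclass(frozen=True)
class CountCalibration:
    """Gamma-counter standard-curve slope: counts per MBq."""

    counts_per_mbq: float

    def __post_init__(self) -> None:
        if self.counts_per_mbq <= 0:
            raise ValueError("counts_per_mbq must be > 0")


def percent_id_per_g(
    rec: OrganRecord,
    cal: CountCalibration,
    injected_mbq: float,
    nuclide: RadionuclideSpec = GA68,
) -> float:
    """Percent injected dose per gram, decay-corrected to injection time.

    Organ activity = counts / counts_per_mbq, divided by the decay factor
    over ``rec.elapsed_min`` (standard %ID/g convention: activity is quoted
    at injection time), then 100 x activity / injected dose / organ weight.
    """
    if injected_mbq <= 0:
        raise ValueError(f"injected_mbq must be > 0, got {injected_mbq}")
    activity = rec.counts / cal.counts_per_mbq
    activity /= decay_factor(rec.elapsed_min, nuclide.half_life_min)
    return 100.0 * activity / injected_mbq / rec.weight_g


def normalize_to_reference(
    records: Sequence[OrganRecord],
    reference: str = "muscle",
) -> list[OrganRecord]:
    """Fill per-organ counts and flux ratios relative to a reference organ.

    Returns new records with ``activity_rel_muscle`` and ``flux_rel_muscle``
    set; the reference organ's ratios are exactly 1.
    """
    ref = [r for r in records if r.organ == reference]
    if not ref:
        raise ValueError(f"reference organ {reference!r} not present")
    ref_rec = ref[0]
    if ref_rec.counts <= 0 or ref_rec.flux_ps <= 0:
        raise ValueError(
            f"reference organ {reference!r} must have positive counts and flux"
        )
    return [
        replace(
            r,
            activity_rel_muscle=r.counts / ref_rec.counts,
            flux_rel_muscle=r.flux_ps / ref_rec.flux_ps,
        )
        for r in records
    ]


def light_activity_ratio(rec: OrganRecord) -> float:
    """Muscle-normalized flux divided by muscle-normalized activity.

    Requires :func:`normalize_to_reference` to have been applied.
    """
    if rec.activity_rel_muscle is None or rec.flux_rel_muscle is None:
        raise ValueError("record has no normalized ratios; run normalize_to_reference")
    if rec.activity_rel_muscle <= 0:
        raise ValueError("activity_rel_muscle must be > 0")
    return rec.flux_rel_muscle / rec.activity_rel_muscle


def records_to_frame(records: Iterable[OrganRecord]) -> pd.DataFrame:
    """Tabulate records (base columns plus any filled derived columns)."""
    rows = []
    for r in records:
        row = {
            "organ": r.organ, "weight_g": r.weight_g, "counts": r.counts,
            "flux_ps": r.flux_ps, "elapsed_min": r.elapsed_min,
        }
        for col in ("pct_id_per_g", "activity_rel_muscle", "flux_rel_muscle"):
            val = getattr(r, col)
            if val is not None:
                row[col] = val
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[OrganRecord]:
    """Inverse of :func:`records_to_frame` for the base columns."""
    required = {"organ", "weight_g", "counts", "flux_ps"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"biodistribution table missing columns: {sorted(missing)}")
    return [
        OrganRecord(
            organ=str(row["organ"]),
            weight_g=float(row["weight_g"]),
            counts=float(row["counts"]),
            flux_ps=float(row["flux_ps"]),
            elapsed_min=float(row.get("elapsed_min", 0.0)),
        )
        for _, row in frame.iterrows()
    ]
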