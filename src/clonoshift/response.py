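"""Tumor-volume computation and the 5-category preclinical response call.

Caliper measurements give volume V = length * width^2 * pi / 6 (mm^3).
Relative tumor volume (RTV) normalizes each timepoint to the randomization
day, and the trajectory of RTVs after randomization is classified as:

* MCR (maintained complete response): RTV = 0 at the end of the study;
* CR  (complete response): RTV = 0 at >= 1 timepoint but regrowth by the end;
* PR  (partial response):  0 < RTV <= 0.5 at >= 1 timepoint;
* SD  (stable disease):    RTV > 0.5 throughout, end RTV <= 1.25;
* PD  (progressive disease): RTV > 0.5 throughout, end RTV > 1.25.

The printed rules overlap (every CR trajectory also satisfies PR); the
precedence MCR > CR > PR > SD/PD makes the classifier total and matches the
clinical hierarchy of response depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError

RESPONSE_CATEGORIES = ("PD", "SD", "PR", "CR", "MCR")


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid-approximation volume, length * width^2 * pi/6, in mm^3.

    Convention: length is the larger caliper axis; a width exceeding length
    is accepted (measurement noise) but the formula is not symmetrized.
    """
    if length <= 0 or width <= 0:
        raise ValueError(f"nonpositive dimensions ({length}, {width})")
    return length * width**2 * math.pi / 6.0


@dataclass
class GrowthSeries:
    """Volume time series of one animal with a randomization reference day."""

    animal_id: str
    days: np.ndarray
    volumes: np.ndarray
    ref_day: int

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.days) != len(self.volumes):
            raise DataError(f"{self.animal_id}: days/volumes length mismatch")
        if not (np.diff(self.days) > 0).all():
            raise DataError(f"{self.animal_id}: days must be strictly increasing")
        if (self.volumes < 0).any():
            raise DataError(f"{self.animal_id}: negative volume")
        if self.ref_day not in self.days:
            raise DataError(
                f"{self.animal_id}: reference day {self.ref_day} not measured"
            )

    @property
    def ref_volume(self) -> float:
        return float(self.volumes[self.days == self.ref_day][0])


def relative_tumor_volume(series: GrowthSeries) -> np.ndarray:
    """RTV_t = V_t / V_ref for every timepoint at or after the reference day."""
    v_ref = series.ref_volume
    if v_ref == 0:
        raise DataError(f"{series.animal_id}: zero volume on randomization day")
    after = series.days >= series.ref_day
    return series.volumes[after] / v_ref


def combine_series(a: GrowthSeries, b: GrowthSeries) -> GrowthSeries:
    """Sum two same-animal series day-by-day (primary + non-irradiated tumor),
    for total-burden response calls in abscopal experiments."""
    if not np.array_equal(a.days, b.days) or a.ref_day != b.ref_day:
        raise DataError("series must share measurement days and reference day")
    return GrowthSeries(
        animal_id=a.animal_id,
        days=a.days,
        volumes=a.volumes + b.volumes,
        ref_day=a.ref_day,
    )


def classify_response(rtv) -> str:
    """Classify an RTV trajectory into PD/SD/PR/CR/MCR.

    ``rtv`` holds the post-reference relative volumes in time order (the
    reference point itself, RTV = 1, may be included; it never changes the
    call).  "End of the study" is the last recorded value, so an animal
    leaving the study early is classified on its available data.
    """
    rtv = np.asarray(rtv, dtype=float)
    if rtv.size == 0:
        raise ValueError("empty RTV trajectory")
    if (rtv < 0).any():
        raise ValueError("negative RTV")
    end = rtv[-1]
    if end == 0:
        return "MCR"
    if (rtv == 0).any():
        return "CR"
    if (rtv <= 0.5).any():
        return "PR"
    return "SD" if end <= 1.25 else "PD"


def classify_series(series: GrowthSeries) -> str:
    """Response category of a growth series (RTV computed internally)."""
    return classify_response(relative_tumor_volume(series))


def percent_volume_change(
    series: GrowthSeries, start_day: int, end_day: int
) -> float:
    """Percent change between two measured days, for waterfall summaries."""
    for day in (start_day, end_day):
        if day not in series.days:
            raise DataError(f"{series.animal_id}: day {day} not measured")
    v0 = float(series.volumes[series.days == start_day][0])
    v1 = float(series.volumes[series.days == end_day][0])
    if v0 == 0:
        raise DataError(f"{series.animal_id}: zero volume on start day")
    return 100.0 * (v1 - v0) / v0
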