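"""Semi-quantitative immunohistochemistry (IHC) scoring for HRS-cell markers.

Raw readings per sample and marker are a four-level staining-intensity
category and the percentage of Hodgkin/Reed-Sternberg (HRS) cells staining
positive.  SATB1 is quantified with the immunoreactive score (IRS): the
staining-intensity points (SI, 0-3) multiplied by the percent-positive
points (PP, 1-3); an IRS above 1 is called positive.  p16 is quantified
with a four-tier percent-positive score (0-3); any tier above "negative"
(>= 10% positive HRS cells) is called positive by default.

Boundary conventions (documented, configurable only for the p16 cut):

* PP points: [0, 10) -> 1, [10, 50] -> 2, (50, 100] -> 3.
* p16 tiers: [0, 10) -> 0, [10, 30) -> 1, [30, 60) -> 2, [60, 100] -> 3.
* Staining location (nuclear vs cytoplasmic) is not modelled; any staining
  counts toward percent_positive.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import DuplicateKeyError, ValidationError

__all__ = [
    "Marker",
    "Intensity",
    "IHCMeasurement",
    "MarkerCall",
    "staining_intensity_score",
    "intensity_from_score",
    "percent_positive_score",
    "satb1_irs_call",
    "p16_tier",
    "p16_call",
    "score_measurement",
    "call_cohort",
]


class Marker(str, Enum):
    SATB1 = "SATB1"
    P16 = "P16"


class Intensity(str, Enum):
    NEGATIVE = "negative"  # no staining
    WEAK = "weak"          # pale yellow
    MODERATE = "moderate"  # yellow-brown
    STRONG = "strong"      # dark brown


_SI_POINTS = {
    Intensity.NEGATIVE: 0,
    Intensity.WEAK: 1,
    Intensity.MODERATE: 2,
    Intensity.STRONG: 3,
}
_SI_INVERSE = {v: k for k, v in _SI_POINTS.items()}


def _coerce_intensity(intensity: Union[str, Intensity]) -> Intensity:
    try:
        return Intensity(intensity)
    except ValueError:
        valid = ", ".join(i.value for i in Intensity)
        raise ValidationError(
            f"unknown staining-intensity category {intensity!r}; expected one of: {valid}"
        ) from None


def _coerce_marker(marker: Union[str, Marker]) -> Marker:
    if isinstance(marker, Marker):
        return marker
    try:
        return Marker(str(marker).upper())
    except ValueError:
        raise ValidationError(f"unknown marker {marker!r}; expected SATB1 or P16") from None


def _check_percent(percent_positive: float) -> float:
    pp = float(percent_positive)
    if not (0.0 <= pp <= 100.0):
        raise ValidationError(f"percent_positive must lie in [0, 100], got {percent_positive!r}")
    return pp


@dataclass(frozen=True)
class IHCMeasurement:
    """One raw IHC reading: a sample, a marker, an intensity category and the
    aggregated percentage of positive HRS cells (already averaged over fields)."""

    sample_id: str
    marker: Marker
    intensity: Intensity
    percent_positive: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", _coerce_marker(self.marker))
        object.__setattr__(self, "intensity", _coerce_intensity(self.intensity))
        object.__setattr__(self, "percent_positive", _check_percent(self.percent_positive))


@dataclass(frozen=True)
class MarkerCall:
    """Derived semi-quantitative scores and the binary positivity call.

    ``si_score``/``pp_score``/``irs`` are populated for SATB1, ``tier`` for
    p16; unused fields are ``None``.
    """

    sample_id: str
    marker: Marker
    positive: bool
    si_score: Optional[int] = None
    pp_score: Optional[int] = None
    irs: Optional[int] = None
    tier: Optional[int] = None


def staining_intensity_score(intensity: Union[str, Intensity]) -> int:
    """Map the staining-intensity category to its points (0-3).

    negative -> 0, weak -> 1, moderate -> 2, strong -> 3.
    """
    return _SI_POINTS[_coerce_intensity(intensity)]


def intensity_from_score(score: int) -> Intensity:
    """Inverse of :func:`staining_intensity_score` (the mapping is a bijection)."""
    try:
        return _SI_INVERSE[int(score)]
    except KeyError:
        raise ValidationError(f"staining-intensity score must be 0..3, got {score!r}") from None


def percent_positive_score(percent_positive: float) -> int:
    """Points for the percentage of positive HRS cells (SATB1 PP score).

    <10% -> 1, 10-50% -> 2, >50% -> 3.  Piecewise constant and
    non-decreasing; the upper edge of each bin belongs to the lower score
    (50 -> 2, 50.1 -> 3).
    """
    pp = _check_percent(percent_positive)
    if pp < 10.0:
        return 1
    if pp <= 50.0:
        return 2
    return 3


def satb1_irs_call(si_score: int, pp_score: int, sample_id: str = "") -> MarkerCall:
    """Combine SI and PP points into the immunoreactive score and call.

    IRS = SI x PP; an IRS of 1 or lower is negative, above 1 positive.
    """
    si = int(si_score)
    pp = int(pp_score)
    if si not in (0, 1, 2, 3):
        raise ValidationError(f"si_score must be in 0..3, got {si_score!r}")
    if pp not in (1, 2, 3):
        raise ValidationError(f"pp_score must be in 1..3, got {pp_score!r}")
    irs = si * pp
    return MarkerCall(
        sample_id=sample_id,
        marker=Marker.SATB1,
        si_score=si,
        pp_score=pp,
        irs=irs,
        positive=irs > 1,
    )


def p16_tier(percent_positive: float) -> int:
    """Four-tier p16 score from the percentage of positive HRS cells.

    <10% -> 0 (negative), 10-29% -> 1 (low), 30-59% -> 2 (moderate),
    >=60% -> 3 (high).
    """
    pp = _check_percent(percent_positive)
    if pp < 10.0:
        return 0
    if pp < 30.0:
        return 1
    if pp < 60.0:
        return 2
    return 3


def p16_call(
    percent_positive: float,
    sample_id: str = "",
    si_score: Optional[int] = None,
    positive_min_tier: int = 1,
) -> MarkerCall:
    """p16 call from the percent-positive tier.

    The binary cut defaults to tier >= 1, i.e. at least 10% positive HRS
    cells; ``positive_min_tier`` makes the cut configurable.
    """
    tier = p16_tier(percent_positive)
    return MarkerCall(
        sample_id=sample_id,
        marker=Marker.P16,
        tier=tier,
        si_score=si_score,
        positive=tier >= positive_min_tier,
    )


def score_measurement(m: IHCMeasurement, p16_positive_min_tier: int = 1) -> MarkerCall:
    """Score one raw measurement according to its marker's scheme."""
    si = staining_intensity_score(m.intensity)
    if m.marker is Marker.SATB1:
        return satb1_irs_call(si, percent_positive_score(m.percent_positive), m.sample_id)
    return p16_call(m.percent_positive, m.sample_id, si_score=si,
                    positive_min_tier=p16_positive_min_tier)


def call_cohort(
    measurements: Iterable[IHCMeasurement],
    p16_positive_min_tier: int = 1,
) -> pd.DataFrame:
    """Score a whole cohort of measurements.

    Returns one row per measurement with columns ``sample_id, marker,
    si_score, pp_score, irs, tier, positive``.  Each (sample_id, marker)
    pair may appear at most once.
    """
    rows = []
    seen = set()
    for m in measurements:
        key = (m.sample_id, m.marker)
        if key in seen:
            raise DuplicateKeyError(
                f"duplicate measurement for sample {m.sample_id!r}, marker {m.marker.value}"
            )
        seen.add(key)
        call = score_measurement(m, p16_positive_min_tier=p16_positive_min_tier)
        rows.append(
            {
                "sample_id": call.sample_id,
                "marker": call.marker.value,
                "si_score": call.si_score,
                "pp_score": call.pp_score,
                "irs": call.irs,
                "tier": call.tier,
                "positive": call.positive,
            }
        )
    columns = ["sample_id", "marker", "si_score", "pp_score", "irs", "tier", "positive"]
    return pd.DataFrame(rows, columns=columns)


def read_measurements_csv(path) -> list:
    """Read raw measurements from CSV with columns
    sample_id, marker, intensity, percent_positive."""
    frame = pd.read_csv(path)
    required = ["sample_id", "marker", "intensity", "percent_positive"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"measurements table is missing columns: {missing}")
    return [
        IHCMeasurement(
            sample_id=str(row["sample_id"]),
            marker=row["marker"],
            intensity=row["intensity"],
            percent_positive=float(row["percent_positive"]),
        )
        for _, row in frame.iterrows()
    ]


def write_measurements_csv(measurements: Iterable[IHCMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "marker": m.marker.value,
                "intensity": m.intensity.value,
                "percent_positive": m.percent_positive,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)
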