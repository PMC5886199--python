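"""Synthetic facility survey and the raw-to-unitless stock scaling.

The stock scales of the simulator are unitless, anchored to the spread of a
national health-facility survey: -1, 0 and +1 stand for below-average,
average and above-average facilities.  This module generates a synthetic
survey emulating that calibration input -- per-facility aggregate quality
scores on a 0-100 scale and monthly client volumes -- and fits the
piecewise-linear maps that carry raw values onto [-1, 1].

The generator is a stand-in for the real (unavailable) survey: it emulates
only the distributional shape needed to anchor the scales, not any actual
facility's data.  Quality scores are drawn from a truncated normal on
[0, 100]; client volumes from a lognormal (right-skewed, as facility
caseloads are).  The simulator's stocks are already unitless, so default
simulations do not depend on this module; it makes the calibration story
testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .params import InvariantError, _require

__all__ = [
    "FacilityRecord",
    "SurveySpec",
    "ScalingMap",
    "generate_survey",
    "fit_scaling",
    "scale",
    "unscale",
]


@dataclass(frozen=True)
class FacilityRecord:
    """One synthetic facility: aggregate quality score and monthly volume."""

    facility_id: str
    raw_quality: float  # 0-100 aggregate of structural/process/perception quality
    raw_volume: float  # clients per month

    def __post_init__(self) -> None:
        _require(0.0 <= self.raw_quality <= 100.0, "raw_quality", "must lie in [0, 100]")
        _require(self.raw_volume >= 0.0, "raw_volume", "must be non-negative")


@dataclass(frozen=True)
class SurveySpec:
    """Distributional shape of the synthetic survey.

    Quality ~ truncated normal(mean, sd) on [0, 100]; volume ~ lognormal
    with the given median (clients/month) and log-scale sigma (right skew).
    Defaults describe a middling rural primary-care network: a broad quality
    distribution centred a little above half marks, and a typical caseload
    of a few hundred clients a month with a heavy right tail.
    """

    quality_mean: float = 55.0
    quality_sd: float = 15.0
    volume_median: float = 450.0
    volume_sigma: float = 0.6

    def __post_init__(self) -> None:
        _require(0.0 <= self.quality_mean <= 100.0, "quality_mean", "must lie in [0, 100]")
        _require(self.quality_sd >= 0.0, "quality_sd", "must be non-negative")
        _require(self.volume_median > 0.0, "volume_median", "must be positive")
        _require(self.volume_sigma >= 0.0, "volume_sigma", "must be non-negative")


def generate_survey(
    n: int = 641, seed: int = 0, spec: SurveySpec | None = None
) -> list[FacilityRecord]:
    """Draw ``n`` synthetic facility records, reproducibly for a fixed seed."""
    if n < 2:
        raise InvariantError("n: at least 2 facilities are needed to fit a scaling range")
    if spec is None:
        spec = SurveySpec()
    rng = np.random.default_rng(seed)
    if spec.quality_sd == 0.0:
        quality = np.full(n, spec.quality_mean)
    else:
        a = (0.0 - spec.quality_mean) / spec.quality_sd
        b = (100.0 - spec.quality_mean) / spec.quality_sd
        quality = stats.truncnorm.rvs(
            a, b, loc=spec.quality_mean, scale=spec.quality_sd, size=n, random_state=rng
        )
    if spec.volume_sigma == 0.0:
        volume = np.full(n, spec.volume_median)
    else:
        volume = spec.volume_median * np.exp(spec.volume_sigma * rng.standard_normal(n))
    return [
        FacilityRecord(f"HF{i:04d}", float(q), float(v))
        for i, (q, v) in enumerate(zip(quality, volume))
    ]


def survey_frame(records: Sequence[FacilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "facility_id": [r.facility_id for r in records],
            "raw_quality": [r.raw_quality for r in records],
            "raw_volume": [r.raw_volume for r in records],
        }
    )


@dataclass(frozen=True)
class ScalingMap:
    """Piecewise-linear map taking raw survey values onto [-1, 1].

    ``anchor_low`` maps to -1, ``anchor_mid`` (the median facility) to 0 and
    ``anchor_high`` to +1; values outside the anchors clip to the bounds.
    """

    anchor_low: float
    anchor_mid: float
    anchor_high: float

    def __post_init__(self) -> None:
        _require(
            self.anchor_low < self.anchor_mid < self.anchor_high,
            "anchor_mid",
            "anchors must be strictly increasing",
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "anchor_low": self.anchor_low,
                    "anchor_mid": self.anchor_mid,
                    "anchor_high": self.anchor_high,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScalingMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["anchor_low"], doc["anchor_mid"], doc["anchor_high"])


def fit_scaling(records: Sequence[FacilityRecord], field: str) -> ScalingMap:
    """Fit the scaling map for ``raw_quality`` or ``raw_volume``.

    Anchors are the 1st percentile, median and 99th percentile of the field
    (percentile anchors rather than min/max keep the map robust to
    generator outliers).
    """
    if field not in ("raw_quality", "raw_volume"):
        raise InvariantError("field: must be 'raw_quality' or 'raw_volume'")
    values = np.asarray([getattr(r, field) for r in records], dtype=float)
    if len(values) < 2 or np.isclose(values.min(), values.max()):
        raise InvariantError(f"{field}: degenerate range; need at least 2 distinct values")
    low, mid, high = np.percentile(values, [1.0, 50.0, 99.0])
    if not (low < mid < high):
        raise InvariantError(f"{field}: percentile anchors are not strictly increasing")
    return ScalingMap(float(low), float(mid), float(high))


def scale(raw, mapping: ScalingMap):
    """Raw survey value -> unitless stock level in [-1, 1] (clipped)."""
    xp = [mapping.anchor_low, mapping.anchor_mid, mapping.anchor_high]
    result = np.interp(raw, xp, [-1.0, 0.0, 1.0])
    return float(result) if np.isscalar(raw) else result


def unscale(u, mapping: ScalingMap):
    """Unitless stock level -> raw survey value (inverse within the anchors)."""
    fp = [mapping.anchor_low, mapping.anchor_mid, mapping.anchor_high]
    result = np.interp(u, [-1.0, 0.0, 1.0], fp)
    return float(result) if np.isscalar(u) else result
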