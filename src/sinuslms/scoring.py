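"""Lund-Mackay scoring by intensity thresholding and pixel counting.

Given a Hounsfield-scale volume and a sinus label map, each region's
opacification fraction is the share of its voxels whose intensity lies
above a threshold separating air from soft tissue/fluid.  The fraction
maps to the Lund-Mackay sub-score through a fixed step function:

    sub-score 0  iff  fraction < 0.01          (clear)
    sub-score 1  iff  0.01 <= fraction <= 0.95 (partial opacification)
    sub-score 2  iff  fraction > 0.95          (complete opacification)

The band endpoints are inclusive in the middle band, making the three
bands exhaustive and non-overlapping.  Counts are aggregated over all
slices, so the fraction is volume-wide per region.  The threshold is a
fixed cutoff of -300 HU by default (any soft tissue or fluid is well
above it, air well below); an adaptive per-region Otsu option is
available.  An absent (aplastic) region has no opacifiable space and is
scored 0 with an ``absent`` flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ShapeMismatchError
from .imaging import ImageVolume, LabelVolume
from .regions import Region, Side

__all__ = [
    "ThresholdPolicy",
    "OpacificationResult",
    "RegionScore",
    "LMSReport",
    "LundMackayScorer",
    "map_score",
    "opacification",
    "score_volume",
    "resolve_threshold",
]

DEFAULT_CUTOFF_HU = -300.0
SCORE_LOW_BAND = 0.01
SCORE_HIGH_BAND = 0.95


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the air/opacification cutoff is chosen.

    ``fixed_hu`` uses ``fixed_cutoff`` for every region; ``otsu_per_region``
    maximizes between-class variance on each region's own intensity
    histogram.  ``operates_on`` records which intensity scale the policy
    expects; thresholding is meant to run on Hounsfield-scale data (the
    z-scored copy exists only for the network).
    """

    method: str = "fixed_hu"
    fixed_cutoff: float = DEFAULT_CUTOFF_HU
    operates_on: str = "hounsfield"

    def __post_init__(self) -> None:
        if self.method not in ("fixed_hu", "otsu_per_region"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.operates_on == "hounsfield" and not (-1000 <= self.fixed_cutoff <= 1000):
            raise ValueError("fixed_cutoff must lie within [-1000, +1000] HU")


@dataclass
class RegionOpacification:
    region: Region
    total_pixels: int
    opacified_pixels: int
    threshold: float | None

    @property
    def absent(self) -> bool:
        return self.total_pixels == 0

    @property
    def fraction(self) -> float | None:
        if self.absent:
            return None
        return self.opacified_pixels / self.total_pixels


@dataclass
class OpacificationResult:
    """Per-region pixel counts and opacified fractions for one volume."""

    regions: dict[Region, RegionOpacification]

    def fraction(self, region: Region) -> float | None:
        return self.regions[region].fraction


@dataclass
class RegionScore:
    region: Region
    sub_score: int
    absent: bool
    total_pixels: int
    opacified_pixels: int
    fraction: float | None
    threshold: float | None


@dataclass
class LMSReport:
    """Per-region Lund-Mackay sub-scores with side and total sums."""

    scores: dict[Region, RegionScore]

    @property
    def total(self) -> int:
        return sum(s.sub_score for s in self.scores.values())

    def side_total(self, side: Side) -> int:
        return sum(s.sub_score for s in self.scores.values() if s.region.side == side)

    def sub_score(self, region: Region) -> int:
        return self.scores[region].sub_score

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": s.region.name.lower(),
                "side": s.region.side.value,
                "sinus": s.region.sinus.value,
                "total_pixels": s.total_pixels,
                "opacified_pixels": s.opacified_pixels,
                "fraction": np.nan if s.fraction is None else s.fraction,
                "sub_score": s.sub_score,
                "absent": s.absent,
                "threshold_used": np.nan if s.threshold is None else s.threshold,
            }
            for s in self.scores.values()
        ]
        df = pd.DataFrame(rows)
        totals = {
            "region": "TOTAL",
            "side": "",
            "sinus": "",
            "total_pixels": int(df["total_pixels"].sum()),
            "opacified_pixels": int(df["opacified_pixels"].sum()),
            "fraction": np.nan,
            "sub_score": self.total,
            "absent": False,
            "threshold_used": np.nan,
        }
        return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)

    def to_json_dict(self) -> dict:
        return {
            "regions": {
                s.region.name.lower(): {
                    "sub_score": s.sub_score,
                    "absent": s.absent,
                    "total_pixels": s.total_pixels,
                    "opacified_pixels": s.opacified_pixels,
                    "fraction": s.fraction,
                    "threshold_used": s.threshold,
                }
                for s in self.scores.values()
            },
            "side_totals": {
                side.value: self.side_total(side) for side in Side
            },
            "total": self.total,
        }

    def save(self, stem: str | Path) -> tuple[Path, Path]:
        """Write the report as ``<stem>.json`` and ``<stem>.csv``."""
        stem = Path(stem)
        jpath = stem.with_suffix(".json")
        cpath = stem.with_suffix(".csv")
        jpath.write_text(json.dumps(self.to_json_dict(), indent=1))
        self.to_frame().to_csv(cpath, index=False)
        return jpath, cpath


def map_score(fraction: float) -> int:
    """Map an opacification fraction in [0, 1] to a sub-score in {0, 1, 2}."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction < SCORE_LOW_BAND:
        return 0
    if fraction <= SCORE_HIGH_BAND:
        return 1
    return 2


def resolve_threshold(
    vol: ImageVolume,
    labels: LabelVolume,
    region: Region,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> float:
    """Resolve the opacification cutoff for one region under a policy."""
    if policy.method == "fixed_hu":
        return policy.fixed_cutoff
    values = vol.data[labels.data == int(region)]
    if values.size == 0:
        raise ValueError(f"region {region.name} is empty; no threshold defined")
    from skimage.filters import threshold_otsu

    if np.ptp(values) == 0:  # degenerate single-valued region
        return float(values[0])
    return float(threshold_otsu(values))


def opacification(
    vol: ImageVolume,
    labels: LabelVolume,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> OpacificationResult:
    """Count above-threshold (opacified) pixels per region over all slices."""
    if vol.shape != labels.shape:
        raise ShapeMismatchError(
            f"volume shape {vol.shape} != label shape {labels.shape}"
        )
    out: dict[Region, RegionOpacification] = {}
    for region in Region:
        mask = labels.data == int(region)
        total = int(mask.sum())
        if total == 0:
            out[region] = RegionOpacification(region, 0, 0, None)
            continue
        thr = resolve_threshold(vol, labels, region, policy)
        opa = int((vol.data[mask] > thr).sum())
        out[region] = RegionOpacification(region, total, opa, thr)
    return OpacificationResult(out)


def score_volume(
    vol: ImageVolume,
    labels: LabelVolume,
    policy: ThresholdPolicy = ThresholdPolicy(),
    omc_binary: bool = False,
    absent_score: int = 0,
) -> LMSReport:
    """Threshold, count and map every region to its Lund-Mackay sub-score.

    ``omc_binary`` collapses OMC sub-score 1 to 2, matching the clinical
    convention of scoring the ostiomeatal complex on {0, 2}; by default
    one rule applies to all twelve regions.  Absent regions receive
    ``absent_score`` (default 0) and are flagged.
    """
    opac = opacification(vol, labels, policy)
    scores: dict[Region, RegionScore] = {}
    for region, r in opac.regions.items():
        if r.absent:
            scores[region] = RegionScore(
                region, absent_score, True, 0, 0, None, None
            )
            continue
        s = map_score(r.fraction)
        if omc_binary and region.sinus.value == "omc" and s == 1:
            s = 2
        scores[region] = RegionScore(
            region, s, False, r.total_pixels, r.opacified_pixels, r.fraction, r.threshold
        )
    return LMSReport(scores)


class LundMackayScorer(BaseEstimator):
    """Estimator-style front end for threshold/pixel-count LMS scoring.

    The scorer is stateless (no ``fit`` is required); it exists so the
    scoring stage composes with scikit-learn style pipelines and config
    plumbing via ``get_params``/``set_params``.

    Parameters
    ----------
    method : "fixed_hu" or "otsu_per_region"
    fixed_cutoff : HU cutoff used by the fixed policy (default -300)
    omc_binary : score the ostiomeatal complex on {0, 2}
    absent_score : sub-score assigned to aplastic (zero-pixel) regions
    """

    def __init__(
        self,
        method: str = "fixed_hu",
        fixed_cutoff: float = DEFAULT_CUTOFF_HU,
        omc_binary: bool = False,
        absent_score: int = 0,
    ):
        self.method = method
        self.fixed_cutoff = fixed_cutoff
        self.omc_binary = omc_binary
        self.absent_score = absent_score

    @property
    def policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(method=self.method, fixed_cutoff=self.fixed_cutoff)

    def opacification(self, vol: ImageVolume, labels: LabelVolume) -> OpacificationResult:
        return opacification(vol, labels, self.policy)

    def score_volume(self, vol: ImageVolume, labels: LabelVolume) -> LMSReport:
        return score_volume(
            vol,
            labels,
            self.policy,
            omc_binary=self.omc_binary,
            absent_score=self.absent_score,
        )

    def transform(self, X) -> list[LMSReport]:
        """Score an iterable of ``(image_volume, label_volume)`` pairs."""
        return [self.score_volume(vol, labels) for vol, labels in X]
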