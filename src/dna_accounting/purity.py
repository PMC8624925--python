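"""Purity statistic and screening classification.

A sample whose measured copies cm fall inside the calibration prediction
interval [lCe, uCe] at its expected copies ce is indistinguishable from the
pure reference material and gets purity 1.  Outside the interval, purity is
the ratio of cm to the violated bound:

    purity = cm / lCe   if cm < lCe
           = 1          if lCe <= cm <= uCe
           = cm / uCe   if cm > uCe   (continuous at uCe)

Samples are classified "non-suspicious" when purity lies in the inclusive
acceptance band [0.80, 1.20] and "suspicious" otherwise; suspicious samples
are further tiered into a high band (0.70-0.80 or > 1.20) and a low band
(< 0.70), mirroring how strongly the evidence suggests adulteration.

A simplified population screen drops the constant terms and checks the raw
ratio cm / dna_ng against mean +/- z*SD bounds estimated from a population
of authentic samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .calibration import CalibrationModel, prediction_interval

__all__ = [
    "Category",
    "Tier",
    "PurityResult",
    "PopulationRule",
    "ACCEPTANCE_LOW",
    "ACCEPTANCE_HIGH",
    "LOW_BAND_LIMIT",
    "percent_purity",
    "classify",
    "population_rule",
    "screen_by_ratio",
]

ACCEPTANCE_LOW = 0.80
ACCEPTANCE_HIGH = 1.20
LOW_BAND_LIMIT = 0.70

BELOW_QUANTIFICATION_FLAG = "below_quantification_range"


class Category(str, Enum):
    NON_SUSPICIOUS = "non_suspicious"
    SUSPICIOUS = "suspicious"


class Tier(str, Enum):
    WITHIN_INTERVAL = "within_interval"
    WITHIN_ACCEPTANCE = "within_acceptance"
    HIGH_BAND = "high_band"
    LOW_BAND = "low_band"


@dataclass(frozen=True)
class PurityResult:
    """Screening outcome for one sample.

    ``purity`` is a fraction (1 = pure); it is NaN, with category and tier
    unset, when the prediction interval's lower bound had to be clamped and
    the statistic is undefined (sample below the quantification range).
    """

    sample_id: str
    cm: float
    ce: float
    lce: float
    uce: float
    purity: float
    category: Category | None
    tier: Tier | None
    flags: tuple[str, ...] = field(default_factory=tuple)


def classify(purity: float) -> tuple[Category, Tier]:
    """Classify a computed purity fraction into category and tier.

    The acceptance band [0.80, 1.20] is inclusive.  Purity exactly 1 means
    the measurement fell inside the prediction interval.
    """
    if math.isnan(purity) or purity < 0:
        raise ValueError(f"purity must be a number >= 0, got {purity}")
    if ACCEPTANCE_LOW <= purity <= ACCEPTANCE_HIGH:
        category = Category.NON_SUSPICIOUS
        tier = Tier.WITHIN_INTERVAL if purity == 1.0 else Tier.WITHIN_ACCEPTANCE
    else:
        category = Category.SUSPICIOUS
        tier = Tier.LOW_BAND if purity < LOW_BAND_LIMIT else Tier.HIGH_BAND
    return category, tier


def percent_purity(
    cm: float,
    ce: float,
    model: CalibrationModel,
    sample_id: str = "",
    upper_denominator: str = "uce",
) -> PurityResult:
    """Compute the purity statistic for one sample and classify it.

    ``upper_denominator`` selects the denominator of the above-interval
    branch: ``"uce"`` (default) divides by the upper bound, making purity
    continuous (-> 1) as cm approaches the interval from above; ``"lce"``
    divides by the lower bound in both outer branches, an alternative
    reading that inflates above-interval purity but never changes which
    side of the acceptance band a sample falls on.
    """
    if upper_denominator not in ("uce", "lce"):
        raise ValueError("upper_denominator must be 'uce' or 'lce'")
    if cm < 0:
        raise ValueError(f"cm must be >= 0, got {cm}")
    interval = prediction_interval(model, ce)
    flags: tuple[str, ...] = ()
    if interval.clamped:
        # purity would divide by an arbitrary clamp value; refuse to quantify
        return PurityResult(
            sample_id=sample_id,
            cm=cm,
            ce=ce,
            lce=interval.lower,
            uce=interval.upper,
            purity=float("nan"),
            category=None,
            tier=None,
            flags=(BELOW_QUANTIFICATION_FLAG,),
        )
    if cm < interval.lower:
        purity = cm / interval.lower
    elif cm <= interval.upper:
        purity = 1.0
    else:
        denom = interval.upper if upper_denominator == "uce" else interval.lower
        purity = cm / denom
    category, tier = classify(purity)
    return PurityResult(
        sample_id=sample_id,
        cm=cm,
        ce=ce,
        lce=interval.lower,
        uce=interval.upper,
        purity=purity,
        category=category,
        tier=tier,
        flags=flags,
    )


@dataclass(frozen=True)
class PopulationRule:
    """Copies-per-ng acceptance range from an authentic-sample population."""

    mean_cpn: float
    sd_cpn: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if not (self.sd_cpn > 0):
            raise ValueError("sd_cpn must be > 0")
        if self.z < 0:
            raise ValueError("z must be >= 0")

    @property
    def low(self) -> float:
        return self.mean_cpn - self.z * self.sd_cpn

    @property
    def high(self) -> float:
        return self.mean_cpn + self.z * self.sd_cpn


def population_rule(mean_cpn: float, sd_cpn: float, z: float = 1.96) -> PopulationRule:
    """Build a mean +/- z*SD copies-per-ng screening rule.

    With z = 1.96 the rule covers ~95% of a normal population of authentic
    samples.  The rule must be verified in-house against authentic material
    before use; no default population values are shipped.
    """
    return PopulationRule(mean_cpn=mean_cpn, sd_cpn=sd_cpn, z=z)


def screen_by_ratio(
    cm: float, dna_ng: float, rule: PopulationRule
) -> tuple[bool, float]:
    """Simplified screen: is cm/dna_ng inside the population range (inclusive)?

    Returns ``(passed, ratio)``.
    """
    if not (dna_ng > 0):
        raise ValueError(f"dna_ng must be > 0, got {dna_ng}")
    ratio = cm / dna_ng
    return rule.low <= ratio <= rule.high, ratio
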