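"""Droplet digital PCR quantification.

A ddPCR reaction splits the sample volume Vs into ~20,000 droplets of
volume Vp.  If target molecules land in droplets independently, droplet
occupancy is Poisson and the mean copies per droplet is estimated from the
fraction of negative droplets:

    lambda_hat = -ln((total - positives) / total)

which is the maximum-likelihood estimate under the binomial likelihood with
positive probability 1 - exp(-lambda).  The total measured copies in the
reaction are then cm = lambda * Vs / Vp.

The module also provides a deliberately minimal amplitude-threshold droplet
caller (two-means split of the amplitude distribution) and Poisson-exact
pooling of replicate wells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DropletCount",
    "PartitionConfig",
    "LambdaEstimate",
    "SaturatedWellError",
    "estimate_lambda",
    "measured_copies",
    "call_droplets",
    "merge_replicates",
]


class SaturatedWellError(ValueError):
    """All droplets positive: lambda is unbounded; re-run at higher dilution."""


@dataclass(frozen=True)
class PartitionConfig:
    """Reaction partitioning geometry.

    Defaults are the QX200 droplet generator: droplet (partition) volume
    Vp = 0.00085 uL and sample volume Vs = 20 uL.
    """

    partition_volume_ul: float = 0.00085
    sample_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if not (self.partition_volume_ul > 0):
            raise ValueError("partition_volume_ul must be > 0")
        if not (self.sample_volume_ul > 0):
            raise ValueError("sample_volume_ul must be > 0")
        if self.sample_volume_ul / self.partition_volume_ul <= 1:
            raise ValueError("sample volume must exceed the partition volume")


@dataclass(frozen=True)
class DropletCount:
    """Counted droplets for one well: positives out of total, plus the
    template mass (ng) loaded into the reaction."""

    well_id: str
    sample_id: str
    positives: int
    total: int
    dna_ng: float = float("nan")

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"well {self.well_id}: total droplets must be > 0")
        if not (0 <= self.positives <= self.total):
            raise ValueError(
                f"well {self.well_id}: positives={self.positives} outside "
                f"[0, total={self.total}]"
            )

    @property
    def saturated(self) -> bool:
        return self.positives == self.total


@dataclass(frozen=True)
class LambdaEstimate:
    """Point estimate and confidence interval for mean copies per droplet."""

    lam: float
    ci_low: float
    ci_high: float
    saturated: bool = False


def estimate_lambda(count: DropletCount, confidence: float = 0.95) -> LambdaEstimate:
    """Estimate lambda (mean target copies per droplet) from counts.

    The point estimate is the Poisson MLE -ln(negatives/total).  The
    interval is a normal approximation on the negative fraction mapped
    through -ln and clipped at zero; it is adequate at the >= 10^4 droplets
    typical of a well.  A fully positive well returns a saturated estimate
    (lam = inf) that downstream conversion refuses.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    t = count.total
    if count.saturated:
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        # even at p_neg_hat = 0 the negative fraction could plausibly be as
        # high as ~z^2/t; everything above is unbounded
        p_hi = min(1.0, z * z / t)
        lo = -math.log(p_hi) if p_hi > 0 else math.inf
        return LambdaEstimate(lam=math.inf, ci_low=lo, ci_high=math.inf, saturated=True)
    p_neg = (t - count.positives) / t
    lam = -math.log(p_neg)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    se = math.sqrt(p_neg * (1.0 - p_neg) / t)
    p_lo = max(p_neg - z * se, math.ulp(0.0))
    p_hi = min(p_neg + z * se, 1.0)
    ci_low = max(0.0, -math.log(p_hi))
    ci_high = -math.log(p_lo)
    return LambdaEstimate(lam=lam, ci_low=ci_low, ci_high=ci_high, saturated=False)


def measured_copies(lam: float, cfg: PartitionConfig = PartitionConfig()) -> float:
    """Total measured copies in the reaction: cm = lambda * Vs / Vp."""
    if not math.isfinite(lam):
        raise SaturatedWellError(
            "lambda is saturated/non-finite; dilute the sample and re-run"
        )
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return lam * cfg.sample_volume_ul / cfg.partition_volume_ul


def _two_means_split(amplitudes: np.ndarray) -> tuple[float, float, float]:
    """1-D two-means clustering (Lloyd, deterministic min/max init).

    Returns (low_center, high_center, threshold at the midpoint).
    """
    lo, hi = float(amplitudes.min()), float(amplitudes.max())
    c0, c1 = lo, hi
    for _ in range(200):
        mid = 0.5 * (c0 + c1)
        low_mask = amplitudes <= mid
        if low_mask.all() or not low_mask.any():
            break
        n0 = float(amplitudes[low_mask].mean())
        n1 = float(amplitudes[~low_mask].mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return c0, c1, 0.5 * (c0 + c1)


def call_droplets(
    amplitudes: "np.ndarray | list[float]", threshold: float | None = None
) -> tuple[int, int]:
    """Call droplets positive/negative from fluorescence amplitudes.

    With an explicit ``threshold``, a droplet is positive iff its amplitude
    is strictly greater than the threshold.  With ``threshold=None`` the
    threshold is placed at the midpoint of a deterministic two-means split
    of the amplitudes; if the two clusters are not separated (unimodal
    distribution) a warning is raised and all droplets are called negative.

    Returns ``(positives, total)``.  This is plumbing only — production
    droplet calling should use a dedicated rain-aware algorithm.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.ndim != 1 or amps.size < 100:
        raise ValueError("need a flat array of at least 100 droplet amplitudes")
    total = int(amps.size)
    if threshold is None:
        c0, c1, thr = _two_means_split(amps)
        low = amps[amps <= thr]
        high = amps[amps > thr]
        spread = max(
            float(low.std()) if low.size > 1 else 0.0,
            float(high.std()) if high.size > 1 else 0.0,
        )
        if high.size == 0 or (c1 - c0) < 4.0 * spread:
            warnings.warn(
                "amplitude distribution looks unimodal; calling all droplets "
                "negative — set an explicit threshold to override",
                stacklevel=2,
            )
            return 0, total
        threshold = thr
    positives = int(np.count_nonzero(amps > threshold))
    return positives, total


def merge_replicates(counts: list[DropletCount]) -> DropletCount:
    """Pool replicate wells of one sample by summing droplet counts.

    Summing positives and totals (rather than averaging per-well lambda
    estimates) preserves the Poisson likelihood: the pooled MLE is the MLE
    of the combined counts.  Saturated wells cannot be pooled.
    """
    if not counts:
        raise ValueError("no wells to merge")
    sample_ids = {c.sample_id for c in counts}
    if len(sample_ids) != 1:
        raise ValueError(f"cannot merge wells from different samples: {sorted(sample_ids)}")
    for c in counts:
        if c.saturated:
            raise SaturatedWellError(
                f"well {c.well_id} is saturated; exclude it or dilute and re-run"
            )
    dna_vals = [c.dna_ng for c in counts if not math.isnan(c.dna_ng)]
    return DropletCount(
        well_id="+".join(c.well_id for c in counts),
        sample_id=counts[0].sample_id,
        positives=sum(c.positives for c in counts),
        total=sum(c.total for c in counts),
        dna_ng=float(np.mean(dna_vals)) if dna_vals else float("nan"),
    )
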