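"""High-level pipeline steps: counts -> calibration points -> purity results.

These functions tie the per-well Poisson quantification, the genome
forecast and the WLS calibration together the way the command-line
interface uses them, and are the natural entry points for scripted use.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Sequence

from .calibration import CalibrationModel, CalibrationPoint, fit_calibration
from .ddpcr import DropletCount, PartitionConfig, estimate_lambda, measured_copies, merge_replicates
from .genome import SpeciesGenomeParams, expected_copies
from .purity import PopulationRule, PurityResult, percent_purity, screen_by_ratio

__all__ = [
    "pool_by_sample",
    "quantify_sample",
    "build_calibration_points",
    "calibrate_from_counts",
    "screen_samples",
    "ratio_screen_samples",
]


def pool_by_sample(counts: Sequence[DropletCount]) -> list[DropletCount]:
    """Merge replicate wells per sample (insertion order preserved)."""
    groups: dict[str, list[DropletCount]] = defaultdict(list)
    for c in counts:
        groups[c.sample_id].append(c)
    return [merge_replicates(wells) for wells in groups.values()]


def quantify_sample(
    pooled: DropletCount, partition: PartitionConfig = PartitionConfig()
) -> float:
    """Measured copies cm for one (pooled) well."""
    return measured_copies(estimate_lambda(pooled).lam, partition)


def build_calibration_points(
    counts: Sequence[DropletCount],
    params: SpeciesGenomeParams,
    partition: PartitionConfig = PartitionConfig(),
) -> list[CalibrationPoint]:
    """Pool replicates, quantify, and forecast to form (ce, cm) pairs."""
    points = []
    for pooled in pool_by_sample(counts):
        if math.isnan(pooled.dna_ng):
            raise ValueError(f"sample {pooled.sample_id}: dna_ng is missing")
        ce = expected_copies(pooled.dna_ng, params)
        points.append(
            CalibrationPoint(ce=ce, cm=quantify_sample(pooled, partition), sample_id=pooled.sample_id)
        )
    return points


def calibrate_from_counts(
    counts: Sequence[DropletCount],
    params: SpeciesGenomeParams,
    partition: PartitionConfig = PartitionConfig(),
    variance_power: float = 2.0,
    through_origin: bool = False,
    level: float = 0.95,
) -> CalibrationModel:
    """Full calibration step from raw well counts of pure reference samples."""
    return fit_calibration(
        build_calibration_points(counts, params, partition),
        variance_power=variance_power,
        through_origin=through_origin,
        level=level,
    )


def screen_samples(
    counts: Sequence[DropletCount],
    model: CalibrationModel,
    params: SpeciesGenomeParams,
    partition: PartitionConfig = PartitionConfig(),
    upper_denominator: str = "uce",
) -> list[PurityResult]:
    """Screen samples against a fitted calibration model."""
    results = []
    for pooled in pool_by_sample(counts):
        if math.isnan(pooled.dna_ng):
            raise ValueError(f"sample {pooled.sample_id}: dna_ng is missing")
        ce = expected_copies(pooled.dna_ng, params)
        cm = quantify_sample(pooled, partition)
        results.append(
            percent_purity(
                cm, ce, model, sample_id=pooled.sample_id, upper_denominator=upper_denominator
            )
        )
    return results


def ratio_screen_samples(
    counts: Sequence[DropletCount],
    rule: PopulationRule,
    partition: PartitionConfig = PartitionConfig(),
) -> list[tuple[str, bool, float]]:
    """Simplified copies-per-ng screen; returns (sample_id, passed, ratio)."""
    out = []
    for pooled in pool_by_sample(counts):
        cm = quantify_sample(pooled, partition)
        passed, ratio = screen_by_ratio(cm, pooled.dna_ng, rule)
        out.append((pooled.sample_id, passed, ratio))
    return out
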