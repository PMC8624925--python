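"""Synthetic ddPCR experiment generator.

Emulates the data-generating process the screening method assumes, so every
pipeline stage is testable without instrument exports:

* **Partitioning** — target molecules distribute over droplets as Poisson;
  the number of positive droplets is Binomial(n_droplets, 1 - exp(-lambda)).
* **Fluorometry** — the template mass entering the expected-copies forecast
  is measured with multiplicative lognormal error; several reads per sample
  are averaged, as fluorometric DNA quantification protocols do.
* **Pipetting** — the mass actually loaded into the reaction carries its own
  multiplicative lognormal error, independent of the measured mass.
* **Admixture** — a bulking agent at w/w mass fraction w with DNA
  extractability r relative to the authentic species dilutes the
  target-bearing template to a fraction f = (1-w) / ((1-w) + w*r); by
  assumption the adulterant carries no target sequence.
* **Market population** — authentic samples vary in true copies-per-ng,
  modelled as a normal distribution truncated at zero.

Multiplicative noise placement is deliberate: it produces exactly the
copy-number-proportional residual spread (constant CV) that the weighted
calibration step exists to handle.  All randomness flows from a single
seed; identical configurations give identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddpcr import DropletCount, PartitionConfig
from .genome import SpeciesGenomeParams, copies_per_ng

__all__ = [
    "SimulationConfig",
    "AdmixtureSpec",
    "ADULTERANT_PRESETS",
    "simulate_fluorometry",
    "simulate_reaction",
    "simulate_amplitudes",
    "simulate_admixture",
    "simulate_market",
    "MarketSimulation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Noise and geometry parameters of a simulated ddPCR experiment.

    Defaults describe a routine screening run: 15,000 accepted droplets per
    well, fluorometric quantification with 5% per-read CV averaged over four
    reads, 3% pipetting CV, ~0.5% rain, and 5-15 ng template per reaction.
    """

    seed: int = 0
    n_droplets: int = 15000
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    fluorometry_cv: float = 0.05
    fluorometry_reads: int = 4
    pipetting_cv: float = 0.03
    rain_fraction: float = 0.005
    dna_ng_range: tuple[float, float] = (5.0, 15.0)

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        for name in ("fluorometry_cv", "pipetting_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.rain_fraction < 1):
            raise ValueError("rain_fraction must be in [0, 1)")
        if self.fluorometry_reads < 1:
            raise ValueError("fluorometry_reads must be >= 1")
        lo, hi = self.dna_ng_range
        if not (0 < lo <= hi):
            raise ValueError("dna_ng_range must satisfy 0 < low <= high")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class AdmixtureSpec:
    """A bulking scenario: mass fraction w of an adulterant whose DNA yield
    per mg is ``extractability_ratio`` times the authentic species' yield."""

    w_adulterant: float
    extractability_ratio: float = 1.0
    adulterant_has_target: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.w_adulterant <= 1):
            raise ValueError("w_adulterant must be in [0, 1]")
        if not (self.extractability_ratio > 0):
            raise ValueError("extractability_ratio must be > 0")

    @property
    def template_fraction(self) -> float:
        """Fraction of extracted template that carries the target."""
        if self.adulterant_has_target:
            return 1.0
        w, r = self.w_adulterant, self.extractability_ratio
        denom = (1.0 - w) + w * r
        return (1.0 - w) / denom if denom > 0 else 0.0


#: Illustrative extractability ratios for classic saffron bulking agents.
#: These are plausible round numbers for testing scenarios, not measured
#: yields: safflower extracts at least as well as saffron, wheat flour about
#: equally, Capsicum poorly.
ADULTERANT_PRESETS: dict[str, float] = {
    "safflower": 20.0,
    "wheat": 1.0,
    "capsicum": 0.3,
}


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size: "int | tuple[int, ...] | None" = None
) -> "float | np.ndarray":
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_fluorometry(
    true_ng_per_ul: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Fluorometric concentration estimate: mean of noisy repeated reads."""
    if true_ng_per_ul < 0:
        raise ValueError("true concentration must be >= 0")
    if true_ng_per_ul == 0:
        return 0.0
    rng = cfg.rng() if rng is None else rng
    factors = _lognormal_factor(rng, cfg.fluorometry_cv, size=cfg.fluorometry_reads)
    return float(true_ng_per_ul * np.mean(factors))


def simulate_reaction(
    true_copies_per_ng: float,
    dna_ng: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    well_id: str = "A01",
    sample_id: str = "sim",
) -> DropletCount:
    """Simulate one ddPCR well.

    The true per-droplet rate is lambda = copies * Vp / Vs with copies =
    ``true_copies_per_ng`` times the pipetted template mass (the nominal
    ``dna_ng`` with pipetting noise).  Positive droplets are binomial with
    success probability 1 - exp(-lambda).  The returned record's ``dna_ng``
    is the fluorometry-*measured* mass, so a downstream expected-copies
    forecast carries realistic quantification error.
    """
    if true_copies_per_ng < 0:
        raise ValueError("true_copies_per_ng must be >= 0")
    if not (dna_ng > 0):
        raise ValueError("dna_ng must be > 0")
    rng = cfg.rng() if rng is None else rng
    pipetted_ng = dna_ng * float(_lognormal_factor(rng, cfg.pipetting_cv))
    copies = true_copies_per_ng * pipetted_ng
    lam = copies * cfg.partition.partition_volume_ul / cfg.partition.sample_volume_ul
    if lam >= math.log(cfg.n_droplets):
        warnings.warn(
            f"true lambda {lam:.2f} is near saturation for {cfg.n_droplets} "
            "droplets; expect all-positive wells",
            stacklevel=2,
        )
    positives = int(rng.binomial(cfg.n_droplets, -math.expm1(-lam)))
    measured_ng = simulate_fluorometry(dna_ng, cfg, rng)
    return DropletCount(
        well_id=well_id,
        sample_id=sample_id,
        positives=positives,
        total=cfg.n_droplets,
        dna_ng=measured_ng,
    )


def simulate_amplitudes(
    n_positive: int,
    n_total: int,
    rng: np.random.Generator,
    rain_fraction: float = 0.005,
    negative_mode: float = 1000.0,
    positive_mode: float = 9000.0,
) -> np.ndarray:
    """Fluorescence amplitudes for a well: two Gaussian clusters plus a
    uniform 'rain' smear between them.  Rain droplets are drawn from the
    positive pool (partially amplified targets)."""
    if not (0 <= n_positive <= n_total):
        raise ValueError("need 0 <= n_positive <= n_total")
    n_rain = int(round(rain_fraction * n_positive))
    n_pos = n_positive - n_rain
    n_neg = n_total - n_positive
    neg = rng.normal(negative_mode, 0.05 * negative_mode, size=n_neg)
    pos = rng.normal(positive_mode, 0.04 * positive_mode, size=n_pos)
    rain = rng.uniform(
        negative_mode + 3 * 0.05 * negative_mode,
        positive_mode - 3 * 0.04 * positive_mode,
        size=n_rain,
    )
    amps = np.concatenate([neg, pos, rain])
    rng.shuffle(amps)
    return amps


def simulate_admixture(
    spec: AdmixtureSpec,
    params: SpeciesGenomeParams,
    dna_ng: float,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    true_copies_per_ng: float | None = None,
    well_id: str = "A01",
    sample_id: str = "admix",
) -> DropletCount:
    """Simulate a well of authentic material bulked with an adulterant.

    Only the fraction f = (1-w)/((1-w) + w*r) of the extracted template
    carries the target, so the effective copies-per-ng is f times the pure
    value.  ``true_copies_per_ng`` overrides the genome forecast for the
    pure material when the simulated population differs from the ideal.
    """
    cpn_pure = (
        copies_per_ng(params) if true_copies_per_ng is None else true_copies_per_ng
    )
    effective = spec.template_fraction * cpn_pure
    return simulate_reaction(
        effective, dna_ng, cfg, rng=rng, well_id=well_id, sample_id=sample_id
    )


@dataclass(frozen=True)
class MarketSimulation:
    """Simulated sample set: per-well droplet counts plus a ground-truth
    table (`sample_id, true_ratio, true_w, true_lambda, true_dna_ng`)."""

    counts: list[DropletCount]
    truth: pd.DataFrame


def simulate_market(
    n_samples: int,
    population_mean_cpn: float,
    population_cv: float,
    cfg: SimulationConfig,
    n_replicates: int = 2,
    admixture: AdmixtureSpec | None = None,
    log_uniform_dna: bool = True,
    sample_prefix: str = "S",
) -> MarketSimulation:
    """Simulate a population of samples, each run in replicate wells.

    Each sample draws a true copies-per-ng ratio from a normal distribution
    (mean ``population_mean_cpn``, CV ``population_cv``) truncated at zero,
    and a template mass from ``cfg.dna_ng_range`` (log-uniform by default,
    mimicking independent extracts and serial dilutions).  With an
    ``admixture`` spec every sample is bulked identically; the ground-truth
    table records the adulterant fraction.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if population_cv < 0:
        raise ValueError("population_cv must be >= 0")
    rng = cfg.rng()
    lo, hi = cfg.dna_ng_range
    frac = admixture.template_fraction if admixture is not None else 1.0
    w_true = admixture.w_adulterant if admixture is not None else 0.0

    counts: list[DropletCount] = []
    truth_rows = []
    width = len(str(n_samples))
    for i in range(n_samples):
        sample_id = f"{sample_prefix}{i + 1:0{width}d}"
        ratio = -1.0
        while ratio <= 0:  # truncate the population at zero
            ratio = rng.normal(population_mean_cpn, population_cv * population_mean_cpn)
            if population_cv == 0:
                ratio = population_mean_cpn
        if log_uniform_dna and hi > lo:
            dna_true = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        else:
            dna_true = rng.uniform(lo, hi)
        effective = frac * ratio
        lam_true = (
            effective
            * dna_true
            * cfg.partition.partition_volume_ul
            / cfg.partition.sample_volume_ul
        )
        for rep in range(n_replicates):
            counts.append(
                simulate_reaction(
                    effective,
                    dna_true,
                    cfg,
                    rng=rng,
                    well_id=f"{sample_id}-w{rep + 1}",
                    sample_id=sample_id,
                )
            )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "true_ratio": ratio,
                "true_w": w_true,
                "true_lambda": lam_true,
                "true_dna_ng": dna_true,
            }
        )
    return MarketSimulation(counts=counts, truth=pd.DataFrame(truth_rows))


def with_noise_off(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of a config with all continuous noise sources silenced (the
    binomial partitioning remains — it is the measurement itself)."""
    return replace(cfg, fluorometry_cv=0.0, pipetting_cv=0.0, rain_fraction=0.0)
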