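"""Genome copy-number forecasting.

Converts a DNA template mass into the number of target-gene copies expected
in a PCR reaction, given the species' genome parameters: the monoploid
genome weight (1C, in picograms), the ploidy (x) and the number of target
copies per monoploid genome (n).  The forecast is

    ce = dna_ng * 1000 * n * (x / 2) / C1

i.e. mass in pg divided by the weight of one diploid-equivalent genome,
scaled by how many target copies that genome carries.

The built-in species entry is saffron crocus (*Crocus sativus*): a triploid
with a monoploid genome weight of 7.87 pg whose target marker sits on only
two of the three subgenomes, hence n = 2/3 copies per monoploid genome.
Those parameters forecast ~127 target copies per ng of template.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Union

__all__ = [
    "SpeciesGenomeParams",
    "SAFFRON",
    "expected_copies",
    "copies_per_ng",
    "SpeciesRegistry",
    "load_species_config",
]

RationalLike = Union[int, float, str, Fraction]


def _as_fraction(value: RationalLike) -> Fraction:
    """Parse a copy-number value, accepting exact fraction strings like "2/3"."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, str):
        return Fraction(value.strip())
    return Fraction(value)


@dataclass(frozen=True)
class SpeciesGenomeParams:
    """Genome parameters of one species.

    Parameters
    ----------
    species_name:
        Free-text species label used as the registry key.
    n_target_copies:
        Target copies per monoploid genome.  Stored as an exact
        :class:`fractions.Fraction`; strings like ``"2/3"`` are accepted.
    ploidy:
        Number of chromosome-set copies per nucleus (x >= 1).
    monoploid_weight_pg:
        Monoploid genome weight (1C) in picograms, > 0.
    """

    species_name: str
    n_target_copies: Fraction
    ploidy: int
    monoploid_weight_pg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_target_copies", _as_fraction(self.n_target_copies))
        if self.n_target_copies < 0:
            raise ValueError("n_target_copies must be >= 0")
        if int(self.ploidy) != self.ploidy or self.ploidy < 1:
            raise ValueError("ploidy must be an integer >= 1")
        object.__setattr__(self, "ploidy", int(self.ploidy))
        if not (self.monoploid_weight_pg > 0):
            raise ValueError("monoploid_weight_pg must be > 0")


#: Saffron crocus defaults: triploid, 1C = 7.87 pg, marker on 2 of 3 subgenomes.
SAFFRON = SpeciesGenomeParams(
    species_name="Crocus sativus",
    n_target_copies=Fraction(2, 3),
    ploidy=3,
    monoploid_weight_pg=7.87,
)


def expected_copies(dna_ng: float, params: SpeciesGenomeParams) -> float:
    """Forecast the target copies (ce) in a reaction with ``dna_ng`` ng of template.

    ce = dna_ng * 1000 * n * (x/2) / C1, linear in the template mass.
    The factor 1000 converts ng to pg; x/2 converts the per-monoploid copy
    count and weight to the per-nucleus scale relative to a diploid reference.
    """
    if dna_ng < 0:
        raise ValueError(f"dna_ng must be >= 0, got {dna_ng}")
    return float(dna_ng) * 1000.0 * float(params.n_target_copies) * params.ploidy / (
        2.0 * params.monoploid_weight_pg
    )


def copies_per_ng(params: SpeciesGenomeParams) -> float:
    """Forecast target copies per nanogram of template (ce at 1 ng)."""
    return expected_copies(1.0, params)


@dataclass
class SpeciesRegistry:
    """Mutable name -> parameters mapping with saffron built in."""

    _entries: dict[str, SpeciesGenomeParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._entries.setdefault(SAFFRON.species_name, SAFFRON)

    def add(self, params: SpeciesGenomeParams) -> None:
        self._entries[params.species_name] = params

    def get(self, species_name: str) -> SpeciesGenomeParams:
        try:
            return self._entries[species_name]
        except KeyError:
            known = ", ".join(sorted(self._entries))
            raise KeyError(
                f"unknown species {species_name!r}; known species: {known}"
            ) from None

    def __contains__(self, species_name: str) -> bool:
        return species_name in self._entries

    def names(self) -> list[str]:
        return sorted(self._entries)


_CONFIG_FIELDS = ("species", "n_target_copies", "ploidy", "monoploid_weight_pg")


def load_species_config(path: Union[str, Path]) -> SpeciesRegistry:
    """Load a species parameter file into a registry.

    The file is CSV with header ``species,n_target_copies,ploidy,
    monoploid_weight_pg`` and one row per species.  ``n_target_copies``
    accepts exact rational strings (``2/3``) as well as integers and
    decimals; parsing is exact (no float round-trip for fractions).
    """
    registry = SpeciesRegistry()
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty species config")
        missing = [f for f in _CONFIG_FIELDS if f not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                registry.add(
                    SpeciesGenomeParams(
                        species_name=row["species"].strip(),
                        n_target_copies=_as_fraction(row["n_target_copies"]),
                        ploidy=int(row["ploidy"]),
                        monoploid_weight_pg=float(row["monoploid_weight_pg"]),
                    )
                )
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
    return registry
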