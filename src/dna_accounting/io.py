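"""CSV readers/writers for droplet counts, sample sheets and reports.

The package defines its own minimal dialects rather than parsing vendor
exports verbatim (vendor formats are version-unstable); a thin adapter maps
the common vendor column names onto the dialect.

Droplet CSV dialect (UTF-8, decimal point, one row per well)::

    well,sample_id,positives,total,dna_ng

Sample sheet dialect::

    sample_id,dna_ng,wells        # wells: semicolon-separated well ids

Report CSV::

    sample_id,cm,ce,lCe,uCe,purity_pct,category,tier,flags
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .ddpcr import DropletCount
from .purity import PurityResult

__all__ = [
    "read_droplet_csv",
    "write_droplet_csv",
    "read_sample_sheet",
    "apply_sample_sheet",
    "read_amplitude_csv",
    "write_report",
    "summarize",
]

DROPLET_COLUMNS = ["well", "sample_id", "positives", "total", "dna_ng"]

#: Vendor export column names accepted by the adapter.
_VENDOR_ALIASES = {
    "Well": "well",
    "Sample": "sample_id",
    "Sample description 1": "sample_id",
    "Positives": "positives",
    "Negatives": "_negatives",
    "AcceptedDroplets": "total",
    "Accepted Droplets": "total",
}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns={k: v for k, v in _VENDOR_ALIASES.items() if k in df.columns})
    if "total" not in df.columns and "_negatives" in df.columns and "positives" in df.columns:
        df["total"] = df["positives"] + df["_negatives"]
    return df.drop(columns=[c for c in df.columns if c.startswith("_")])


def read_droplet_csv(path: Union[str, Path]) -> list[DropletCount]:
    """Read per-well droplet counts, validating every row.

    Errors name the offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no records")
    df = _normalize_columns(df)
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns and c != "dna_ng"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "dna_ng" not in df.columns:
        df["dna_ng"] = np.nan
    counts = []
    for idx, row in df.iterrows():
        rowno = idx + 2
        try:
            positives = int(row["positives"])
            total = int(row["total"])
            dna = float(row["dna_ng"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {rowno}: non-numeric value ({exc})") from exc
        try:
            counts.append(
                DropletCount(
                    well_id=str(row["well"]),
                    sample_id=str(row["sample_id"]),
                    positives=positives,
                    total=total,
                    dna_ng=dna,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {rowno}: {exc}") from exc
    return counts


def write_droplet_csv(counts: Sequence[DropletCount], path: Union[str, Path]) -> None:
    """Write droplet counts in the package dialect (round-trips exactly)."""
    df = pd.DataFrame(
        {
            "well": [c.well_id for c in counts],
            "sample_id": [c.sample_id for c in counts],
            "positives": [c.positives for c in counts],
            "total": [c.total for c in counts],
            "dna_ng": [repr(c.dna_ng) for c in counts],
        }
    )
    df.to_csv(path, index=False)


def read_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample sheet: unique sample ids, template masses, well lists."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sample_id", "dna_ng"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    if (df["dna_ng"] <= 0).any():
        raise ValueError(f"{path}: dna_ng must be > 0 for every sample")
    if "wells" in df.columns:
        df["wells"] = df["wells"].fillna("").map(
            lambda s: [w for w in str(s).split(";") if w]
        )
    return df


def apply_sample_sheet(
    counts: Sequence[DropletCount], sheet: pd.DataFrame
) -> list[DropletCount]:
    """Attach sample-sheet template masses to droplet records.

    Every well listed in the sheet must exist in the droplet data; droplet
    rows for samples absent from the sheet keep their own ``dna_ng``.
    """
    known_wells = {c.well_id for c in counts}
    dna_by_sample = dict(zip(sheet["sample_id"].astype(str), sheet["dna_ng"]))
    if "wells" in sheet.columns:
        for _, row in sheet.iterrows():
            missing = [w for w in row["wells"] if w not in known_wells]
            if missing:
                raise ValueError(
                    f"sample {row['sample_id']}: wells {missing} not in droplet data"
                )
    out = []
    for c in counts:
        dna = dna_by_sample.get(c.sample_id, c.dna_ng)
        out.append(
            DropletCount(
                well_id=c.well_id,
                sample_id=c.sample_id,
                positives=c.positives,
                total=c.total,
                dna_ng=float(dna),
            )
        )
    return out


def read_amplitude_csv(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read per-droplet fluorescence amplitudes grouped by well
    (columns ``well,amplitude``)."""
    df = pd.read_csv(path)
    if not {"well", "amplitude"}.issubset(df.columns):
        raise ValueError(f"{path}: amplitude CSV needs columns well,amplitude")
    return {
        str(well): grp["amplitude"].to_numpy(dtype=float)
        for well, grp in df.groupby("well", sort=True)
    }


def _sig4(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return f"{x:.4g}"


def results_frame(results: Sequence[PurityResult]) -> pd.DataFrame:
    """Purity results as a DataFrame in report column order."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "cm": [_sig4(r.cm) for r in results],
            "ce": [_sig4(r.ce) for r in results],
            "lCe": [_sig4(r.lce) for r in results],
            "uCe": [_sig4(r.uce) for r in results],
            "purity_pct": [_sig4(r.purity * 100.0) for r in results],
            "category": [r.category.value if r.category else "NA" for r in results],
            "tier": [r.tier.value if r.tier else "NA" for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )


def summarize(results: Sequence[PurityResult]) -> str:
    """One-line category tally, e.g. ``"2 non-suspicious / 1 suspicious"``."""
    from .purity import Category

    n_ok = sum(1 for r in results if r.category is Category.NON_SUSPICIOUS)
    n_sus = sum(1 for r in results if r.category is Category.SUSPICIOUS)
    line = f"{n_ok} non-suspicious / {n_sus} suspicious"
    n_flagged = sum(1 for r in results if r.category is None)
    if n_flagged:
        line += f" / {n_flagged} not quantifiable"
    return line


def write_report(results: Sequence[PurityResult], path: Union[str, Path]) -> str:
    """Write the screening report CSV; returns the summary line.

    Deterministic column order, purity formatted as a percentage to four
    significant digits; re-running on the same input yields a byte-identical
    file.
    """
    if not results:
        raise ValueError("no results to report")
    results_frame(results).to_csv(path, index=False)
    return summarize(results)
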