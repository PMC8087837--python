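"""Feature-table IO, sample identifiers, and the abundance time series."""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    CLASS_COLUMN,
    DATE_COLUMN,
    LabeledDataset,
    TANK_COLUMN,
)
from .errors import MissingFeatureError
from .particles import FEATURE_NAMES
from . import reference

#: Labels excluded from the colonial denominator of the abundance table
#: (colony remnants and dispersed non-colonial forms are triaged out of
#: the morphospecies composition, as is anything left unclassified).
EXCLUDED_LABELS = ("Membrane", "Undefined", "unclassified")


def parse_sample_date(text: str) -> _dt.date:
    """Parse a sample date; accepts ISO-8601 or DD/MM/YYYY."""
    text = str(text).strip()
    for fmt in ("%Y-%m-%d", "%d/%m/%Y"):
        try:
            return _dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable sample date {text!r}")


def make_sample_id(tank: str, date) -> str:
    """Canonical ``tank_date`` sample identifier (ISO date)."""
    if not isinstance(date, _dt.date):
        date = parse_sample_date(date)
    return f"{tank}_{date.isoformat()}"


def split_sample_id(sample_id: str) -> tuple[str, _dt.date]:
    """Inverse of :func:`make_sample_id`."""
    tank, _, date = sample_id.partition("_")
    if not date:
        raise ValueError(f"malformed sample id {sample_id!r}")
    return tank, parse_sample_date(date)


def write_feature_table(dataset: LabeledDataset, path) -> None:
    """Write the dataset as CSV, one row per particle.

    Columns are the ten particle properties named exactly as in the
    property catalogue, plus any id/class/tank/date metadata and unknown
    extra columns, which are preserved verbatim.  Floats are written at
    full precision so a write/read cycle is value-exact.
    """
    dataset.table.to_csv(path, index=False)


def read_feature_table(path) -> LabeledDataset:
    """Read a feature-table CSV written by this package (or compatible).

    Raises :class:`MissingFeatureError` naming any absent feature column
    and reports unparseable numeric cells with their row number.
    """
    table = pd.read_csv(path, dtype={CLASS_COLUMN: str})
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise MissingFeatureError(
            f"feature column(s) missing: {', '.join(missing)}"
        )
    for col in FEATURE_NAMES:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unparseable numeric cell in column {col!r}, row {row}"
            )
        table[col] = values
    if DATE_COLUMN in table.columns:
        table[DATE_COLUMN] = [
            parse_sample_date(d).isoformat() for d in table[DATE_COLUMN]
        ]
    return LabeledDataset(table)


def abundance_timeseries(
    labels: pd.Series,
    tanks: pd.Series,
    dates: pd.Series,
    colonial_classes=reference.INTRAGENERIC_CLASSES,
) -> pd.DataFrame:
    """Per (tank, date) counts and percentages of colonial morphospecies.

    ``labels`` are exclusive-mode class assignments.  Labels in
    :data:`EXCLUDED_LABELS` (and anything not in ``colonial_classes``)
    are tallied in an ``excluded`` column and left out of the colonial
    denominator, so the percentages of the colonial classes sum to 100
    per sample.  Samples with zero colonial particles keep their zero
    counts, carry NaN percentages and are flagged.  Output is sorted by
    tank, then date.
    """
    frame = pd.DataFrame(
        {
            "label": np.asarray(labels, dtype=object),
            TANK_COLUMN: np.asarray(tanks, dtype=object),
            DATE_COLUMN: [parse_sample_date(d).isoformat() for d in dates],
        }
    )
    colonial = list(colonial_classes)
    rows = []
    for (tank, date), grp in frame.groupby([TANK_COLUMN, DATE_COLUMN], sort=True):
        counts = grp["label"].value_counts()
        row: dict = {
            TANK_COLUMN: tank,
            DATE_COLUMN: date,
            "sample_id": make_sample_id(tank, date),
        }
        total = 0
        for cls in colonial:
            c = int(counts.get(cls, 0))
            row[f"count {cls}"] = c
            total += c
        row["excluded"] = int(len(grp) - total)
        for cls in colonial:
            row[f"pct {cls}"] = (
                100.0 * row[f"count {cls}"] / total if total > 0 else np.nan
            )
        row["empty_sample"] = total == 0
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values([TANK_COLUMN, DATE_COLUMN], ignore_index=True)


def write_images(dataset_dir, images) -> list[str]:
    """Save rendered frames as 8-bit RGB PNGs; returns relative paths."""
    from PIL import Image

    out = Path(dataset_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, image in images:
        path = out / f"{name}.png"
        Image.fromarray(image.pixels, mode="RGB").save(path)
        paths.append(str(path))
    return paths


def read_image(path, pixel_size_um: float = None):
    """Load a PNG/TIFF frame as a :class:`~colonygate.particles.ParticleImage`."""
    from PIL import Image

    from .particles import DEFAULT_PIXEL_SIZE_UM, ParticleImage

    if pixel_size_um is None:
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
    with Image.open(path) as img:
        pixels = np.asarray(img.convert("RGB"))
    return ParticleImage(pixels, pixel_size_um)
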