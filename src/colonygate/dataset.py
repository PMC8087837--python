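"""The labelled feature-table container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MissingFeatureError
from .particles import FEATURE_NAMES

ID_COLUMN = "id"
CLASS_COLUMN = "class"
TANK_COLUMN = "tank"
DATE_COLUMN = "date"

#: Metadata columns expected (but not required) alongside the features.
META_COLUMNS = (ID_COLUMN, CLASS_COLUMN, TANK_COLUMN, DATE_COLUMN)


@dataclass
class LabeledDataset:
    """A per-particle feature table with class labels and sample metadata.

    ``table`` holds one row per particle with the ten particle-property
    columns (:data:`~colonygate.particles.FEATURE_NAMES`) plus optional
    ``id``, ``class``, ``tank`` and ``date`` columns.  Unknown extra
    columns are allowed and preserved by the readers/writers.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.table.columns]
        if missing:
            raise MissingFeatureError(
                f"feature column(s) missing: {', '.join(missing)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def features(self) -> pd.DataFrame:
        """The ten feature columns, in canonical order."""
        return self.table[list(FEATURE_NAMES)]

    @property
    def labels(self) -> pd.Series:
        if CLASS_COLUMN not in self.table.columns:
            raise MissingFeatureError("dataset has no 'class' column")
        return self.table[CLASS_COLUMN]

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset(self, index) -> "LabeledDataset":
        """Rows selected by positional index or boolean mask."""
        import numpy as np

        index = np.asarray(index)
        if index.dtype == bool:
            return LabeledDataset(self.table.loc[index].copy())
        return LabeledDataset(self.table.iloc[index].copy())
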