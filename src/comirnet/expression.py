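"""Expression matrix container.

A thin, validated wrapper around a pandas DataFrame (features x samples) with
species and dataset labels.  All numerical routines operate on ``.values``
(the DataFrame) directly, so anything pandas can do remains available.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import DataError


@dataclass
class ExpressionMatrix:
    """Named real matrix of one species/dataset: rows are miRNAs (or probes,
    or genes), columns are samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Features x samples.  Index and columns must be unique.
    species : str
        Species label, e.g. ``"human"``.
    dataset_id : str
        Provenance label for the dataset; used to disambiguate sample IDs
        when several datasets are concatenated.
    """

    values: pd.DataFrame
    species: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise DataError(f"duplicate feature IDs: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5].tolist()
            raise DataError(f"duplicate sample IDs: {dup}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return replace(self, values=values)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[list(feature_ids)])
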