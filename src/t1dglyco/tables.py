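"""Core tabular containers for glycan peak data and sample metadata.

A :class:`PeakTable` is a sample x peak matrix of chromatogram areas (or
values derived from them) together with a processing-state flag.  The state
machine is linear and fixed::

    raw -> percent -> log -> batch_corrected -> rank_normal

Each preprocessing operation checks the incoming state and stamps the
outgoing one, so a table cannot silently be normalized twice or
rank-transformed before batch correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: Valid processing states, in pipeline order.
STATES = ("raw", "percent", "log", "batch_corrected", "rank_normal")

REQUIRED_METADATA_COLUMNS = ("sample_id", "family_id", "sex", "age", "status", "batch")


class StateError(ValueError):
    """Operation applied to a PeakTable in the wrong processing state."""


@dataclass
class PeakTable:
    """Sample x peak matrix of chromatogram peak areas or derived values.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per glycan peak
        (``GP1`` .. ``GPn``).
    state
        Processing state; one of :data:`STATES`.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate peak ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if self.state in ("raw", "percent") and np.any(arr < 0):
            raise ValueError(f"negative values not allowed in state {self.state!r}")
        if self.state == "percent":
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 100.0, atol=1e-9, rtol=0):
                bad = self.values.index[~np.isclose(sums, 100.0, atol=1e-9, rtol=0)]
                raise ValueError(
                    f"percent rows must sum to 100 within 1e-9; offending samples: {list(bad[:5])}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def peak_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise StateError(
                f"operation requires state in {allowed}, got {self.state!r}"
            )

    def with_values(self, values: pd.DataFrame, state: str) -> "PeakTable":
        """Return a new table with replaced values and state."""
        return PeakTable(values=values, state=state)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, state: str = "raw") -> "PeakTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, state=state)


@dataclass
class SampleMetadata:
    """Per-sample covariates: family, sex, age, disease status, batch.

    ``sex`` is coded ``{"F", "M"}``, ``status`` is 0 (unaffected) / 1
    (affected), ``batch`` is an arbitrary plate label.  Autoantibody
    measurements, when present, live in columns ``<assay>_level`` (the
    recorded, possibly LOQ-truncated level) and ``<assay>_below_loq``
    (the indicator I: 1 if the latent level is below the assay LOQ).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if not set(self.table["status"].unique()) <= {0, 1}:
            raise ValueError("status must be coded 0/1")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def aligned_to(self, peak_table: PeakTable) -> "SampleMetadata":
        """Metadata reindexed to the peak table's sample order."""
        df = self.table.set_index("sample_id").loc[peak_table.sample_ids].reset_index()
        return SampleMetadata(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class BatchDesign:
    """Batch assignment used by ComBat correction.

    ``covariates`` optionally carries a numeric design matrix of biological
    covariates to protect during correction (default none, matching a
    correction performed before any modelling).
    """

    batch: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.batch.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"every batch needs >= 2 samples; undersized: {dict(small)}"
            )
        if self.covariates is not None and len(self.covariates) != len(self.batch):
            raise ValueError("covariates and batch must cover the same samples")

    @property
    def n_batches(self) -> int:
        return self.batch.nunique()

    @classmethod
    def from_metadata(cls, metadata: SampleMetadata) -> "BatchDesign":
        return cls(batch=metadata.table.set_index("sample_id")["batch"])
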