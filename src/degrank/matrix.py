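"""Core container for probes-by-samples expression data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

NATURAL = "natural"
LOG2 = "log2"

#: Required columns of the per-sample metadata table.
SAMPLE_COLUMNS = ("type", "site", "platform")


@dataclass
class ExpressionMatrix:
    """Expression values with a scale flag and per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of intensities, index = probe (or gene) identifiers,
        columns = sample identifiers.  The index may contain duplicate
        probe IDs *before* duplicate averaging; afterwards it must be
        unique.
    scale
        Either ``"natural"`` or ``"log2"``.
    samples
        Optional per-sample metadata indexed by sample ID with columns
        ``type`` (A/B/C/D), ``site`` and ``platform``.  Every column of
        ``values`` must be present in the metadata index when given.
    """

    values: pd.DataFrame
    scale: str
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in (NATURAL, LOG2):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.values.isna().to_numpy().any():
            raise DataError("missing values are not permitted")
        if self.scale == NATURAL and (self.values.to_numpy() < 0).any():
            raise DataError("negative intensities on the natural scale")
        if self.samples is not None:
            missing = set(self.values.columns) - set(self.samples.index)
            if missing:
                raise DataError(f"samples missing from metadata: {sorted(missing)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_unique_probes(self) -> bool:
        return self.values.index.is_unique

    def samples_of_type(self, sample_type: str) -> list[str]:
        """Sample IDs with metadata ``type == sample_type``."""
        if self.samples is None:
            raise DataError("matrix carries no sample metadata")
        mask = self.samples["type"] == sample_type
        return [s for s in self.values.columns if s in self.samples.index[mask]]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.scale,
            None if self.samples is None else self.samples.copy(),
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """Return a new matrix sharing this one's metadata."""
        return ExpressionMatrix(values, scale or self.scale, self.samples)


def natural_values(matrix: ExpressionMatrix) -> np.ndarray:
    """Values of ``matrix`` on the natural scale regardless of its flag."""
    vals = matrix.values.to_numpy(dtype=float)
    if matrix.scale == LOG2:
        return np.exp2(vals)
    return vals
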