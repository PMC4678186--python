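"""Near-infrared water-stress index.

Leaf NIR reflectance rises as tissue water content falls, so the upper
part of a plant's NIR intensity histogram is a sensitive drought signal.
For each digital plant the third quartile (Q3, 75th percentile) of its NIR
pixel intensities is computed; the index is Q3 relative to the same
plant's Q3 at a fixed baseline timepoint, times 100.  An index above 120
calls the plant stressed (wilted or dried); at or below 120, non-stressed.

The baseline day must itself be quiet: it is the earliest timepoint whose
subsequent cohort measurements stay within a small relative band
(homogeneity of the index base reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import PlatformConfig

__all__ = [
    "NIRMeasurement",
    "NIRIndexRecord",
    "third_quartile",
    "nir_index",
    "classify_nir",
    "select_base_das",
]


@dataclass
class NIRMeasurement:
    """Q3 of one digital plant's NIR intensities at one timepoint."""

    sample_id: str
    das: int
    q3: float

    def __post_init__(self) -> None:
        if not 0 <= self.q3 <= 255:
            raise ValueError("Q3 must lie on the 0-255 intensity scale")


@dataclass
class NIRIndexRecord:
    """Index of one sample at one DAS against the base reference."""

    sample_id: str
    das: int
    base_das: int
    q3: float
    q3_base: float
    index: float
    call: str  # "stressed" | "non-stressed"


def third_quartile(values: Sequence[float] | np.ndarray) -> float:
    """Q3 (75th percentile) by linear interpolation between order stats.

    The quantile sits at position 1 + 0.75*(n - 1) on the sorted list —
    the interpolation convention of mainstream statistical environments.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take the quartile of an empty list")
    return float(np.percentile(values, 75, method="linear"))


def nir_index(q3: float, q3_base: float) -> float:
    """Index = 100 * Q3 / Q3_base."""
    if q3_base <= 0:
        raise ValueError("base Q3 must be positive")
    return 100.0 * q3 / q3_base


def classify_nir(index: float, cfg: PlatformConfig | None = None) -> str:
    """Stress call from the index: stressed iff index > threshold (120)."""
    cfg = cfg or PlatformConfig()
    return "stressed" if index > cfg.nir_index_threshold else "non-stressed"


def select_base_das(
    q3_series: pd.DataFrame,
    tolerance: float = 0.02,
    lookahead: int = 2,
) -> int:
    """Pick the base-reference DAS from a cohort Q3 time series.

    ``q3_series`` has one row per sample and one column per DAS (columns
    sorted ascending).  The base is the earliest DAS whose mean absolute
    relative cohort change over the next ``lookahead`` measurements is at
    most ``tolerance`` (default 2%, the scale of the quiet early
    measurements the reference condition demands).  If no DAS qualifies
    the first DAS is returned with a warning.
    """
    das_list = [int(d) for d in q3_series.columns]
    if len(das_list) < 3:
        raise ValueError("need at least 3 timepoints to select a base")
    if das_list != sorted(das_list):
        raise ValueError("DAS columns must be sorted ascending")
    q = q3_series.to_numpy(dtype=float)
    for i, das in enumerate(das_list[:-1]):
        js = range(i + 1, min(i + 1 + lookahead, len(das_list)))
        base = q[:, i]
        if np.any(base <= 0):
            continue
        rel = [np.abs(q[:, j] - base) / base for j in js]
        if float(np.mean(rel)) <= tolerance:
            return das
    warnings.warn(
        "no DAS satisfies the homogeneity condition; falling back to the first DAS",
        stacklevel=2,
    )
    return das_list[0]


def index_records(
    q3_series: pd.DataFrame,
    base_das: int,
    cfg: PlatformConfig | None = None,
) -> list[NIRIndexRecord]:
    """Index + stress call for every sample x DAS against one base DAS."""
    cfg = cfg or PlatformConfig()
    if base_das not in [int(d) for d in q3_series.columns]:
        raise ValueError(f"base DAS {base_das} not in series")
    records = []
    for sample_id, row in q3_series.iterrows():
        q3_base = float(row[base_das])
        for das in q3_series.columns:
            idx = nir_index(float(row[das]), q3_base)
            records.append(
                NIRIndexRecord(
                    sample_id=str(sample_id),
                    das=int(das),
                    base_das=int(base_das),
                    q3=float(row[das]),
                    q3_base=q3_base,
                    index=idx,
                    call=classify_nir(idx, cfg),
                )
            )
    return records
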