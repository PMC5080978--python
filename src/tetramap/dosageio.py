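"""Dosage-matrix container and delimited-text I/O.

The central exchange format is a markers × individuals matrix of tetraploid
allele dosages (integers 0–4, NA for a call that could not be assigned with
sufficient confidence), with an optional per-call confidence matrix of the
same shape.  Files are plain CSV: one header row of sample ids, one row per
marker, values ``0..4`` or empty/``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DosageMatrix", "read_dosage_csv", "write_dosage_csv"]


@dataclass
class DosageMatrix:
    """Markers × individuals dosage calls with per-call confidence.

    ``calls`` is a float DataFrame (NaN = missing) indexed by marker id with
    sample ids as columns; ``confidence`` (same shape) holds the assignment
    probability of each call, in [0, 1].  Missing calls carry confidence
    below 0.95 by construction.
    """

    calls: pd.DataFrame
    confidence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.confidence is not None:
            if not self.calls.index.equals(self.confidence.index) or not (
                self.calls.columns.equals(self.confidence.columns)
            ):
                raise ValueError("calls and confidence must be aligned")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 4) & (vals == np.round(vals)))
        if not ok.all():
            raise ValueError("dosage calls must be integers in 0..4 or missing")

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing calls."""
        return self.calls.isna().mean(axis=1)

    def subset_markers(self, marker_ids) -> "DosageMatrix":
        conf = None if self.confidence is None else self.confidence.loc[marker_ids]
        return DosageMatrix(self.calls.loc[marker_ids], conf)

    def subset_samples(self, sample_ids) -> "DosageMatrix":
        conf = None if self.confidence is None else self.confidence[list(sample_ids)]
        return DosageMatrix(self.calls[list(sample_ids)], conf)


def write_dosage_csv(dm: DosageMatrix, path, confidence_path=None) -> None:
    """Write calls (and optionally confidence) as CSV with NA for missing."""
    out = dm.calls.copy()
    # keep integer formatting for non-missing cells
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.index.name = "marker"
    out.to_csv(path)
    if confidence_path is not None and dm.confidence is not None:
        conf = dm.confidence.round(6)
        conf.index.name = "marker"
        conf.to_csv(confidence_path)


def read_dosage_csv(path, confidence_path=None) -> DosageMatrix:
    """Read a dosage CSV; raises on duplicate markers or out-of-range cells.

    Non-integer, non-missing cells raise a parse error naming the offending
    row and column.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate marker ids in {path}: {dups[:5]}")
    raw = df.apply(lambda s: s.str.strip())
    is_missing = raw.isin(["", "NA", "NaN", "nan"])
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = (~is_missing) & (
        numeric.isna() | (numeric != numeric.round()) | (numeric < 0) | (numeric > 4)
    )
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"invalid dosage at marker {df.index[i]!r}, sample "
            f"{df.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    parsed = numeric.where(~is_missing).astype(float)
    conf = None
    if confidence_path is not None and Path(confidence_path).exists():
        conf = pd.read_csv(confidence_path, index_col=0)
    return DosageMatrix(parsed, conf)
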