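"""Activity recordings, circadian quality control, and Pearson correlation.

The in-memory container is :class:`ActivityRecording`: an ``N x T`` matrix of
unit activity (rows = units, columns = time points) with unit identifiers and
time stamps in hours.  Recordings are exchanged as delimited text: the first
column holds unit ids, the header row holds time stamps.

No detrending or global-signal regression is performed here: common trends
are handled spectrally by the null model (see :mod:`funcsig.rmt`), not by
pre-subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InputError, NoRhythmicUnitsError, ZeroVarianceError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-12


@dataclass
class ActivityRecording:
    """N unit time series of length T sampled at a common grid.

    Parameters
    ----------
    values
        ``(N, T)`` float array, one row per unit.
    unit_ids
        N unit identifiers.
    time_stamps
        T strictly increasing time points, in hours.
    sampling_interval
        Nominal spacing of ``time_stamps`` in hours.
    coords
        Optional ``(N, 2)`` image-plane positions used only for back-mapping
        modules onto anatomy; never enters the computation.
    """

    values: np.ndarray
    unit_ids: list[str]
    time_stamps: np.ndarray
    sampling_interval: float = 1.0
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        self.unit_ids = [str(u) for u in self.unit_ids]
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D (units x time) array")
        n, t = self.values.shape
        if n < 2:
            raise InputError(f"need at least 2 units, got {n}")
        if t < 3:
            raise InputError(f"need at least 3 time points, got {t}")
        if len(self.unit_ids) != n:
            raise InputError("unit_ids length does not match number of rows")
        if self.time_stamps.shape != (t,):
            raise InputError("time_stamps length does not match number of columns")
        if np.any(np.diff(self.time_stamps) <= 0):
            raise InputError("time_stamps must be strictly increasing")
        if np.isnan(self.values).any():
            raise InputError("recording contains NaN after loading")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise InputError("coords must have shape (N, 2)")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "ActivityRecording":
        """Restrict to a subset of units (original time series, same grid)."""
        idx = np.asarray(indices, dtype=int)
        return ActivityRecording(
            values=self.values[idx],
            unit_ids=[self.unit_ids[i] for i in idx],
            time_stamps=self.time_stamps,
            sampling_interval=self.sampling_interval,
            coords=None if self.coords is None else self.coords[idx],
        )


@dataclass
class CorrelationMatrix:
    """Pearson correlation matrix with the (N, T) provenance the null needs."""

    values: np.ndarray
    unit_ids: list[str]
    n_timepoints: int
    n_units: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise InputError("correlation matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > _SYMMETRY_TOL:
            raise InputError("correlation matrix is not symmetric")
        if np.max(np.abs(np.diag(self.values) - 1.0)) > 1e-10:
            raise InputError("correlation matrix diagonal must be 1")
        if np.min(self.values) < -1 - 1e-10 or np.max(self.values) > 1 + 1e-10:
            raise InputError("correlation entries must lie in [-1, 1]")
        self.n_units = n
        self.unit_ids = [str(u) for u in self.unit_ids]


def load_recording(
    path: str | Path,
    *,
    delimiter: str | None = None,
    transpose: bool = False,
    coords_path: str | Path | None = None,
) -> ActivityRecording:
    """Read a delimited unit-by-time matrix.

    Rows are units, the first column holds unit ids and the header row the
    time stamps (in hours; non-numeric headers fall back to a unit-spaced
    grid).  ``transpose=True`` reads a time-by-unit layout instead.  Units
    containing any missing value are dropped with a logged warning so that
    the null model's (N, T) stays well defined.
    """
    path = Path(path)
    sep = delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T

    numeric = df.apply(pd.to_numeric, errors="coerce")
    stripped = df.apply(lambda col: col.astype(str).str.strip())
    bad = numeric.isna() & df.notna() & (stripped != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"in {path}"
        )

    values = numeric.to_numpy(dtype=float)
    keep = ~np.isnan(values).any(axis=1)
    if not keep.all():
        dropped = [str(u) for u in df.index[~keep]]
        logger.warning(
            "dropping %d unit(s) with missing values: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    values = values[keep]
    unit_ids = [str(u) for u in df.index[keep]]
    if values.shape[0] < 2:
        raise InputError(f"fewer than 2 usable units in {path}")

    try:
        stamps = np.asarray([float(c) for c in df.columns], dtype=float)
        if np.any(np.diff(stamps) <= 0):
            raise ValueError
    except ValueError:
        stamps = np.arange(values.shape[1], dtype=float)
    interval = float(np.median(np.diff(stamps))) if len(stamps) > 1 else 1.0

    coords = None
    if coords_path is not None:
        cdf = pd.read_csv(coords_path, index_col=0)
        cdf.index = cdf.index.astype(str)
        try:
            coords = cdf.loc[unit_ids].to_numpy(dtype=float)[:, :2]
        except KeyError as exc:
            raise InputError(f"coordinates sidecar misses unit {exc}") from exc

    return ActivityRecording(values, unit_ids, stamps, interval, coords)


def save_recording(rec: ActivityRecording, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a recording in the layout :func:`load_recording` reads."""
    df = pd.DataFrame(rec.values, index=rec.unit_ids, columns=rec.time_stamps)
    df.index.name = "unit_id"
    df.to_csv(path, sep=delimiter, float_format="%.12g")


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def circadian_qc(
    rec: ActivityRecording,
    min_cycles: int = 3,
    period_range: tuple[float, float] = (20.0, 28.0),
    *,
    smooth_window: int = 0,
) -> tuple[ActivityRecording, pd.DataFrame]:
    """Keep units with sustained rhythms in the circadian range.

    A unit passes when it shows at least ``min_cycles`` peaks whose mean
    inter-peak interval lies within ``period_range`` (hours).  Peaks are local
    maxima (:func:`scipy.signal.find_peaks`), optionally after moving-average
    smoothing (off by default; raw and smoothed traces give equivalent
    downstream results on rhythmic data).

    Returns the filtered recording and a per-unit report with columns
    ``unit_id, n_peaks, mean_interval_h, passed``.  Raises
    :class:`NoRhythmicUnitsError` when nothing survives.  Idempotent.
    """
    lo, hi = period_range
    rows = []
    keep = np.zeros(rec.n_units, dtype=bool)
    for i in range(rec.n_units):
        x = _moving_average(rec.values[i], smooth_window)
        peaks, _ = find_peaks(x)
        n_peaks = len(peaks)
        if n_peaks >= 2:
            mean_interval = float(np.mean(np.diff(rec.time_stamps[peaks])))
        else:
            mean_interval = np.nan
        passed = n_peaks >= min_cycles and lo <= mean_interval <= hi
        keep[i] = passed
        rows.append((rec.unit_ids[i], n_peaks, mean_interval, bool(passed)))
    report = pd.DataFrame(rows, columns=["unit_id", "n_peaks", "mean_interval_h", "passed"])
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise NoRhythmicUnitsError(
            f"no rhythmic units: 0 of {rec.n_units} passed circadian QC "
            f"(min {min_cycles} peaks, mean interval in {period_range} h)"
        )
    if n_kept < rec.n_units:
        logger.info("circadian QC kept %d of %d units", n_kept, rec.n_units)
    if n_kept < 2:
        raise NoRhythmicUnitsError("fewer than 2 units passed circadian QC")
    return rec.subset(np.flatnonzero(keep)), report


def pearson_correlation(rec: ActivityRecording) -> CorrelationMatrix:
    """Pearson product-moment correlation matrix of the unit time series.

    By construction the result is invariant under per-unit affine rescaling
    with positive slope and under any common permutation of the time columns;
    the latter is why arbitrary temporal modulation (nonstationary trends)
    can be handled at the level of the correlation matrix.
    """
    sd = rec.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(rec.unit_ids[i] for i in dead[:10])
        raise ZeroVarianceError(
            f"unit(s) with zero variance: {names}; run QC before correlating"
        )
    c = np.corrcoef(rec.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c, rec.unit_ids, rec.n_timepoints)
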