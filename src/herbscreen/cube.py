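"""Three-way DAD data model and I/O.

A diode-array detector records absorbance simultaneously over a wavelength
range while the chromatographic run unfolds in time, so every injection
yields a two-way slice (wavelength x time) and a study yields a three-way
cube (sample x wavelength x time).  Chemometric modelling operates on the
sample-wise *unfolded* two-way matrix in which each row concatenates the
selected wavelength channels of one sample, wavelength-major (all time
points of the first channel, then the second, ...).

The interchange format is a long-format CSV with columns
``sample_id,label,wavelength_nm,time_min,absorbance_au``, one row per cube
cell, rows sorted by (sample_id, wavelength_nm, time_min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import CubeFormatError, EmptySelectionError

CSV_COLUMNS = ["sample_id", "label", "wavelength_nm", "time_min", "absorbance_au"]

_AXIS_TOL = 1e-9  # absolute tolerance when matching wavelength/time stamps


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return axis


@dataclass
class DataCube:
    """Three-way absorbance array with labelled axes.

    values : float array, shape (n_samples, n_wavelengths, n_times), AU
    sample_ids : unique identifiers, one per sample
    wavelengths : nm, strictly increasing
    times : minutes, strictly increasing
    labels : optional integer class codes, one per sample
    """

    values: np.ndarray
    sample_ids: list[str]
    wavelengths: np.ndarray
    times: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array (sample, wavelength, time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        self.wavelengths = _check_axis("wavelengths", self.wavelengths)
        self.times = _check_axis("times", self.times)
        n_s, n_w, n_t = self.values.shape
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match values")
        if self.wavelengths.size != n_w or self.times.size != n_t:
            raise ValueError("axis lengths do not match value dimensions")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n_s,):
                raise ValueError("labels length does not match samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def record(self, sample_id: str) -> np.ndarray:
        """One sample's (wavelength x time) slice."""
        return self.values[self.sample_index(sample_id)]

    def select_wavelengths(self, wavelengths) -> "DataCube":
        """Restrict to the given channels (matched within 1e-9 nm)."""
        idx = []
        for w in np.atleast_1d(wavelengths):
            hits = np.nonzero(np.abs(self.wavelengths - w) <= _AXIS_TOL)[0]
            if hits.size == 0:
                raise EmptySelectionError(f"wavelength {w} nm not on the cube grid")
            idx.append(hits[0])
        idx = sorted(set(idx))
        return replace(
            self,
            values=self.values[:, idx, :].copy(),
            wavelengths=self.wavelengths[idx].copy(),
        )


@dataclass
class FingerprintMatrix:
    """Sample-wise unfolded two-way table used for modelling.

    Column ``j*T + k`` of the unfold of a (S, W, T) cube holds wavelength
    ``j``'s absorbance at time point ``k``; ``feature_wavelengths`` and
    ``feature_times`` record the (wavelength, time) pair behind each column.
    """

    values: np.ndarray
    feature_wavelengths: np.ndarray
    feature_times: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (sample, feature)")
        self.feature_wavelengths = np.asarray(self.feature_wavelengths, dtype=float)
        self.feature_times = np.asarray(self.feature_times, dtype=float)
        n_s, n_f = self.values.shape
        if self.feature_wavelengths.shape != (n_f,) or self.feature_times.shape != (n_f,):
            raise ValueError("feature map length does not match columns")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n_s,):
                raise ValueError("labels length does not match rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take(self, indices) -> "FingerprintMatrix":
        """Row subset in the given order."""
        indices = np.asarray(indices, dtype=int)
        return FingerprintMatrix(
            values=self.values[indices].copy(),
            feature_wavelengths=self.feature_wavelengths,
            feature_times=self.feature_times,
            sample_ids=[self.sample_ids[i] for i in indices],
            labels=None if self.labels is None else self.labels[indices].copy(),
        )

    def take_ids(self, ids) -> "FingerprintMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take([index[s] for s in ids])


def crop_time_window(cube: DataCube, start: float, end: float) -> DataCube:
    """Retain the time points ``start <= t <= end`` (closed interval).

    The closed interval means a 1.5-6.6 min window on a 0.05 s grid keeps
    both endpoints, i.e. 6121 points.
    """
    if not start < end:
        raise ValueError("start must be < end")
    mask = (cube.times >= start - _AXIS_TOL) & (cube.times <= end + _AXIS_TOL)
    if not mask.any():
        raise EmptySelectionError(
            f"window [{start}, {end}] min does not overlap the time axis"
        )
    return replace(
        cube, values=cube.values[:, :, mask].copy(), times=cube.times[mask].copy()
    )


def unfold_cube(cube: DataCube) -> FingerprintMatrix:
    """Unfold (S, W, T) -> (S, W*T), wavelength-major.

    Row i satisfies ``matrix[i, j*T + k] == cube[i, j, k]``, keeping each
    wavelength channel contiguous so that per-channel alignment blocks map
    onto contiguous column runs.
    """
    if cube.values.size == 0:
        raise ValueError("cannot unfold an empty cube")
    n_s, n_w, n_t = cube.values.shape
    return FingerprintMatrix(
        values=cube.values.reshape(n_s, n_w * n_t).copy(),
        feature_wavelengths=np.repeat(cube.wavelengths, n_t),
        feature_times=np.tile(cube.times, n_w),
        sample_ids=list(cube.sample_ids),
        labels=None if cube.labels is None else cube.labels.copy(),
    )


def refold_matrix(matrix: FingerprintMatrix) -> DataCube:
    """Inverse of :func:`unfold_cube` (exact round trip)."""
    wavelengths = np.unique(matrix.feature_wavelengths)
    times = np.unique(matrix.feature_times)
    n_w, n_t = wavelengths.size, times.size
    if n_w * n_t != matrix.n_features:
        raise ValueError("feature map is not a full wavelength x time grid")
    expected_w = np.repeat(wavelengths, n_t)
    expected_t = np.tile(times, n_w)
    if not (
        np.array_equal(expected_w, matrix.feature_wavelengths)
        and np.array_equal(expected_t, matrix.feature_times)
    ):
        raise ValueError("feature map is not in wavelength-major order")
    return DataCube(
        values=matrix.values.reshape(matrix.n_samples, n_w, n_t).copy(),
        sample_ids=list(matrix.sample_ids),
        wavelengths=wavelengths,
        times=times,
        labels=None if matrix.labels is None else matrix.labels.copy(),
    )


def write_cube(cube: DataCube, path) -> None:
    """Write the long-format CSV dialect.

    Rows are canonicalized to (sample_id, wavelength_nm, time_min) order as
    the dialect requires, so ``read(write(cube))`` is the exact identity
    when ``sample_ids`` are already in lexicographic order (the simulator
    emits zero-padded sorted ids) and a sample-order permutation otherwise.
    """
    n_s, n_w, n_t = cube.values.shape
    order = np.argsort(np.asarray(cube.sample_ids, dtype=object))
    frames = []
    for i in order:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": cube.sample_ids[i],
                    "label": "" if cube.labels is None else cube.labels[i],
                    "wavelength_nm": np.repeat(cube.wavelengths, n_t),
                    "time_min": np.tile(cube.times, n_w),
                    "absorbance_au": cube.values[i].reshape(-1),
                }
            )
        )
    # %.17g round-trips IEEE doubles exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_cube(path) -> DataCube:
    """Read the long-format CSV dialect, validating it strictly.

    Raises :class:`CubeFormatError` (with the offending 1-based file row
    where attributable) on missing columns, duplicate (sample, wavelength,
    time) keys, unsorted rows, ragged per-sample grids, inconsistent labels
    or non-finite absorbances.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if list(df.columns) != CSV_COLUMNS:
        raise CubeFormatError(
            f"expected columns {CSV_COLUMNS}, found {list(df.columns)}"
        )
    if df.empty:
        raise CubeFormatError("file contains no data rows")
    # +2: 1-based numbering and the header line
    dup = df.duplicated(["sample_id", "wavelength_nm", "time_min"])
    if dup.any():
        raise CubeFormatError(
            "duplicate (sample_id, wavelength_nm, time_min) key",
            row=int(dup.idxmax()) + 2,
        )
    key = df[["sample_id", "wavelength_nm", "time_min"]]
    sorted_ok = (
        key.sort_values(
            ["sample_id", "wavelength_nm", "time_min"], kind="stable"
        ).index.to_numpy()
        == np.arange(len(df))
    )
    if not sorted_ok.all():
        raise CubeFormatError(
            "rows are not sorted by (sample_id, wavelength_nm, time_min)",
            row=int(np.nonzero(~sorted_ok)[0][0]) + 2,
        )
    if not np.all(np.isfinite(df["absorbance_au"].to_numpy(dtype=float))):
        bad = ~np.isfinite(df["absorbance_au"].to_numpy(dtype=float))
        raise CubeFormatError(
            "non-finite absorbance value", row=int(np.nonzero(bad)[0][0]) + 2
        )

    sample_ids = list(dict.fromkeys(df["sample_id"]))  # == sorted, by the check above
    wavelengths = np.unique(df["wavelength_nm"].to_numpy(dtype=float))
    times = np.unique(df["time_min"].to_numpy(dtype=float))
    n_w, n_t = wavelengths.size, times.size

    counts = df.groupby("sample_id", sort=False).size()
    for sid, c in counts.items():
        if c != n_w * n_t:
            raise CubeFormatError(
                f"sample {sid!r} has {c} cells, expected {n_w}x{n_t}="
                f"{n_w * n_t}; a (wavelength, time) cell is missing or extra"
            )

    labels = None
    if df["label"].notna().any():
        if df["label"].isna().any():
            raise CubeFormatError("labels present for some samples but not all")
        per_sample = df.groupby("sample_id", sort=False)["label"].nunique()
        bad = per_sample[per_sample > 1]
        if len(bad):
            raise CubeFormatError(
                f"sample {bad.index[0]!r} carries more than one label"
            )
        labels = (
            df.groupby("sample_id", sort=False)["label"].first().to_numpy(dtype=int)
        )

    values = df["absorbance_au"].to_numpy(dtype=float).reshape(len(sample_ids), n_w, n_t)
    return DataCube(
        values=values,
        sample_ids=sample_ids,
        wavelengths=wavelengths,
        times=times,
        labels=labels,
    )
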