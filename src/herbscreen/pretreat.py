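"""Optional fingerprint pretreatments: SNV, Savitzky-Golay derivatives,
autoscaling.

The screening pipeline's default applies *no* pretreatment after warping
(evaluating them showed no benefit for this kind of data), but the
operations are available behind config flags.  SNV and derivatives are
row-wise/stateless; autoscaling is fitted on the calibration rows only and
its state is applied unchanged to validation or screening data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .cube import FingerprintMatrix
from .exceptions import DegenerateRowError

__all__ = [
    "ScalingState",
    "PretreatConfig",
    "snv_rows",
    "derivative_rows",
    "autoscale",
    "apply_scaling",
]


@dataclass
class ScalingState:
    """Column means/sds learned from a calibration set.

    Zero-variance columns are scaled by 1 and flagged so that applying the
    state never divides by zero.
    """

    column_means: np.ndarray
    column_sds: np.ndarray
    flagged: np.ndarray  # zero-variance columns
    fitted_on: int

    def __post_init__(self):
        if not (len(self.column_means) == len(self.column_sds) == len(self.flagged)):
            raise ValueError("state arrays must have equal length")
        if np.any(self.column_sds[~self.flagged] <= 0):
            raise ValueError("retained columns must have sd > 0")


@dataclass(frozen=True)
class PretreatConfig:
    """Which pretreatments to run.  ``derivative`` is (order, window,
    polyorder) or None; window must be odd and window > polyorder >= order."""

    snv: bool = False
    derivative: tuple[int, int, int] | None = None
    autoscale: bool = False


def snv_rows(matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Standard normal variate: each row to zero mean, unit population sd.

    Idempotent on non-degenerate rows; a constant row raises
    :class:`DegenerateRowError` naming the sample.
    """
    if matrix.n_features < 2:
        raise ValueError("SNV needs more than one feature per row")
    values = matrix.values
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, keepdims=True)  # population (n) sd
    flat = np.nonzero(sds.ravel() == 0)[0]
    if flat.size:
        raise DegenerateRowError(matrix.sample_ids[int(flat[0])])
    return replace(matrix, values=(values - means) / sds)


def _wavelength_blocks(matrix: FingerprintMatrix) -> list[slice]:
    """Contiguous column runs belonging to one wavelength channel."""
    fw = matrix.feature_wavelengths
    edges = np.nonzero(np.diff(fw) != 0)[0] + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [fw.size]))
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def derivative_rows(
    matrix: FingerprintMatrix, order: int, window: int, polyorder: int
) -> FingerprintMatrix:
    """Savitzky-Golay derivative of given order along time, per wavelength block.

    The filter never crosses a block boundary (channels are physically
    independent traces).  Differentiation is with respect to the point
    index (delta = 1 grid step).  Output dimensions are unchanged.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not window > polyorder >= order:
        raise ValueError("need window > polyorder >= order")
    out = np.empty_like(matrix.values)
    for block in _wavelength_blocks(matrix):
        if window > (block.stop - block.start):
            raise ValueError(
                f"window {window} exceeds wavelength-block length "
                f"{block.stop - block.start}"
            )
        out[:, block] = savgol_filter(
            matrix.values[:, block],
            window_length=window,
            polyorder=polyorder,
            deriv=order,
            axis=1,
        )
    return replace(matrix, values=out)


def autoscale(
    train: FingerprintMatrix, apply_to: FingerprintMatrix | None = None
) -> tuple[FingerprintMatrix, ScalingState]:
    """Center and scale columns by calibration statistics only.

    Returns the transformed ``apply_to`` (or the transformed training
    matrix when ``apply_to`` is None) together with the fitted state.
    Population (n) sds are used, matching SNV.
    """
    if train.n_samples == 0:
        raise ValueError("training matrix is empty")
    means = train.values.mean(axis=0)
    sds = train.values.std(axis=0)
    flagged = sds == 0
    sds = np.where(flagged, 1.0, sds)
    state = ScalingState(
        column_means=means, column_sds=sds, flagged=flagged, fitted_on=train.n_samples
    )
    target = train if apply_to is None else apply_to
    return apply_scaling(state, target), state


def apply_scaling(state: ScalingState, matrix: FingerprintMatrix) -> FingerprintMatrix:
    """Apply stored centering/scaling; never recomputes statistics."""
    if matrix.n_features != len(state.column_means):
        raise ValueError(
            f"feature count {matrix.n_features} does not match scaling state "
            f"({len(state.column_means)})"
        )
    return replace(matrix, values=(matrix.values - state.column_means) / state.column_sds)


def apply_stateless(matrix: FingerprintMatrix, config: PretreatConfig) -> FingerprintMatrix:
    """Run the row-wise (stateless) pretreatments configured: SNV, derivative."""
    out = matrix
    if config.snv:
        out = snv_rows(out)
    if config.derivative is not None:
        order, window, polyorder = config.derivative
        out = derivative_rows(out, order, window, polyorder)
    return out
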