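"""Wavelength-channel correlation analysis and orthogonal channel selection.

Neighbouring DAD channels are highly redundant: a compound absorbing at
one wavelength produces a near-identical time trace a few nm away.  To
build a *multidimensional* fingerprint from a handful of channels, the
reference standard's record is screened for a small set of mutually
low-correlated ("orthogonal") wavelengths: compute the Pearson correlation
between every pair of channel time traces, then greedily pick channels
whose absolute correlation to everything already picked stays below a
cutoff (0.95 by default, at most five channels).

The greedy rule is deterministic: seed with the channel of maximal total
absorbance, then repeatedly add the channel whose maximum |r| to the
current selection is smallest, stopping once that value reaches the cutoff
or the size limit is hit; ties break toward the lower wavelength.
Absolute correlation is used because anti-correlated channels are just as
redundant for fingerprint specificity as correlated ones.  Channels with a
flat (zero-variance) trace are flagged and never selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ChannelCorrelationMap", "channel_correlation_map", "select_orthogonal_wavelengths"]


@dataclass
class ChannelCorrelationMap:
    """Symmetric wavelength x wavelength Pearson correlation matrix.

    ``channel_intensity`` holds each channel's total absorbance (used to
    seed the greedy selection); ``zero_variance`` flags flat channels,
    whose off-diagonal coefficients are set to 0.
    """

    coefficients: np.ndarray
    wavelengths: np.ndarray
    channel_intensity: np.ndarray
    zero_variance: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n = self.wavelengths.size
        if self.coefficients.shape != (n, n):
            raise ValueError("coefficient matrix shape does not match wavelengths")
        if not np.allclose(self.coefficients, self.coefficients.T, atol=1e-12):
            raise ValueError("coefficient matrix must be symmetric")
        if not np.allclose(np.diag(self.coefficients), 1.0, atol=1e-12):
            raise ValueError("coefficient matrix must have a unit diagonal")
        if np.any(np.abs(self.coefficients) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def channel_correlation_map(
    record: np.ndarray, wavelengths: np.ndarray
) -> ChannelCorrelationMap:
    """Pearson correlation between the time traces of every channel pair.

    ``record`` is one sample's (wavelength x time) slice.  Zero-variance
    channels get coefficient 0 off-diagonal (1 on the diagonal) and are
    flagged in the returned map.
    """
    record = np.asarray(record, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if record.ndim != 2 or record.shape[0] != wavelengths.size:
        raise ValueError("record must be (n_wavelengths, n_times)")
    if record.shape[1] < 2:
        raise ValueError("need at least 2 time points per channel")

    n = record.shape[0]
    sd = record.std(axis=1)
    flat = sd == 0
    coeff = np.eye(n)
    live = ~flat
    if live.sum() >= 2:
        sub = np.corrcoef(record[live])
        coeff[np.ix_(live, live)] = sub
        np.fill_diagonal(coeff, 1.0)
    return ChannelCorrelationMap(
        coefficients=np.clip(coeff, -1.0, 1.0),
        wavelengths=wavelengths,
        channel_intensity=record.sum(axis=1),
        zero_variance=flat,
    )


def select_orthogonal_wavelengths(
    cmap: ChannelCorrelationMap, cutoff: float = 0.95, max_k: int = 5
) -> np.ndarray:
    """Greedy selection of mutually low-correlated channels.

    Returns the selected wavelengths in selection order.  Every pair in
    the result has |r| < cutoff.  If every other channel correlates with
    the seed at or above the cutoff, the single seed channel is returned
    with a warning.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")

    absr = np.abs(cmap.coefficients)
    n = cmap.wavelengths.size
    candidates = np.nonzero(~cmap.zero_variance)[0]
    if candidates.size == 0:
        raise ValueError("all channels have zero variance")

    # seed: maximal total signal; np.argmax takes the first maximum, and
    # wavelengths are ascending, so ties already break toward lower nm
    intensity = cmap.channel_intensity[candidates]
    selected = [int(candidates[int(np.argmax(intensity))])]

    while len(selected) < max_k:
        best_c, best_score = -1, np.inf
        for c in candidates:
            if c in selected:
                continue
            score = absr[c, selected].max()
            if score < best_score - 1e-15:
                best_c, best_score = int(c), float(score)
        if best_c < 0 or best_score >= cutoff:
            break
        selected.append(best_c)

    if len(selected) == 1 and max_k > 1 and n > 1:
        warnings.warn(
            "all channels correlate above the cutoff with the seed channel; "
            "returning the seed only",
            UserWarning,
            stacklevel=2,
        )
    return cmap.wavelengths[selected]
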