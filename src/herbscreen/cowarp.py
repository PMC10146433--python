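"""Correlation-optimized warping (COW) of chromatograms.

Run-to-run drifts in mobile phase composition or instrument state shift
peaks along the time axis; COW undoes them by piecewise stretching and
compressing a sample trace onto a target trace.  The target axis is split
into segments of fixed length (the final segment absorbs the remainder);
the segment boundaries in the *sample* may deviate from their proportional
positions, each successive boundary by at most ``slack`` points relative
to the previous one (so boundary b can drift up to +-b*slack cumulatively,
with the first and last nodes pinned).  Each candidate sample segment is
linearly interpolated onto its target segment and scored by the Pearson
correlation with it; dynamic programming over the boundary states returns
the node path maximizing the summed per-segment correlations.  Warping a
trace onto itself is the exact identity with score equal to the number of
segments; zero-variance segments contribute 0.

The DP inner loop is numba-compiled: aligning a full 67-sample, 5-channel,
6121-point study is a few hundred warps and needs to stay in the tens of
milliseconds per warp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .cube import DataCube

__all__ = [
    "WarpSpec",
    "WarpResult",
    "ChannelAlignment",
    "select_target_profile",
    "cow_warp",
    "optimize_warp_params",
    "align_cube",
]

DEFAULT_SEGMENT_GRID = tuple(range(10, 51, 5))
DEFAULT_SLACK_GRID = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class WarpSpec:
    """COW parameters: segment length and slack, both in time points."""

    segment_length: int
    slack: int

    def __post_init__(self):
        if self.segment_length < 3:
            raise ValueError("segment_length must be >= 3")
        if not 1 <= self.slack < self.segment_length:
            raise ValueError("slack must satisfy 1 <= slack < segment_length")


@dataclass
class WarpResult:
    """Optimal node path, warped trace and cumulative correlation score."""

    node_positions: np.ndarray  # sample indices per segment boundary
    warped: np.ndarray  # on the target grid
    score: float  # sum of per-segment Pearson correlations

    def __post_init__(self):
        self.node_positions = np.asarray(self.node_positions, dtype=int)
        self.warped = np.asarray(self.warped, dtype=float)
        if np.any(np.diff(self.node_positions) <= 0):
            raise ValueError("node positions must be strictly increasing")


@njit(cache=True, fastmath=True)
def _cow_dp(sample, target, bounds, prop, slack):  # pragma: no cover - jitted
    N = bounds.size - 1
    LS = sample.size
    maxcap = slack * (N // 2) if N > 1 else 0
    width = 2 * maxcap + 1
    off = maxcap
    NEG = -1e30

    F = np.full((N + 1, width), NEG)
    ptr = np.zeros((N + 1, width), dtype=np.int64)
    F[0, off] = 0.0

    for i in range(1, N + 1):
        cap_i = slack * min(i, N - i)
        cap_p = slack * min(i - 1, N - i + 1)
        t0 = bounds[i - 1]
        t1 = bounds[i]
        L = t1 - t0
        tsum = 0.0
        for k in range(L + 1):
            tsum += target[t0 + k]
        tmean = tsum / (L + 1)
        tnorm2 = 0.0
        for k in range(L + 1):
            d = target[t0 + k] - tmean
            tnorm2 += d * d
        tnorm = np.sqrt(tnorm2)

        for w in range(-cap_i, cap_i + 1):
            b = prop[i] + w
            best = NEG
            barg = 0
            lo = max(-cap_p, w - slack)
            hi = min(cap_p, w + slack)
            for v in range(lo, hi + 1):
                prev = F[i - 1, v + off]
                if prev <= NEG / 2:
                    continue
                a = prop[i - 1] + v
                if tnorm > 0.0:
                    ratio = (b - a) / L
                    sx = 0.0
                    sxx = 0.0
                    sxy = 0.0
                    for k in range(L + 1):
                        pos = a + k * ratio
                        j = int(pos)
                        frac = pos - j
                        if frac > 0.0 and j + 1 < LS:
                            val = sample[j] * (1.0 - frac) + sample[j + 1] * frac
                        else:
                            val = sample[j]
                        sx += val
                        sxx += val * val
                        sxy += val * (target[t0 + k] - tmean)
                    var = sxx - sx * sx / (L + 1)
                    r = sxy / (np.sqrt(var) * tnorm) if var > 1e-300 else 0.0
                else:
                    r = 0.0
                cand = prev + r
                if cand > best:
                    best = cand
                    barg = v
            F[i, w + off] = best
            ptr[i, w + off] = barg

    devs = np.zeros(N + 1, dtype=np.int64)
    for i in range(N, 0, -1):
        devs[i - 1] = ptr[i, devs[i] + off]
    nodes = np.empty(N + 1, dtype=np.int64)
    for i in range(N + 1):
        nodes[i] = prop[i] + devs[i]
    return nodes, F[N, off]


def _segment_bounds(n_points: int, segment_length: int) -> np.ndarray:
    n_seg = (n_points - 1) // segment_length
    bounds = [k * segment_length for k in range(n_seg)]
    bounds.append(n_points - 1)
    return np.asarray(bounds, dtype=np.int64)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float((xc @ yc) / (nx * ny))


def _as_trace_matrix(traces) -> np.ndarray:
    try:
        arr = np.asarray(traces, dtype=float)
    except ValueError as exc:
        raise ValueError("traces must all have the same length") from exc
    if arr.ndim != 2:
        raise ValueError("traces must be a 2-D (trace, time) collection")
    return arr


def select_target_profile(traces) -> int:
    """Index of the trace with maximal mean Pearson correlation to all others.

    Ties resolve to the lowest index (``np.argmax`` takes the first
    maximum).  Zero-variance traces correlate 0 with everything.
    """
    arr = _as_trace_matrix(traces)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 traces")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    mean_others = (corr.sum(axis=1) - np.diag(corr)) / (n - 1)
    return int(np.argmax(mean_others))


def cow_warp(sample: np.ndarray, target: np.ndarray, spec: WarpSpec) -> WarpResult:
    """Warp ``sample`` onto ``target``'s grid, maximizing summed segment correlations."""
    sample = np.ascontiguousarray(sample, dtype=float)
    target = np.ascontiguousarray(target, dtype=float)
    if sample.ndim != 1 or target.ndim != 1:
        raise ValueError("sample and target must be 1-D traces")
    m = spec.segment_length
    if sample.size < 2 * m or target.size < 2 * m:
        raise ValueError("both traces must hold at least 2 x segment_length points")

    bounds = _segment_bounds(target.size, m)
    scale = (sample.size - 1) / (target.size - 1)
    prop = np.asarray(np.rint(bounds * scale), dtype=np.int64)
    if np.min(np.diff(prop)) - spec.slack < 1:
        raise ValueError("slack too large for the proportional segment lengths")

    nodes, score = _cow_dp(sample, target, bounds, prop, spec.slack)

    warped = np.empty(target.size)
    for i in range(1, bounds.size):
        t0, t1 = bounds[i - 1], bounds[i]
        x0, x1 = nodes[i - 1], nodes[i]
        L = t1 - t0
        if x1 - x0 == L:
            warped[t0 : t1 + 1] = sample[x0 : x1 + 1]  # exact copy: identity stays exact
        else:
            warped[t0 : t1 + 1] = np.interp(
                np.linspace(0.0, float(x1 - x0), L + 1),
                np.arange(x1 - x0 + 1, dtype=float),
                sample[x0 : x1 + 1],
            )
    return WarpResult(node_positions=nodes, warped=warped, score=float(score))


def optimize_warp_params(
    traces,
    target_index: int,
    segment_grid=None,
    slack_grid=None,
) -> WarpSpec:
    """Grid search for the (segment, slack) maximizing mean warped-to-target
    correlation over all non-target traces; ties prefer the smaller segment,
    then the smaller slack."""
    arr = _as_trace_matrix(traces)
    target = arr[target_index]
    segment_grid = sorted(set(DEFAULT_SEGMENT_GRID if segment_grid is None else segment_grid))
    slack_grid = sorted(set(DEFAULT_SLACK_GRID if slack_grid is None else slack_grid))
    if not segment_grid or not slack_grid:
        raise ValueError("parameter grids must be non-empty")

    best_spec = None
    best_score = -np.inf
    for m in segment_grid:
        if arr.shape[1] < 2 * m:
            continue
        for s in slack_grid:
            if s >= m:
                continue
            spec = WarpSpec(m, s)
            scores = [
                _pearson(cow_warp(arr[i], target, spec).warped, target)
                for i in range(arr.shape[0])
                if i != target_index
            ]
            score = float(np.mean(scores)) if scores else -np.inf
            if score > best_score:  # strict: first (smallest) grid point wins ties
                best_score = score
                best_spec = spec
    if best_spec is None:
        raise ValueError("no admissible (segment, slack) pair for these traces")
    return best_spec


@dataclass
class ChannelAlignment:
    """Per-wavelength alignment log."""

    wavelength: float
    target_id: str
    target_index: int
    spec: WarpSpec
    mean_corr_before: float
    mean_corr_after: float
    scores: np.ndarray  # per-sample cumulative segment correlations
    n_segments: int


def mean_cross_sample_correlation(traces) -> float:
    """Mean pairwise Pearson correlation between sample traces."""
    arr = _as_trace_matrix(traces)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.nan_to_num(np.corrcoef(arr), nan=0.0)
    iu = np.triu_indices(arr.shape[0], k=1)
    return float(corr[iu].mean())


def align_cube(
    cube: DataCube,
    spec: WarpSpec | None = None,
    *,
    optimize: bool = False,
    per_channel: bool = False,
    segment_grid=None,
    slack_grid=None,
) -> tuple[DataCube, list[ChannelAlignment]]:
    """Align every wavelength channel of a (cropped) cube independently.

    Per channel: the target trace is the sample with the highest mean
    correlation to all others; every sample's trace is replaced by its COW
    result against that target.  With ``optimize=True`` the (segment,
    slack) grid search runs once on the channel of maximal total signal
    (or per channel when ``per_channel`` is set).  Dimensions are
    unchanged; returns the aligned cube plus one log entry per channel.
    """
    if spec is None and not optimize:
        raise ValueError("provide a WarpSpec or set optimize=True")
    dt = np.diff(cube.times)
    if dt.size and (dt.max() - dt.min()) > 1e-9:
        raise ValueError("COW requires a regular time grid (tolerance 1e-9 min)")

    global_spec = spec
    if optimize and not per_channel:
        j = int(np.argmax(cube.values.sum(axis=(0, 2))))
        traces = cube.values[:, j, :]
        global_spec = optimize_warp_params(
            traces,
            select_target_profile(traces),
            segment_grid=segment_grid,
            slack_grid=slack_grid,
        )

    aligned = np.empty_like(cube.values)
    logs: list[ChannelAlignment] = []
    for j in range(cube.n_wavelengths):
        traces = cube.values[:, j, :]
        t_idx = select_target_profile(traces)
        ch_spec = global_spec
        if optimize and per_channel:
            ch_spec = optimize_warp_params(
                traces, t_idx, segment_grid=segment_grid, slack_grid=slack_grid
            )
        before = mean_cross_sample_correlation(traces)
        scores = np.empty(cube.n_samples)
        for i in range(cube.n_samples):
            res = cow_warp(traces[i], traces[t_idx], ch_spec)
            aligned[i, j, :] = res.warped
            scores[i] = res.score
        after = mean_cross_sample_correlation(aligned[:, j, :])
        logs.append(
            ChannelAlignment(
                wavelength=float(cube.wavelengths[j]),
                target_id=cube.sample_ids[t_idx],
                target_index=t_idx,
                spec=ch_spec,
                mean_corr_before=before,
                mean_corr_after=after,
                scores=scores,
                n_segments=_segment_bounds(cube.n_times, ch_spec.segment_length).size - 1,
            )
        )
    return replace(cube, values=aligned), logs


def warp_to_stored_target(
    traces, target_trace: np.ndarray, spec: WarpSpec
) -> np.ndarray:
    """Warp new traces against a stored (train-time) target; used at screening time."""
    arr = _as_trace_matrix(traces)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = cow_warp(arr[i], target_trace, spec).warped
    return out
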