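"""Photobleaching calibration and equal-step staircase fitting.

The single-fluorophore unit is calibrated from sparse-fluorophore movies
as the mean intensity difference across single-step photobleaching
events.  Assembly traces are then decomposed into staircases whose steps
are integer multiples of a per-trace step size: an offline penalized
changepoint segmentation (piecewise-constant least squares, optimal
partitioning) is quantized onto the lattice ``baseline + k * step_size``
for candidate step sizes spanning the calibration mean ± a few SD, and
the candidate with the lowest total squared error wins.  Jumps of more
than one unit between consecutive frames ("missing steps") are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from latkit.core import ImageStack, IntensityTrace
from latkit.tracking import disc_mean


class CalibrationError(RuntimeError):
    """No usable single-step bleaching traces."""


class UnfittableTraceError(ValueError):
    """Trace too short for staircase fitting."""


@dataclass
class FluorophoreCalibration:
    """Single-fluorophore intensity: sample mean / SD over bleaching steps."""

    mean_intensity: float
    sd_intensity: float
    n_molecules: int

    def __post_init__(self) -> None:
        if self.mean_intensity <= 0 or self.sd_intensity < 0 or self.n_molecules < 1:
            raise ValueError("invalid calibration")


@dataclass
class StepFitResult:
    """Fitted equal-step staircase for one intensity trace."""

    step_size: float
    baseline: float
    step_times: list[tuple[int, int]]  # (frame, signed molecule count change)
    fitted_levels: np.ndarray
    count_trace: np.ndarray
    residual_sse: float
    traj_id: int | None = field(default=None)

    @property
    def joins(self) -> int:
        return sum(k for _, k in self.step_times if k > 0)

    @property
    def leaves(self) -> int:
        return sum(-k for _, k in self.step_times if k < 0)

    @property
    def max_count(self) -> int:
        return int(self.count_trace.max()) if len(self.count_trace) else 0


# ---------------------------------------------------------------------------
# changepoint machinery


def _segment_cost_tables(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: np.ndarray | int, j: int) -> np.ndarray:
    n = j - np.asarray(i)
    tot = s1[j] - s1[i]
    return (s2[j] - s2[i]) - tot * tot / np.maximum(n, 1)


def segment_changepoints(x: np.ndarray, penalty: float) -> list[int]:
    """Optimal partitioning of ``x`` into piecewise-constant segments.

    Minimizes sum of per-segment SSE plus ``penalty`` per changepoint;
    returns the sorted interior changepoint indices (segment start
    positions, 0 excluded).
    """
    n = len(x)
    s1, s2 = _segment_cost_tables(x)
    F = np.empty(n + 1)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    idx = np.arange(n + 1)
    for j in range(1, n + 1):
        cand = F[:j] + _sse(s1, s2, idx[:j], j) + penalty
        best = int(np.argmin(cand))
        F[j] = cand[best]
        last[j] = best
    cps = []
    j = n
    while j > 0:
        i = last[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def best_k_changepoints(x: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exact best piecewise-constant fit with exactly ``k`` changepoints.

    Dynamic programming in O(k n²); returns (changepoints, SSE).  Used to
    compare 0/1/2-step hypotheses for single-fluorophore screening.
    """
    n = len(x)
    s1, s2 = _segment_cost_tables(x)
    idx = np.arange(n + 1)
    # C[m][j] = best cost of x[:j] with m changepoints
    C = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    for j in range(1, n + 1):
        C[0, j] = _sse(s1, s2, 0, j)
    for m in range(1, k + 1):
        for j in range(m + 1, n + 1):
            i_opts = idx[m:j]
            cand = C[m - 1, m:j] + _sse(s1, s2, i_opts, j)
            best = int(np.argmin(cand))
            C[m, j] = cand[best]
            back[m, j] = i_opts[best]
    cps = []
    j, m = n, k
    while m > 0:
        i = back[m, j]
        cps.append(int(i))
        j, m = i, m - 1
    return sorted(cps), float(C[k, n])


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from first differences (steps are sparse outliers)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# single-fluorophore identification and calibration


def _fit_gaussian_spot(window: np.ndarray) -> tuple[float, float] | None:
    """Fit A·exp(-r²/2σ²)+b to a square window; return (amplitude, residual SD)."""
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]

    def model(coords, amp, x0, y0, sigma, off):
        x, y = coords
        return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + off

    p0 = [float(window.max() - window.min()), w / 2, h / 2, 1.5, float(window.min())]
    try:
        popt, _ = curve_fit(model, (xx.ravel(), yy.ravel()), window.ravel(),
                            p0=p0, maxfev=2000)
    except RuntimeError:
        return None
    resid = window.ravel() - model((xx.ravel(), yy.ravel()), *popt)
    return float(popt[0]), float(resid.std())


def identify_single_fluorophores(stack: ImageStack, fit_diameter_px: int = 6,
                                 min_snr: float = 6.0) -> list[IntensityTrace]:
    """Extract single-step bleaching traces from a sparse calibration movie.

    Spots are candidate maxima in frame 0, accepted when a 2D Gaussian
    fit in a ``fit_diameter_px`` window has amplitude / residual-SD >=
    ``min_snr``.  The fixed-coordinate disc-mean trace over the whole
    movie is kept only when a 1-changepoint (downward) fit beats both the
    0- and 2-changepoint fits under a BIC-style penalty — i.e. single-step
    photobleaching.
    """
    frame0 = np.asarray(stack.data[0], dtype=float)
    sm = gaussian(frame0, sigma=1.0, preserve_range=True)
    thr = sm.min() + 0.2 * (sm.max() - sm.min())
    peaks = peak_local_max(sm, min_distance=fit_diameter_px,
                           threshold_abs=thr, exclude_border=2)
    half = fit_diameter_px // 2 + 1
    traces: list[IntensityTrace] = []
    n = stack.n_frames
    for py, px in peaks:
        y0, y1 = py - half, py + half + 1
        x0, x1 = px - half, px + half + 1
        if y0 < 0 or x0 < 0 or y1 > frame0.shape[0] or x1 > frame0.shape[1]:
            continue
        fit = _fit_gaussian_spot(frame0[y0:y1, x0:x1])
        if fit is None:
            continue
        amp, resid_sd = fit
        if resid_sd > 0 and amp / resid_sd < min_snr:
            continue
        if resid_sd == 0 and amp <= 0:
            continue
        values = np.array([disc_mean(np.asarray(stack.data[t], dtype=float),
                                     px, py, fit_diameter_px) for t in range(n)])
        if _is_single_step_down(values):
            traces.append(IntensityTrace(values, frame_interval=stack.frame_interval))
    return traces


def _is_single_step_down(x: np.ndarray) -> bool:
    n = len(x)
    if n < 4:
        return False
    sigma = max(_noise_sd(x), 1e-12)
    # a changepoint must beat the best spuriously placed split in pure noise,
    # whose expected gain is ~2 sigma^2 log n; double that as the price
    pen = 4.0 * sigma**2 * np.log(n)
    scores = {}
    cps1 = None
    for k in (0, 1, 2):
        if n <= k + 1:
            continue
        cps, sse = best_k_changepoints(x, k)
        scores[k] = sse + k * pen
        if k == 1:
            cps1 = cps
    if 1 not in scores or min(scores, key=scores.get) != 1 or cps1 is None:
        return False
    cp = cps1[0]
    return float(x[:cp].mean()) > float(x[cp:].mean())


def calibrate(traces: list[IntensityTrace]) -> FluorophoreCalibration:
    """Single-fluorophore intensity from single-step bleaching traces.

    Per trace the intensity is mean(before step) - mean(after step); the
    calibration is the sample mean and SD of these differences.
    """
    if not traces:
        raise CalibrationError("no single-step bleaching traces")
    drops = []
    for tr in traces:
        x = tr.values
        cps, _ = best_k_changepoints(x, 1)
        cp = cps[0]
        drops.append(float(x[:cp].mean() - x[cp:].mean()))
    drops_arr = np.array(drops)
    sd = float(drops_arr.std(ddof=1)) if len(drops_arr) > 1 else 0.0
    return FluorophoreCalibration(mean_intensity=float(drops_arr.mean()),
                                  sd_intensity=sd, n_molecules=len(drops_arr))


# ---------------------------------------------------------------------------
# staircase fitting


def fit_steps(trace: IntensityTrace, calib: FluorophoreCalibration,
              step_size_search_sd: float = 2.0, penalty_factor: float = 3.0,
              n_grid: int = 81) -> StepFitResult:
    """Fit an equal-step staircase to one assembly intensity trace.

    The changepoint segmentation is computed once with penalty
    ``penalty_factor · σ̂² · log n`` (σ̂ from the robust SD of first
    differences).  Candidate step sizes span
    ``calib.mean ± step_size_search_sd · calib.sd``; for each, segment
    means quantize onto ``baseline + k·s`` (k >= 0, baseline = multiple of
    s nearest the pre-assembly mean) and total SSE is scored.  Among
    candidates within a small SSE slack the *largest* step size wins,
    which removes the sub-multiple degeneracy (s/2 reproduces the same
    levels with doubled counts).
    """
    x = trace.values
    n = len(x)
    if n < 5:
        raise UnfittableTraceError("trace shorter than 5 frames")

    sigma = max(_noise_sd(x), 1e-12)
    penalty = penalty_factor * sigma**2 * np.log(n)
    cps = segment_changepoints(x, penalty)
    bounds = [0] + cps + [n]
    seg_means = np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    seg_slices = list(zip(bounds[:-1], bounds[1:]))

    if trace.back_extended_frames > 0:
        pre_mean = float(x[:trace.back_extended_frames].mean())
    else:
        pre_mean = float(seg_means[0])

    lo = calib.mean_intensity - step_size_search_sd * calib.sd_intensity
    hi = calib.mean_intensity + step_size_search_sd * calib.sd_intensity
    lo = max(lo, 0.05 * calib.mean_intensity)
    grid = np.linspace(lo, hi, n_grid) if hi > lo else np.array([calib.mean_intensity])

    seg_lens = np.array([b - a for a, b in seg_slices], dtype=float)
    seg_sse = np.array([float(np.sum((x[a:b] - m) ** 2))
                        for (a, b), m in zip(seg_slices, seg_means)])

    def score(s0: float) -> tuple[float, float, np.ndarray, int]:
        """Quantize onto the lattice of s0, then refine s by least squares."""
        m0 = int(round(pre_mean / s0))
        counts = np.maximum(np.round((seg_means - m0 * s0) / s0), -m0).astype(int)
        total = counts + m0  # absolute lattice index, >= 0
        denom = float(np.sum(seg_lens * total.astype(float) ** 2))
        if denom > 0:
            s = float(np.sum(seg_lens * total * seg_means) / denom)
            s = min(max(s, lo), hi)
        else:
            s = s0
        levels = total * s
        sse = float(seg_sse.sum() + np.sum(seg_lens * (seg_means - levels) ** 2))
        return sse, s, counts, m0

    scored = [score(s0) for s0 in grid]
    sse_min = min(sc[0] for sc in scored)
    # a sub-multiple lattice can absorb ~sigma^2 of noise per segment mean;
    # allow that much slack so the coarsest equivalent lattice wins
    slack = 2.0 * sigma**2 * len(seg_means) + 1e-6 * max(sse_min, 1.0)
    # among (near-)optimal candidates the largest refined step size wins,
    # which collapses the sub-multiple (s/2, s/3, ...) degeneracy
    sse, s, counts, m0 = max((sc for sc in scored if sc[0] <= sse_min + slack),
                             key=lambda sc: sc[1])
    baseline = m0 * s

    count_trace = np.empty(n, dtype=int)
    for (a, b), k in zip(seg_slices, counts):
        count_trace[a:b] = k
    fitted_levels = baseline + count_trace * s
    deltas = np.diff(count_trace)
    step_times = [(int(i + 1), int(d)) for i, d in enumerate(deltas) if d != 0]
    residual = float(np.sum((x - fitted_levels) ** 2))
    return StepFitResult(step_size=float(s), baseline=float(baseline),
                         step_times=step_times, fitted_levels=fitted_levels,
                         count_trace=count_trace, residual_sse=residual,
                         traj_id=trace.traj_id)


def assembly_kinetics(results: list[StepFitResult]) -> dict:
    """Aggregate join/leave statistics over an ensemble of fitted staircases.

    Returns per-trace joins, leaves and maximum molecule counts plus a
    mean molecule-count-vs-frame summary over the ensemble.
    """
    if not results:
        raise ValueError("need at least one StepFitResult")
    joins = np.array([r.joins for r in results])
    leaves = np.array([r.leaves for r in results])
    max_counts = np.array([r.max_count for r in results])
    longest = max(len(r.count_trace) for r in results)
    sums = np.zeros(longest)
    cover = np.zeros(longest)
    for r in results:
        m = len(r.count_trace)
        sums[:m] += r.count_trace
        cover[:m] += 1
    mean_count = sums / np.maximum(cover, 1)
    return {
        "joins": joins,
        "leaves": leaves,
        "max_count": max_counts,
        "mean_count_per_frame": mean_count,
    }
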