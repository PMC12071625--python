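"""k-space image correlation spectroscopy (kICS) with a two-population model.

The spatial Fourier transform of every movie frame is correlated across
temporal lags; normalizing by the zero-lag correlation cancels the PSF
optical transfer function, and circularly averaging over |k|² assumes
isotropic diffusion.  For Brownian motion the normalized correlation at
lag τ decays as exp(−k² D τ), so a freely diffusing plus a confined
population produce a sum of two exponential decays in k².  Fitting that
sum per lag yields amplitude and decay-scale curves from which the two
diffusion coefficients, the free/confined amplitude ratio and a
confinement length are extracted.

Fluctuations that are spatially uniform (e.g. vesicles entering and
leaving the evanescent field) only contribute at k = 0, which is
excluded, making the analysis immune to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class KicsCF:
    """Circularly averaged, zero-lag-normalized correlation function.

    ``values[i, j]`` is R(k² = ksq[j], τ = tau[i]); the DC component is
    excluded and R(k², 0) = 1 by construction.
    """

    ksq: np.ndarray  # µm⁻², bin centers
    tau: np.ndarray  # seconds, including τ = 0
    values: np.ndarray  # (n_tau, n_bins)
    zero_lag_snr: np.ndarray | None = None  # (signal - noise floor)/floor per bin


@dataclass
class KicsDecays:
    """Per-lag two-exponential fit parameters (τ > 0 lags only)."""

    tau: np.ndarray
    a_free: np.ndarray
    a_conf: np.ndarray
    s_free: np.ndarray  # µm², decay scale of the fast (macro) component
    s_conf: np.ndarray  # µm², decay scale of the slow (micro) component
    valid: np.ndarray  # lags where the fit converged with usable signal
    ksq_min: float = 0.0  # smallest fitted k² (µm⁻²)


@dataclass
class KicsResult:
    """Extracted two-population diffusion/confinement parameters."""

    d_free: float  # µm²/s
    d_confined: float  # µm²/s
    amp_ratio_free_over_confined: float
    confinement_length: float  # µm
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.d_free, self.d_confined,
                  self.amp_ratio_free_over_confined, self.confinement_length):
            if v < 0:
                raise ValueError("kICS parameters must be >= 0")


def compute_kics_cf(stack, max_tau: int, n_k_bins: int = 64,
                    subtract_temporal_mean: bool = False,
                    noise_correction: bool = True) -> KicsCF:
    """Compute the circularly averaged, zero-lag-normalized kICS correlation.

    Per frame the 2D FFT is taken; the raw correlation r(k, τ) is the
    time average of F(k, t)·conj(F(k, t+τ)), normalized by r(k, 0) and
    binned uniformly in k² (DC excluded).  A strictly static movie is
    fully correlated (R = 1 everywhere).

    ``subtract_temporal_mean`` removes each pixel's temporal mean before
    the FFT.  It is off by default: the confined population's signal is
    quasi-static, so subtracting the mean destroys the late-lag plateau
    and the free/confined amplitude ratio; the excluded DC bin already
    makes the analysis immune to spatially uniform backgrounds.

    ``noise_correction`` subtracts the white (shot + read) noise floor —
    estimated from the high-k tail where the PSF transfer function has
    extinguished all signal — from the zero-lag normalization, so the
    normalization does not attenuate with k.
    """
    n_frames = stack.n_frames
    if not (1 <= max_tau < n_frames):
        raise ValueError("require n_frames > max_tau >= 1")
    data = np.asarray(stack.data, dtype=float)
    if subtract_temporal_mean:
        data = data - data.mean(axis=0, keepdims=True)
    F = np.fft.fft2(data, axes=(1, 2))

    h, w = data.shape[1:]
    ky = 2 * np.pi * np.fft.fftfreq(h, d=stack.pixel_size)
    kx = 2 * np.pi * np.fft.fftfreq(w, d=stack.pixel_size)
    ksq2d = ky[:, None] ** 2 + kx[None, :] ** 2

    r0 = np.mean(np.abs(F) ** 2, axis=0)
    # a strictly static movie (after mean subtraction) has no non-DC power at
    # all; treat it as fully correlated rather than dividing dust by dust
    non_dc_power = float(r0[ksq2d > 0].sum())
    dust = 1e-18 * (float(np.abs(data).max()) ** 2 + 1.0) * data[0].size
    all_static = non_dc_power <= dust
    if noise_correction:
        # white (shot + read) noise contributes a k-independent floor to the
        # zero-lag power only; estimate it from the high-k tail, where the
        # PSF optical transfer function has extinguished all signal, and
        # remove it so the normalization does not attenuate with k
        tail = ksq2d >= np.quantile(ksq2d, 0.9)
        floor = float(np.median(r0[tail]))
        r0_sig = np.maximum(r0 - floor, 1e-3 * floor if floor > 0 else 0.0)
    else:
        r0_sig = r0
    denom = np.where(r0_sig > 0, r0_sig, 1.0)

    edges = np.linspace(0, ksq2d.max(), n_k_bins + 1)
    which = np.digitize(ksq2d.ravel(), edges[1:-1])
    dc = ksq2d.ravel() == 0
    counts = np.bincount(which[~dc], minlength=n_k_bins).astype(float)
    counts[counts == 0] = np.nan
    ksq_centers = 0.5 * (edges[:-1] + edges[1:])

    values = np.empty((max_tau + 1, n_k_bins))
    for t_lag in range(max_tau + 1):
        if t_lag == 0 or all_static:
            R = np.ones_like(r0)
        else:
            r = np.mean(F[:-t_lag] * np.conj(F[t_lag:]), axis=0).real
            R = np.where(r0_sig > 0, r / denom, 0.0)
        values[t_lag] = np.bincount(which[~dc], weights=R.ravel()[~dc],
                                    minlength=n_k_bins) / counts

    keep = ~np.isnan(counts)
    if noise_correction and floor > 0:
        snr_grid = (r0 - floor) / floor
        snr = np.bincount(which[~dc], weights=snr_grid.ravel()[~dc],
                          minlength=n_k_bins) / counts
        snr = snr[keep]
    else:
        snr = None
    tau = np.arange(max_tau + 1) * stack.frame_interval
    return KicsCF(ksq=ksq_centers[keep], tau=tau, values=values[:, keep],
                  zero_lag_snr=snr)


def _double_exp(ksq, a_f, s_f, a_c, s_c):
    return a_f * np.exp(-ksq * s_f) + a_c * np.exp(-ksq * s_c)


def fit_decays(cf: KicsCF, ksq_max: float | None = None,
               min_signal: float = 0.02) -> KicsDecays:
    """Fit R(k², τ) at every lag with a sum of two exponential decays.

    ``ksq_max`` bounds the fitted k² range; by default it is the k² where
    the first-lag correlation falls below 0.05.  The fit is nonnegative
    nonlinear least squares, initialized from a single-exponential
    (log-linear) fit split ±50%; at each lag components are labelled so
    the free (macro) component has the larger decay scale.  Lags where
    the fit fails or the signal has decayed below ``min_signal`` are
    flagged invalid.
    """
    if ksq_max is None:
        # restrict to k² where the zero-lag signal power still dominates the
        # white-noise floor; beyond that the normalized CF is pure noise
        if cf.zero_lag_snr is not None:
            ok = np.where(cf.zero_lag_snr >= 1.0)[0]
            ksq_max = cf.ksq[ok[-1]] if len(ok) else cf.ksq[-1]
        else:
            first = cf.values[1] if len(cf.tau) > 1 else cf.values[0]
            below = np.where(first < 0.05)[0]
            ksq_max = cf.ksq[below[0]] if len(below) else cf.ksq[-1]
    sel = cf.ksq <= ksq_max
    if sel.sum() < 8:
        raise ValueError("need at least 8 k-bins below ksq_max")
    ksq = cf.ksq[sel]

    n_lags = len(cf.tau) - 1
    params = np.full((n_lags, 4), np.nan)  # a_f, s_f, a_c, s_c
    sses = np.full(n_lags, np.inf)
    valid = np.zeros(n_lags, dtype=bool)
    bounds = ([0.0, 0.0, 0.0, 0.0], [2.0, 1e3, 2.0, 1e3])

    def split_init(R: np.ndarray) -> list[float]:
        pos = R > 1e-6
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(ksq[pos], np.log(R[pos]), 1)
            a0 = min(float(np.exp(intercept)), 1.5)
            s0 = max(-float(slope), 1e-6)
        else:
            a0, s0 = float(np.clip(R.max(), 0.1, 1.5)), 1e-3
        return [0.5 * a0, 1.5 * s0, 0.5 * a0, 0.5 * s0]

    def try_fit(i: int, p0: list[float]) -> None:
        R = cf.values[i + 1][sel]
        p0 = list(np.clip(p0, [b + 1e-9 for b in bounds[0]], bounds[1]))
        try:
            popt, _ = curve_fit(_double_exp, ksq, R, p0=p0, bounds=bounds,
                                maxfev=5000)
        except (RuntimeError, ValueError):
            return
        sse = float(np.sum((R - _double_exp(ksq, *popt)) ** 2))
        if sse < sses[i]:
            params[i] = popt
            sses[i] = sse
            valid[i] = True

    signal_ok = np.array([np.nanmax(cf.values[i + 1][sel]) >= min_signal
                          for i in range(n_lags)])
    # pass 1: independent fits from the single-exponential split
    for i in range(n_lags):
        if signal_ok[i]:
            try_fit(i, split_init(cf.values[i + 1][sel]))
    # pass 2: continuation from late lags, where the two components are
    # well separated, back towards τ -> 0 (tracks the physical branch)
    prev = None
    for i in range(n_lags - 1, -1, -1):
        if not signal_ok[i]:
            prev = None
            continue
        if prev is not None:
            try_fit(i, list(prev))
        if valid[i]:
            prev = params[i]
    # pass 3: forward continuation for any stragglers
    prev = None
    for i in range(n_lags):
        if not signal_ok[i]:
            prev = None
            continue
        if prev is not None:
            try_fit(i, list(prev))
        if valid[i]:
            prev = params[i]

    # parsimony: when a single exponential fits (almost) as well, the
    # two-component split is arbitrary — collapse to one population
    def _single_exp(k, a, s):
        return a * np.exp(-k * s)

    for i in range(n_lags):
        if not valid[i]:
            continue
        R = cf.values[i + 1][sel]
        try:
            popt1, _ = curve_fit(_single_exp, ksq, R,
                                 p0=[float(np.clip(R.max(), 0.05, 1.5)), 1e-3],
                                 bounds=([0, 0], [2.0, 1e3]), maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        sse1 = float(np.sum((R - _single_exp(ksq, *popt1)) ** 2))
        if (sse1 - sses[i]) < 0.02 * max(sse1, 1e-30):
            params[i] = [popt1[0], popt1[1], 0.0, 0.0]

    a_f, s_f, a_c, s_c = (np.nan_to_num(params[:, j]) for j in range(4))
    swap = s_f < s_c
    a_f, a_c = np.where(swap, a_c, a_f), np.where(swap, a_f, a_c)
    s_f, s_c = np.where(swap, s_c, s_f), np.where(swap, s_f, s_c)
    return KicsDecays(tau=cf.tau[1:], a_free=a_f, a_conf=a_c,
                      s_free=s_f, s_conf=s_c, valid=valid,
                      ksq_min=float(ksq.min()))


def extract_parameters(decays: KicsDecays, frame_interval: float,
                       n_early_lags: int = 3,
                       late_lag_window: int | None = None) -> KicsResult:
    """Reduce per-lag decay curves to the four confinement parameters.

    D_free and D_confined are the slopes of the free/confined decay
    scales versus lag time over the first ``n_early_lags`` valid lags
    (s = D τ for Brownian motion).  The confinement length is
    2·sqrt(mean confined decay scale) over the last ``late_lag_window``
    valid lags (default: last 25 %), where the confined MSD has
    plateaued; the free/confined amplitude ratio is averaged over the
    same window.
    """
    idx = np.where(decays.valid)[0]
    if late_lag_window is None:
        late_lag_window = max(2, int(np.ceil(0.25 * len(idx))))
    if len(idx) < n_early_lags + late_lag_window:
        raise ValueError("not enough valid lags to extract parameters")
    early = idx[:n_early_lags]
    late = idx[-late_lag_window:]

    def slope(tau, s):
        if len(tau) == 1:
            return s[0] / tau[0]
        return np.polyfit(tau, s, 1)[0]

    d_free = max(float(slope(decays.tau[early], decays.s_free[early])), 0.0)
    d_conf = max(float(slope(decays.tau[early], decays.s_conf[early])), 0.0)
    s_c_late = float(np.mean(decays.s_conf[late]))
    conf_len = 2.0 * np.sqrt(max(s_c_late, 0.0))
    # amplitude ratio: read where the CF has collapsed into two resolved
    # populations (macro decaying at least 5x faster than micro) while the
    # macro amplitude is still anchored by the lowest-k bins; outside that
    # window the extrapolated macro amplitude is unreliable
    with np.errstate(divide="ignore", invalid="ignore"):
        resolved = decays.valid & (decays.s_free >= 5.0 * decays.s_conf)             & (decays.s_free * decays.ksq_min <= 1.0)
    window = np.where(resolved)[0] if resolved.any() else late
    ac = decays.a_conf[window]
    ratios = decays.a_free[window] / np.where(ac > 0, ac, np.nan)
    amp_ratio = float(np.nanmedian(ratios)) if np.any(np.isfinite(ratios)) else 0.0
    amp_ratio = max(amp_ratio, 0.0)
    return KicsResult(d_free=d_free, d_confined=d_conf,
                      amp_ratio_free_over_confined=amp_ratio,
                      confinement_length=conf_len,
                      diagnostics={"n_valid_lags": int(len(idx)),
                                   "late_lag_window": int(late_lag_window)})


def analyze(stack, max_tau: int, n_k_bins: int = 64,
            ksq_max: float | None = None, n_early_lags: int = 3,
            late_lag_window: int | None = None) -> KicsResult:
    """End-to-end kICS: correlation function → decay fits → parameters."""
    cf = compute_kics_cf(stack, max_tau=max_tau, n_k_bins=n_k_bins)
    decays = fit_decays(cf, ksq_max=ksq_max)
    return extract_parameters(decays, stack.frame_interval,
                              n_early_lags=n_early_lags,
                              late_lag_window=late_lag_window)
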