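"""Synthetic ground-truth data for every stage of the analysis pipeline.

The generators emulate the statistical structure the downstream analyses
assume:

* :func:`simulate_membrane_movie` — 2D membrane diffusion with a freely
  diffusing and a confined/trapped population, rendered as Gaussian PSFs
  on an EMCCD-like camera (Poisson shot noise, Gaussian read noise,
  constant offset), with exponential photobleaching.
* :func:`simulate_assembly_trace` — step-wise assembly intensity traces:
  a birth–death process of molecules whose single-fluorophore intensities
  follow the mCherry calibration (mean 111, SD 40 camera counts).
* :func:`simulate_point_pattern` — clustered two-channel SMLM point
  patterns (Neyman–Scott process) with tunable colocalization,
  localization precision jitter and blinking re-localizations.
* :func:`simulate_paired_traces` — two-channel traces with a known
  lead/lag for temporal cross-correlation ordering.

All generators are deterministic given their seed and return a
:class:`GroundTruth` record alongside the observable data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from latkit.core import ImageStack, IntensityTrace

logger = logging.getLogger(__name__)

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "intensity", "precision_nm", "channel"]


# ---------------------------------------------------------------------------
# configs


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class MembraneSimConfig:
    """Two-population membrane diffusion movie parameters.

    ``frac_confined`` of the molecules start inside circular domains of
    diameter ``domain_diameter`` and are reflected at the domain edge with
    probability ``trap_strength`` per attempted crossing; the rest diffuse
    freely.  ``membrane_photons`` adds diffuse cell fluorescence inside a
    circular "cell" covering ``cell_diameter_fraction`` of the field, so
    the cell-mask / membrane-mean steps of spot detection have a membrane
    to work with.
    """

    n_molecules: int = 200
    frac_confined: float = 0.5
    d_free: float = 0.2  # µm²/s
    d_confined: float = 0.01  # µm²/s
    domain_diameter: float = 0.4  # µm
    trap_strength: float = 1.0
    field_size: int = 64  # pixels, square
    pixel_size: float = 0.1  # µm
    frame_interval: float = 0.03  # s  (33.3 fps default, SPT uses 0.2 s)
    n_frames: int = 3000
    psf_sigma: float = 1.3  # pixels
    photons_per_molecule: float = 300.0  # mean counts/frame
    read_noise_sd: float = 2.0  # counts
    baseline: float = 10.0  # counts
    bleach_rate: float = 0.0  # 1/s
    membrane_photons: float = 0.0  # counts/pixel/frame inside the cell
    cell_diameter_fraction: float = 0.85
    shot_noise: bool = True
    min_separation: float = 0.0  # µm, minimum initial distance between molecules
    boundary: str = "reflect"  # "reflect" at the field edge, or "periodic"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_molecules >= 0, "n_molecules must be >= 0")
        _require(0.0 <= self.frac_confined <= 1.0, "frac_confined must be in [0,1]")
        _require(0.0 <= self.trap_strength <= 1.0, "trap_strength must be in [0,1]")
        _require(self.d_free >= 0 and self.d_confined >= 0, "diffusion coefficients must be >= 0")
        _require(self.domain_diameter > 0, "domain_diameter must be > 0")
        _require(self.field_size > 0 and self.pixel_size > 0, "field geometry must be > 0")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(self.psf_sigma > 0, "psf_sigma must be > 0")
        _require(self.photons_per_molecule >= 0, "photons_per_molecule must be >= 0")
        _require(self.read_noise_sd >= 0 and self.baseline >= 0, "noise terms must be >= 0")
        _require(self.bleach_rate >= 0, "bleach_rate must be >= 0")
        _require(0 < self.cell_diameter_fraction <= 1.0, "cell_diameter_fraction in (0,1]")
        _require(self.boundary in ("reflect", "periodic"), "boundary must be 'reflect' or 'periodic'")


@dataclass
class AssemblyTraceConfig:
    """Birth–death assembly trace parameters.

    Single-fluorophore intensities default to the mCherry calibration
    (mean 111, SD 40 counts).  ``brightness_mode`` selects whether the
    intensity is drawn once per molecule ("per_molecule") or once per
    trace ("per_trace", an equal-step staircase whose unit varies from
    trace to trace).
    """

    arrival_rate: float = 0.5  # molecules/s
    departure_rate: float = 0.0  # 1/s per molecule
    single_intensity_mean: float = 111.0  # counts
    single_intensity_sd: float = 40.0  # counts
    bleach_rate: float = 0.0  # 1/s per molecule
    frame_interval: float = 0.2  # s
    n_frames: int = 300
    noise_sd: float = 20.0  # counts
    brightness_mode: str = "per_molecule"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.arrival_rate >= 0, "arrival_rate must be >= 0")
        _require(self.departure_rate >= 0, "departure_rate must be >= 0")
        _require(self.single_intensity_mean > 0, "single_intensity_mean must be > 0")
        _require(self.single_intensity_sd >= 0, "single_intensity_sd must be >= 0")
        _require(self.bleach_rate >= 0, "bleach_rate must be >= 0")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.brightness_mode in ("per_molecule", "per_trace"),
                 "brightness_mode must be 'per_molecule' or 'per_trace'")


@dataclass
class PointPatternConfig:
    """Two-channel clustered SMLM point pattern (Neyman–Scott) parameters."""

    roi_size: float = 4000.0  # nm, square
    cluster_density: float = 2.0  # clusters/µm²
    molecules_per_cluster_mean: float = 30.0
    cluster_sigma: float = 40.0  # nm
    background_density: float = 20.0  # molecules/µm²
    coloc_fraction: float = 0.0
    loc_precision_sd: float = 25.0  # nm (mean precision reported ~25.6 nm)
    blink_duplication_rate: float = 0.0  # extra localizations per molecule
    blink_frame_gap_max: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.roi_size > 0, "roi_size must be > 0")
        _require(self.cluster_density >= 0, "cluster_density must be >= 0")
        _require(self.molecules_per_cluster_mean >= 0, "molecules_per_cluster_mean >= 0")
        _require(self.cluster_sigma >= 0, "cluster_sigma must be >= 0")
        _require(self.background_density >= 0, "background_density must be >= 0")
        _require(0.0 <= self.coloc_fraction <= 1.0, "coloc_fraction must be in [0,1]")
        _require(self.loc_precision_sd >= 0, "loc_precision_sd must be >= 0")
        _require(self.blink_duplication_rate >= 0, "blink_duplication_rate >= 0")
        _require(self.blink_frame_gap_max >= 1, "blink_frame_gap_max must be >= 1")


@dataclass
class GroundTruth:
    """Ground-truth record returned by every generator.

    Only the fields relevant to the generator that produced it are set.
    """

    # membrane movie
    positions_um: np.ndarray | None = None  # (n_frames, n_molecules, 2)
    population: np.ndarray | None = None  # "free" / "confined" per molecule
    bleach_frame: np.ndarray | None = None  # first dark frame per molecule
    domain_centers_um: np.ndarray | None = None
    domain_diameter_um: float | None = None
    # assembly trace
    staircase: np.ndarray | None = None  # molecule count per frame
    molecule_intensities: np.ndarray | None = None
    arrival_frames: np.ndarray | None = None
    departure_frames: np.ndarray | None = None
    # point pattern
    molecule_ids: np.ndarray | None = None  # per localization
    cluster_ids: np.ndarray | None = None  # per molecule, -1 = background
    molecule_channels: np.ndarray | None = None
    molecule_positions_nm: np.ndarray | None = None
    shared_center_clusters: np.ndarray | None = None
    # paired traces
    delta_frames: int | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, np.ndarray):
                out[key] = value.tolist()
            else:
                out[key] = value
        return out


# ---------------------------------------------------------------------------
# membrane movie


def _render_frame(photons: np.ndarray, xy_px: np.ndarray, flux: np.ndarray,
                  sigma: float, periodic: bool = False) -> None:
    """Accumulate Gaussian PSF stamps (in place) onto a photon image.

    ``xy_px`` holds sub-pixel molecule centers in pixel units; ``flux``
    the total expected photons of each molecule this frame.  With
    ``periodic`` the stamps wrap around the field edges (no clipped-PSF
    edge artifacts; matches the FFT's periodic boundary).
    """
    size = photons.shape[0]
    half = int(np.ceil(4 * sigma))
    ax = np.arange(-half, half + 1)
    norm = 2 * np.pi * sigma**2
    for (x, y), f in zip(xy_px, flux):
        if f <= 0:
            continue
        cx, cy = int(round(x)), int(round(y))
        if not periodic and (cx < -half or cx >= size + half
                             or cy < -half or cy >= size + half):
            continue
        gx = np.exp(-((ax + cx - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ax + cy - y) ** 2) / (2 * sigma**2))
        stamp = (f / norm) * np.outer(gy, gx)
        if periodic:
            ys = (cy + ax) % size
            xs = (cx + ax) % size
            np.add.at(photons, (ys[:, None], xs[None, :]), stamp)
            continue
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        sy0, sx0 = max(0, -y0), max(0, -x0)
        sy1 = stamp.shape[0] - max(0, y1 - size)
        sx1 = stamp.shape[1] - max(0, x1 - size)
        if sy1 <= sy0 or sx1 <= sx0:
            continue
        photons[max(0, y0):min(size, y1), max(0, x0):min(size, x1)] += \
            stamp[sy0:sy1, sx0:sx1]


def simulate_membrane_movie(cfg: MembraneSimConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate a TIRF movie of membrane molecules with two diffusive populations.

    Free molecules perform Brownian steps with ``d_free`` and reflect at
    the field edge.  Confined molecules diffuse with ``d_confined`` inside
    a circular domain; a step that would cross the domain boundary is
    reflected with probability ``trap_strength`` and otherwise escapes the
    domain (re-entry is unhindered).  Molecules bleach irreversibly with
    rate ``bleach_rate`` and render as 2D Gaussian PSFs; the camera model
    is Poisson shot noise plus Gaussian read noise and a constant offset.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_molecules
    field_um = cfg.field_size * cfg.pixel_size
    dt = cfg.frame_interval

    rms_step = np.sqrt(4 * cfg.d_confined * dt)
    if cfg.domain_diameter <= 2 * rms_step:
        logger.warning(
            "domain_diameter (%.3g µm) <= 2x RMS step (%.3g µm): confinement "
            "is unresolvable at this frame interval", cfg.domain_diameter, 2 * rms_step)

    n_conf = int(round(cfg.frac_confined * n))
    population = np.array(["confined"] * n_conf + ["free"] * (n - n_conf))

    cell_r = 0.5 * cfg.cell_diameter_fraction * field_um
    center = np.array([field_um / 2, field_um / 2])

    # one circular domain per confined molecule, fully inside the cell
    dom_r = cfg.domain_diameter / 2
    max_r = max(cell_r - dom_r, 1e-6)
    theta = rng.uniform(0, 2 * np.pi, n_conf)
    rad = max_r * np.sqrt(rng.uniform(0, 1, n_conf))
    domain_centers = center + np.c_[rad * np.cos(theta), rad * np.sin(theta)]

    def _place(base: np.ndarray, radius: float, count: int,
               existing: list[np.ndarray]) -> np.ndarray:
        """Uniform placement in discs with optional rejection for separation."""
        placed = np.empty((count, 2))
        for i in range(count):
            c = base[i] if base.ndim == 2 else base
            for _ in range(200):
                th = rng.uniform(0, 2 * np.pi)
                rr = radius * np.sqrt(rng.uniform(0, 1))
                p = c + np.array([rr * np.cos(th), rr * np.sin(th)])
                if cfg.min_separation <= 0 or not existing or \
                        min(np.hypot(*(p - q)) for q in existing) >= cfg.min_separation:
                    break
            placed[i] = p
            existing.append(p)
        return placed

    existing: list[np.ndarray] = []
    pos = np.empty((n, 2))
    if n_conf:
        pos[:n_conf] = _place(domain_centers, dom_r, n_conf, existing)
    n_free = n - n_conf
    if n_free:
        pos[n_conf:] = _place(center, cell_r, n_free, existing)

    if cfg.bleach_rate > 0:
        bleach_t = rng.exponential(1.0 / cfg.bleach_rate, n)
        bleach_frame = np.ceil(bleach_t / dt).astype(int)
    else:
        bleach_frame = np.full(n, cfg.n_frames + 1, dtype=int)

    sig_free = np.sqrt(2 * cfg.d_free * dt)
    sig_conf = np.sqrt(2 * cfg.d_confined * dt)
    sigma_step = np.where(population == "confined", sig_conf, sig_free)

    # pre-build cell mask for the diffuse membrane background
    yy, xx = np.mgrid[0:cfg.field_size, 0:cfg.field_size]
    px_centers = (np.stack([xx, yy], axis=-1) + 0.5) * cfg.pixel_size
    in_cell = np.linalg.norm(px_centers - center, axis=-1) <= cell_r

    positions = np.empty((cfg.n_frames, n, 2))
    frames = np.empty((cfg.n_frames, cfg.field_size, cfg.field_size), dtype=np.float32)

    for t in range(cfg.n_frames):
        positions[t] = pos
        photons = np.zeros((cfg.field_size, cfg.field_size))
        if cfg.membrane_photons > 0:
            photons[in_cell] += cfg.membrane_photons
        active = bleach_frame > t
        if np.any(active) and cfg.photons_per_molecule > 0:
            _render_frame(photons, pos[active] / cfg.pixel_size,
                          np.full(active.sum(), cfg.photons_per_molecule),
                          cfg.psf_sigma, periodic=cfg.boundary == "periodic")
        if cfg.shot_noise and photons.max() > 0:
            img = rng.poisson(photons).astype(float)
        else:
            img = photons.copy()
        img = img + cfg.baseline
        if cfg.read_noise_sd > 0:
            img = img + rng.normal(0, cfg.read_noise_sd, img.shape)
        frames[t] = img.astype(np.float32)

        if t == cfg.n_frames - 1:
            break

        steps = rng.normal(0, 1, (n, 2)) * sigma_step[:, None]
        new = pos + steps
        # confined molecules: reflect at the domain boundary with prob trap_strength,
        # but only for inside -> outside moves
        if n_conf:
            rel = new[:n_conf] - domain_centers
            dist = np.linalg.norm(rel, axis=1)
            was_in = np.linalg.norm(pos[:n_conf] - domain_centers, axis=1) <= dom_r
            crossing = was_in & (dist > dom_r)
            if np.any(crossing):
                reflect = rng.uniform(0, 1, n_conf) < cfg.trap_strength
                do = crossing & reflect
                if np.any(do):
                    d = dist[do]
                    new_d = np.clip(2 * dom_r - d, 0, dom_r)
                    new[:n_conf][do] = (domain_centers[do]
                                        + rel[do] * (new_d / d)[:, None])
        if cfg.boundary == "periodic":
            pos = np.mod(new, field_um)
        else:
            # everyone reflects at the field boundary
            new = np.where(new < 0, -new, new)
            new = np.where(new > field_um, 2 * field_um - new, new)
            pos = np.clip(new, 0, field_um)

    stack = ImageStack(frames, pixel_size=cfg.pixel_size, frame_interval=dt)
    gt = GroundTruth(
        positions_um=positions,
        population=population,
        bleach_frame=bleach_frame,
        domain_centers_um=domain_centers,
        domain_diameter_um=cfg.domain_diameter,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# assembly traces


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) truncated to strictly positive values (rejection)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def simulate_assembly_trace(cfg: AssemblyTraceConfig) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one step-wise assembly intensity trace.

    The molecule count follows a birth–death process: Poisson arrivals at
    ``arrival_rate`` and independent exponential departures (rate
    ``departure_rate + bleach_rate`` per molecule; a bleach ends the
    fluorescence just like a departure).  Each molecule's intensity is
    drawn once from a truncated normal and contributes until it leaves,
    so the trace is a staircase plus Gaussian readout noise.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval
    n = cfg.n_frames

    p_arrive = cfg.arrival_rate * dt
    leave_rate = cfg.departure_rate + cfg.bleach_rate
    p_leave = 1.0 - np.exp(-leave_rate * dt) if leave_rate > 0 else 0.0

    trace_unit = _truncated_normal(rng, cfg.single_intensity_mean,
                                   cfg.single_intensity_sd, 1)[0]

    intensities: list[float] = []
    arrival_frames: list[int] = []
    departure_frames: list[int] = []
    active: list[int] = []  # indices of present molecules
    staircase = np.zeros(n, dtype=int)
    signal = np.zeros(n)

    for t in range(n):
        for _ in range(rng.poisson(p_arrive)):
            if cfg.brightness_mode == "per_trace":
                inten = trace_unit
            else:
                inten = _truncated_normal(rng, cfg.single_intensity_mean,
                                          cfg.single_intensity_sd, 1)[0]
            intensities.append(inten)
            arrival_frames.append(t)
            departure_frames.append(n)  # provisional: still present at end
            active.append(len(intensities) - 1)
        if p_leave > 0 and active:
            keep = rng.uniform(0, 1, len(active)) >= p_leave
            for idx, k in zip(list(active), keep):
                if not k:
                    departure_frames[idx] = t
            active = [idx for idx, k in zip(active, keep) if k]
        staircase[t] = len(active)
        signal[t] = sum(intensities[i] for i in active)

    values = signal + (rng.normal(0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0)
    trace = IntensityTrace(values, frame_interval=dt)
    gt = GroundTruth(
        staircase=staircase,
        molecule_intensities=np.array(intensities),
        arrival_frames=np.array(arrival_frames, dtype=int),
        departure_frames=np.array(departure_frames, dtype=int),
    )
    return trace, gt


# ---------------------------------------------------------------------------
# point patterns


def simulate_point_pattern(cfg: PointPatternConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a two-channel clustered SMLM localization table.

    Channel A is a Neyman–Scott process (Poisson cluster centers, Gaussian
    offspring) over uniform background.  Channel B re-uses a
    ``coloc_fraction`` of channel-A cluster centers and draws the rest
    fresh.  Each molecule emits ``1 + Poisson(blink_duplication_rate)``
    localizations, each jittered by the localization precision and spread
    over frames with inter-blink gaps of at most ``blink_frame_gap_max``.
    """
    rng = np.random.default_rng(cfg.seed)
    area_um2 = (cfg.roi_size / 1000.0) ** 2

    def draw_members(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos_list, cid_list = [], []
        for cid, c in enumerate(centers):
            m = rng.poisson(cfg.molecules_per_cluster_mean)
            if m == 0:
                continue
            pos_list.append(c + rng.normal(0, cfg.cluster_sigma, (m, 2)))
            cid_list.append(np.full(m, cid))
        if not pos_list:
            return np.empty((0, 2)), np.empty(0, dtype=int)
        return np.vstack(pos_list), np.concatenate(cid_list)

    # channel A centers
    n_clus_a = rng.poisson(cfg.cluster_density * area_um2)
    centers_a = rng.uniform(0, cfg.roi_size, (n_clus_a, 2))
    # channel B centers: share a fraction of A's
    n_clus_b = rng.poisson(cfg.cluster_density * area_um2)
    n_shared = min(int(round(cfg.coloc_fraction * n_clus_b)), n_clus_a)
    shared_idx = rng.choice(n_clus_a, n_shared, replace=False) if n_shared else np.empty(0, int)
    centers_b = np.vstack([
        centers_a[shared_idx] if n_shared else np.empty((0, 2)),
        rng.uniform(0, cfg.roi_size, (n_clus_b - n_shared, 2)),
    ])

    mol_pos, mol_cid, mol_chan = [], [], []
    shared_flags = np.zeros(max(n_clus_a, 1), dtype=bool)
    shared_flags[:0] = False
    if n_shared:
        flags = np.zeros(n_clus_a, dtype=bool)
        flags[shared_idx] = True
        shared_flags = flags
    else:
        shared_flags = np.zeros(n_clus_a, dtype=bool)

    for chan, centers in (("A", centers_a), ("B", centers_b)):
        cpos, ccid = draw_members(centers)
        n_bg = rng.poisson(cfg.background_density * area_um2)
        bpos = rng.uniform(0, cfg.roi_size, (n_bg, 2))
        mol_pos.append(np.vstack([cpos, bpos]))
        mol_cid.append(np.concatenate([ccid, np.full(n_bg, -1)]))
        mol_chan.append(np.array([chan] * (len(cpos) + n_bg)))

    positions = np.vstack(mol_pos) if mol_pos else np.empty((0, 2))
    cluster_ids = np.concatenate(mol_cid)
    channels = np.concatenate(mol_chan)
    n_mol = len(positions)

    rows = []
    mol_of_loc = []
    for i in range(n_mol):
        n_loc = 1 + rng.poisson(cfg.blink_duplication_rate)
        first = int(rng.integers(0, 10000))
        frame = first
        for j in range(n_loc):
            if j > 0:
                frame += int(rng.integers(1, cfg.blink_frame_gap_max + 1))
            xy = positions[i] + rng.normal(0, cfg.loc_precision_sd, 2)
            rows.append((frame, xy[0], xy[1],
                         float(rng.gamma(5.0, 100.0)), cfg.loc_precision_sd,
                         channels[i]))
            mol_of_loc.append(i)
    table = pd.DataFrame(rows, columns=LOC_COLUMNS)
    if len(table):
        table = table.astype({"frame": int, "x_nm": float, "y_nm": float,
                              "intensity": float, "precision_nm": float})
    gt = GroundTruth(
        molecule_ids=np.array(mol_of_loc, dtype=int),
        cluster_ids=cluster_ids,
        molecule_channels=channels,
        molecule_positions_nm=positions,
        shared_center_clusters=shared_flags,
        extras={"n_clusters_a": int(n_clus_a), "n_clusters_b": int(n_clus_b),
                "centers_a": centers_a.tolist(), "centers_b": centers_b.tolist()},
    )
    return table, gt


# ---------------------------------------------------------------------------
# paired traces


def simulate_paired_traces(delta_frames: int, n_frames: int, noise_sd: float,
                           seed: int, amplitude: float = 9.0,
                           rise_frames: float = 4.0,
                           baseline: float = 5.0) -> tuple[IntensityTrace, IntensityTrace, GroundTruth]:
    """Simulate two assembly-like traces where channel 2 lags channel 1.

    Trace 1 is a smoothed rising step (logistic ramp from ``baseline`` to
    ``baseline + amplitude``); trace 2 is the same ramp delayed by
    ``delta_frames`` frames.  ``noise_sd`` is the independent Gaussian
    noise SD expressed as a fraction of the amplitude.  The baseline
    emulates the positive camera/membrane background of real intensity
    traces; it keeps the pre-assembly value safely above zero so the
    first-time-point normalization is well defined at realistic noise.
    """
    if abs(delta_frames) >= n_frames / 2:
        raise ValueError("|delta_frames| must be < n_frames/2")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float)
    onset = n_frames / 3.0

    def ramp(shift: float) -> np.ndarray:
        return baseline + amplitude / (1.0 + np.exp(-(t - onset - shift) / rise_frames))

    t1 = ramp(0.0)
    t2 = ramp(float(delta_frames))
    if noise_sd > 0:
        t1 = t1 + rng.normal(0, noise_sd * amplitude, n_frames)
        t2 = t2 + rng.normal(0, noise_sd * amplitude, n_frames)
    trace1 = IntensityTrace(t1, frame_interval=0.2)
    trace2 = IntensityTrace(t2, frame_interval=0.2)
    return trace1, trace2, GroundTruth(delta_frames=delta_frames)
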