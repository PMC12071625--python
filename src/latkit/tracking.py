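"""Spot detection, overlap linking and trajectory filtering for TIRF movies.

Detection follows a two-stage scheme: a cell mask is derived from a
coarsely median-filtered frame (Otsu threshold, then expanded), after
which spots are enhanced (Gaussian smoothing + white top-hat) and
accepted wherever the local 6-px-disc mean intensity exceeds
``intensity_ratio`` times the mean intensity of the surrounding membrane.
Linking is greedy frame-to-frame nearest-neighbour matching with a
Chebyshev gate of 3 pixels and no gap closing; trajectories must span at
least two consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian, median, threshold_otsu
from skimage.morphology import dilation, disk, white_tophat
from skimage.feature import peak_local_max

from latkit.core import ImageStack, IntensityTrace


@dataclass
class Detection:
    """One detected assembly in one frame (0-based pixel coordinates)."""

    frame: int
    x: float
    y: float
    mean_intensity: float  # mean within the 6-px-diameter disc
    total_intensity: float  # sum within the disc


@dataclass
class Trajectory:
    """Linked detections of one assembly on strictly consecutive frames."""

    id: int
    detections: list[Detection]
    intensity_trace: IntensityTrace | None = None
    diffusion_coefficient: float | None = field(default=None)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def origin_frame(self) -> int:
        return self.detections[0].frame

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections])


def _disc_offsets(diameter: int) -> tuple[np.ndarray, np.ndarray]:
    r = diameter / 2.0
    half = int(np.floor(r))
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1]
    keep = dx**2 + dy**2 <= r**2
    return dy[keep], dx[keep]


def disc_mean(img: np.ndarray, x: float, y: float, diameter: int = 6) -> float:
    """Mean intensity within a disc of the given pixel diameter at (x, y)."""
    dy, dx = _disc_offsets(diameter)
    cy, cx = int(round(y)), int(round(x))
    ys = np.clip(cy + dy, 0, img.shape[0] - 1)
    xs = np.clip(cx + dx, 0, img.shape[1] - 1)
    return float(img[ys, xs].mean())


def _disc_sum(img: np.ndarray, x: float, y: float, diameter: int = 6) -> float:
    dy, dx = _disc_offsets(diameter)
    cy, cx = int(round(y)), int(round(x))
    ys = np.clip(cy + dy, 0, img.shape[0] - 1)
    xs = np.clip(cx + dx, 0, img.shape[1] - 1)
    return float(img[ys, xs].sum())


def _cell_mask(frame: np.ndarray, median_px: int, expand_px: int) -> np.ndarray:
    smooth = median(frame.astype(float), footprint=disk(median_px // 2))
    if smooth.max() == smooth.min():
        return np.zeros_like(frame, dtype=bool)
    mask = smooth > threshold_otsu(smooth)
    return dilation(mask, disk(expand_px))


def detect_assemblies(stack: ImageStack, spot_diameter_px: int = 6,
                      intensity_ratio: float = 2.0, gaussian_sigma_px: float = 2.0,
                      cell_median_px: int = 30, cell_expand_px: int = 8
                      ) -> list[list[Detection]]:
    """Detect bright assemblies in every frame of a TIRF movie.

    Returns one list of :class:`Detection` per frame.  A frame with an
    empty cell mask (or no contrast) yields an empty list.  Candidate
    spots are local maxima of the enhanced image inside the cell mask;
    a candidate is accepted if its 6-px-disc mean in the raw frame is at
    least ``intensity_ratio`` times the membrane mean (mean of masked
    pixels outside all candidate discs).  Touching candidates are kept
    apart by the local-maximum separation; positions are refined to the
    intensity-weighted centroid of the enhanced image in the disc.
    """
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    out: list[list[Detection]] = []
    dy_d, dx_d = _disc_offsets(spot_diameter_px)
    for t in range(stack.n_frames):
        frame = np.asarray(stack.data[t], dtype=float)
        mask = _cell_mask(frame, cell_median_px, cell_expand_px)
        if not mask.any():
            out.append([])
            continue
        sm = gaussian(frame, sigma=gaussian_sigma_px, preserve_range=True)
        enh = white_tophat(sm, disk(spot_diameter_px // 2))
        enh = np.where(mask, enh, 0.0)
        if enh.max() <= 0:
            out.append([])
            continue
        peaks = peak_local_max(enh, min_distance=max(1, spot_diameter_px // 3),
                               threshold_abs=1e-3 * enh.max(), exclude_border=False)
        if len(peaks) == 0:
            out.append([])
            continue
        # membrane mean: masked pixels away from any candidate disc
        spot_mask = np.zeros_like(mask)
        for py, px in peaks:
            ys = np.clip(py + dy_d, 0, frame.shape[0] - 1)
            xs = np.clip(px + dx_d, 0, frame.shape[1] - 1)
            spot_mask[ys, xs] = True
        membrane = mask & ~spot_mask
        membrane_mean = float(frame[membrane].mean()) if membrane.any() \
            else float(frame[mask].mean())
        dets: list[Detection] = []
        for py, px in peaks:
            local_mean = disc_mean(frame, px, py, spot_diameter_px)
            if membrane_mean > 0 and local_mean < intensity_ratio * membrane_mean:
                continue
            if membrane_mean <= 0 and local_mean <= 0:
                continue
            # centroid refinement on the enhanced image
            ys = np.clip(py + dy_d, 0, frame.shape[0] - 1)
            xs = np.clip(px + dx_d, 0, frame.shape[1] - 1)
            w = enh[ys, xs]
            if w.sum() > 0:
                cx = float((xs * w).sum() / w.sum())
                cy = float((ys * w).sum() / w.sum())
            else:
                cx, cy = float(px), float(py)
            dets.append(Detection(frame=t, x=cx, y=cy,
                                  mean_intensity=local_mean,
                                  total_intensity=_disc_sum(frame, cx, cy,
                                                            spot_diameter_px)))
        out.append(dets)
    return out


def link_trajectories(detections: list[list[Detection]],
                      max_shift_px: float = 3.0) -> list[Trajectory]:
    """Greedy frame-to-frame linking with a Chebyshev gate and no gap closing.

    A detection in frame ``t+1`` continues the trajectory whose frame-``t``
    detection is nearest in Euclidean distance among those within
    ``max_shift_px`` in both x and y.  Ties break on smaller distance,
    then lower trajectory id.  A trajectory ends on its first undetected
    frame; trajectories shorter than two frames are discarded.
    """
    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0
    for t, dets in enumerate(detections):
        candidates = []
        for traj in active:
            last = traj.detections[-1]
            for j, det in enumerate(dets):
                if abs(det.x - last.x) <= max_shift_px and \
                   abs(det.y - last.y) <= max_shift_px:
                    dist = np.hypot(det.x - last.x, det.y - last.y)
                    candidates.append((dist, traj.id, traj, j))
        candidates.sort(key=lambda c: (c[0], c[1]))
        used_traj: set[int] = set()
        used_det: set[int] = set()
        extended: list[Trajectory] = []
        for dist, tid, traj, j in candidates:
            if tid in used_traj or j in used_det:
                continue
            traj.detections.append(dets[j])
            used_traj.add(tid)
            used_det.add(j)
            extended.append(traj)
        for traj in active:
            if traj.id not in used_traj:
                trajectories.append(traj)
        for j, det in enumerate(dets):
            if j not in used_det:
                extended.append(Trajectory(id=next_id, detections=[det]))
                next_id += 1
        active = extended
    trajectories.extend(active)
    kept = [tr for tr in trajectories if len(tr) >= 2]
    kept.sort(key=lambda tr: tr.id)
    return kept


def diffusion_coefficient(traj: Trajectory, pixel_size: float,
                          frame_interval: float, max_lag: int = 4) -> float | None:
    """MSD-based diffusion coefficient (µm²/s) of one trajectory.

    The time-averaged MSD at lags 1..``max_lag`` is fitted with an
    unweighted least-squares line MSD = 4 D τ + b; negative slopes clip
    to zero.  Trajectories shorter than ``max_lag + 1`` frames return
    ``None`` (excluded from D-based filters).
    """
    if len(traj) < max_lag + 1:
        return None
    pos = traj.positions * pixel_size
    taus = np.arange(1, max_lag + 1)
    msd = np.array([np.mean(np.sum((pos[lag:] - pos[:-lag]) ** 2, axis=1))
                    for lag in taus])
    tsec = taus * frame_interval
    slope = np.polyfit(tsec, msd, 1)[0]
    return max(slope / 4.0, 0.0)


def filter_and_extend(trajs: list[Trajectory], stack: ImageStack,
                      min_frames: int = 30, max_D: float = 0.05,
                      back_frames: int = 20,
                      spot_diameter_px: int = 6) -> list[Trajectory]:
    """Select long-lived, immobile, late-starting trajectories and
    back-extend their intensity traces.

    Keeps trajectories with length >= ``min_frames``, diffusion
    coefficient < ``max_D`` and first detection after frame 0, then
    prepends to each trace the 6-px-disc mean intensity at the first
    detected position for the ``back_frames`` preceding frames (fewer if
    the movie starts earlier).
    """
    kept: list[Trajectory] = []
    for traj in trajs:
        if len(traj) < min_frames:
            continue
        if traj.diffusion_coefficient is None or traj.diffusion_coefficient >= max_D:
            continue
        origin = traj.origin_frame
        if origin <= 0:
            continue
        first = traj.detections[0]
        n_back = min(back_frames, origin)
        pre = [disc_mean(np.asarray(stack.data[f], dtype=float), first.x, first.y,
                         spot_diameter_px)
               for f in range(origin - n_back, origin)]
        values = np.concatenate([pre, [d.mean_intensity for d in traj.detections]])
        traj.intensity_trace = IntensityTrace(
            values, frame_interval=stack.frame_interval, origin_frame=origin,
            back_extended_frames=n_back, traj_id=traj.id)
        kept.append(traj)
    return kept


def build_traces(trajs: list[Trajectory], frame_interval: float) -> list[IntensityTrace]:
    """Intensity traces (disc means) of trajectories without back-extension."""
    out = []
    for traj in trajs:
        values = np.array([d.mean_intensity for d in traj.detections])
        out.append(IntensityTrace(values, frame_interval=frame_interval,
                                  origin_frame=traj.origin_frame, traj_id=traj.id))
    return out
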