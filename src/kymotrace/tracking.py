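"""Sub-pixel particle tracking on kymographs.

Pipeline: crop saturated bead margins -> per-line Gaussian localization on a
three-line moving-window average -> greedy nearest-neighbour linking ->
Savitzky-Golay smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from kymotrace.io import Kymograph, Localization, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["TrackingConfig", "crop_beads", "localize", "link", "smooth"]


@dataclass
class TrackingConfig:
    window_frames: int = 3
    detect_threshold_sd: float = 3.0
    max_step_um: float = 0.5
    max_gap_frames: int = 3
    min_track_frames: int = 10
    sg_window: int = 51
    sg_order: int = 3
    overlap_radius_px: float = 3.0
    sigma_bounds_px: tuple[float, float] = (0.8, 4.0)
    fit_halfwidth_px: int = 6

    def __post_init__(self) -> None:
        if self.window_frames % 2 != 1:
            raise ValueError("window_frames must be odd")
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")


def crop_beads(kymo: Kymograph, saturation_quantile: float = 0.999) -> Kymograph:
    """Remove contiguous saturated columns at both edges.

    A column is saturated when its median intensity reaches the
    ``saturation_quantile`` quantile of the whole image.  ``origin_offset``
    is advanced so physical coordinates are unchanged.
    """
    ref = next(iter(kymo.channels.values()))
    thresh = np.quantile(ref, saturation_quantile)
    col_med = np.median(ref, axis=0)
    saturated = col_med >= thresh
    left = 0
    while left < saturated.size and saturated[left]:
        left += 1
    right = saturated.size
    while right > left and saturated[right - 1]:
        right -= 1
    if right <= left:
        raise ValueError("whole image saturated")
    if left == 0 and right == saturated.size:
        return kymo
    channels = {ch: a[:, left:right].copy() for ch, a in kymo.channels.items()}
    return Kymograph(
        channels=channels,
        pixel_size_nm=kymo.pixel_size_nm,
        line_time_s=kymo.line_time_s,
        origin_offset=kymo.origin_offset + left,
    )


def _gaussian(x, amp, mu, sigma, offset):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def _line_background(profile: np.ndarray) -> tuple[float, float]:
    """(background level, noise SD) — median/MAD, robust to sparse peaks."""
    med = float(np.median(profile))
    mad = float(np.median(np.abs(profile - med)))
    return med, max(1.4826 * mad, 1e-9)


def localize(kymo: Kymograph, channel: str, cfg: TrackingConfig | None = None) -> list[Localization]:
    """Sub-pixel localizations from per-line 1D Gaussian fits.

    For each scan line the column profile is averaged over a centered
    ``window_frames`` window, candidate peaks above
    ``background + detect_threshold_sd * SD`` are fit with
    amplitude/center/sigma/offset, and implausible fits are discarded.
    """
    cfg = cfg or TrackingConfig()
    img = kymo.channels[channel]
    n_lines, width = img.shape
    half = cfg.window_frames // 2
    x = np.arange(width, dtype=float)
    out: list[Localization] = []
    n_peaks = n_rejected = 0

    for t in range(n_lines):
        lo, hi = max(0, t - half), min(n_lines, t + half + 1)
        profile = img[lo:hi].mean(axis=0)
        bg, sd = _line_background(profile)
        height = bg + cfg.detect_threshold_sd * sd
        peaks, _ = find_peaks(profile, height=height, distance=3)
        for pk in peaks:
            n_peaks += 1
            a = max(0, pk - cfg.fit_halfwidth_px)
            b = min(width, pk + cfg.fit_halfwidth_px + 1)
            xs, ys = x[a:b], profile[a:b]
            try:
                popt, _ = curve_fit(
                    _gaussian,
                    xs,
                    ys,
                    p0=[profile[pk] - bg, float(pk), 1.5, bg],
                    bounds=(
                        [0.0, a - 1.0, cfg.sigma_bounds_px[0] / 2, -np.inf],
                        [np.inf, b + 1.0, cfg.sigma_bounds_px[1] * 2, np.inf],
                    ),
                    maxfev=2000,
                )
            except RuntimeError:
                n_rejected += 1
                continue
            amp, mu, sigma, offset = popt
            if (
                amp <= (cfg.detect_threshold_sd + 1.0) * sd
                or not (cfg.sigma_bounds_px[0] <= sigma <= cfg.sigma_bounds_px[1])
                or not (0.0 <= mu < width)
            ):
                n_rejected += 1
                continue
            out.append(
                Localization(
                    frame=t,
                    position_px=float(mu),
                    amplitude=float(amp),
                    sigma_px=float(sigma),
                    background=float(offset),
                    channel=channel,
                )
            )
    logger.info(
        "localize[%s]: %d peaks, %d fits rejected, %d localizations",
        channel, n_peaks, n_rejected, len(out),
    )
    return out


def link(
    locs: list[Localization],
    cfg: TrackingConfig,
    pixel_size_nm: float,
    line_time_s: float,
    origin_offset: int = 0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Gate ``max_step_um`` per elapsed line (scaled by gap length), up to
    ``max_gap_frames`` missed lines; tracks shorter than
    ``min_track_frames`` are dropped.  Ties break toward the smaller column
    index.  Samples where two tracks approach within
    ``overlap_radius_px`` are flagged ineligible for MSD analysis.
    """
    px_um = pixel_size_nm / 1000.0
    by_frame: dict[int, list[Localization]] = {}
    for l in sorted(locs, key=lambda l: (l.frame, l.position_px)):
        by_frame.setdefault(l.frame, []).append(l)

    active: list[list[Localization]] = []  # growing tracks
    finished: list[list[Localization]] = []
    for frame in sorted(by_frame):
        cands = by_frame[frame]
        # retire stale tracks
        still = []
        for tr in active:
            if frame - tr[-1].frame > cfg.max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        # greedy assignment: smallest distance first, ties to smaller column
        pairs = []
        for ti, tr in enumerate(active):
            gap = frame - tr[-1].frame
            gate_px = cfg.max_step_um * gap / px_um
            for ci, c in enumerate(cands):
                d = abs(c.position_px - tr[-1].position_px)
                if d <= gate_px:
                    pairs.append((d, c.position_px, ti, ci))
        used_t: set[int] = set()
        used_c: set[int] = set()
        for d, _, ti, ci in sorted(pairs):
            if ti in used_t or ci in used_c:
                continue
            active[ti].append(cands[ci])
            used_t.add(ti)
            used_c.add(ci)
        for ci, c in enumerate(cands):
            if ci not in used_c:
                active.append([c])
    finished.extend(active)

    kept = [tr for tr in finished if len(tr) >= cfg.min_track_frames]
    logger.info("link: %d raw tracks, %d kept (>= %d frames)",
                len(finished), len(kept), cfg.min_track_frames)

    trajs: list[Trajectory] = []
    for tid, tr in enumerate(sorted(kept, key=lambda tr: tr[0].frame)):
        frames = np.array([l.frame for l in tr])
        pos_um = (np.array([l.position_px for l in tr]) + 0.5 + origin_offset) * px_um
        # fill missed lines by linear interpolation so sampling stays
        # uniform (MSD, SG filtering); filled samples are MSD-ineligible
        full = np.arange(frames[0], frames[-1] + 1)
        pos_full = np.interp(full, frames, pos_um)
        observed = np.isin(full, frames)
        trajs.append(
            Trajectory(
                id=tid,
                channel=tr[0].channel,
                times_s=full * line_time_s,
                positions_um=pos_full,
                frames=full,
                eligible=observed,
            )
        )
    _flag_overlaps(trajs, cfg.overlap_radius_px * px_um)
    return trajs


def _flag_overlaps(trajs: list[Trajectory], radius_um: float) -> None:
    """Mark samples ineligible where two trajectories come within radius."""
    for i, a in enumerate(trajs):
        for b in trajs[i + 1 :]:
            fa = {int(f): k for k, f in enumerate(a.frames)}
            for kb, fb in enumerate(b.frames):
                ka = fa.get(int(fb))
                if ka is None:
                    continue
                if abs(a.positions_um[ka] - b.positions_um[kb]) <= radius_um:
                    a.eligible[ka] = False
                    b.eligible[kb] = False


def smooth(traj: Trajectory, cfg: TrackingConfig | None = None) -> Trajectory:
    """Savitzky-Golay smoothing of positions; times untouched.

    Trajectories shorter than the filter window are returned unchanged with
    ``smoothed=False``.
    """
    cfg = cfg or TrackingConfig()
    if len(traj) <= cfg.sg_window:
        return replace_smoothed(traj, traj.positions_um, smoothed=False)
    filtered = savgol_filter(traj.positions_um, cfg.sg_window, cfg.sg_order)
    return replace_smoothed(traj, filtered, smoothed=True)


def replace_smoothed(traj: Trajectory, positions: np.ndarray, smoothed: bool) -> Trajectory:
    return Trajectory(
        id=traj.id,
        channel=traj.channel,
        times_s=traj.times_s.copy(),
        positions_um=np.asarray(positions, dtype=float).copy(),
        frames=None if traj.frames is None else traj.frames.copy(),
        eligible=None if traj.eligible is None else traj.eligible.copy(),
        smoothed=smoothed,
    )
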