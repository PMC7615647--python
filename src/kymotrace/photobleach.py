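"""Photobleaching step counting for fluorophore stoichiometry.

Intensity traces of diffraction-limited spots are segmented with penalized
binary change-point detection on a piecewise-constant mean model; the number
of downward level changes exceeding a robust minimum step height estimates
the number of fluorophores.  Upward changes (arrivals) terminate the usable
prefix of the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from kymotrace._changepoint import (
    robust_noise_sd,
    rolling_noise_sd,
    segment_constant_dp,
)
from kymotrace.io import Kymograph
from kymotrace.kinetics import EventRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BleachTrace",
    "StepCountResult",
    "extract_trace",
    "count_steps",
    "oligomer_distribution",
]


@dataclass
class BleachTrace:
    time_s: np.ndarray
    intensity: np.ndarray
    edge_narrowed: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class StepCountResult:
    n_steps: int
    step_times_s: list[float]
    step_heights: list[float]
    residual_sd: float
    truncated_at_s: float | None = None  # upward step cut the trace here


def _quantize_drops(
    drop_sizes: list[float],
    drop_ses: list[float],
    max_mult: int = 6,
    complexity: float = 2.0,
) -> list[int]:
    """Express each drop as an integer number of unit steps.

    Candidate multiplicity assignments come from rounding against every
    ``drop/k``; for each assignment the unit is refit by weighted least
    squares and the assignment is scored by chi-square against the drop
    standard errors plus an AIC-like charge per step.  A spurious small drop
    is explained as zero units instead of shrinking the unit for everyone.
    """
    d = np.asarray(drop_sizes, dtype=float)
    se = np.asarray(drop_ses, dtype=float)
    # segment boundaries can be off by a sample, mixing levels into the
    # segment means: allow a relative height tolerance on top of the
    # purely statistical standard error
    se = np.maximum(np.sqrt(se**2 + (0.15 * d) ** 2), 1e-12)
    best_mults = [1] * d.size
    best_score = np.inf
    seen: set[tuple[int, ...]] = set()
    candidates = {dj / k for dj in drop_sizes for k in range(1, max_mult + 1)}
    for u0 in candidates:
        m = np.minimum(np.round(d / u0).astype(int), max_mult)
        key = tuple(m)
        if key in seen or not m.any():
            continue
        seen.add(key)
        wm = m / se**2
        u = float(np.dot(wm, d) / np.dot(wm, m)) if np.dot(wm, m) > 0 else u0
        chi2 = float(np.sum(((d - m * u) / se) ** 2))
        score = chi2 + complexity * int(m.sum())
        if score < best_score - 1e-12:
            best_score, best_mults = score, [int(v) for v in m]
    return best_mults


def _segment_sds(y: np.ndarray, bounds: list[int], global_sd: float) -> list[float]:
    """Noise SD per segment, from within-segment first differences.

    Post-segmentation estimates are free of level mixing, so they track
    shot noise honestly at every intensity.  Short segments borrow the
    larger of their neighbors' estimates (conservative).
    """
    sds: list[float | None] = []
    lens, means = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lens.append(b - a)
        means.append(float(np.mean(y[a:b])))
        if b - a >= 6:
            sds.append(max(robust_noise_sd(y[a:b]), 0.3 * global_sd))
        else:
            sds.append(None)
    # Short segments need a borrowed noise estimate.  Shot noise grows with
    # intensity, so fit a variance-vs-mean line through the well-estimated
    # segments and extrapolate; the line adapts under affine transforms of
    # the trace, keeping the step count offset- and scale-invariant.
    known = [(means[i], sds[i] ** 2, lens[i]) for i, s in enumerate(sds) if s is not None]
    line = None
    if len(known) >= 2 and np.ptp([m for m, _, _ in known]) > 1e-12:
        m_arr = np.array([m for m, _, _ in known])
        v_arr = np.array([v for _, v, _ in known])
        w_arr = np.array([n for _, _, n in known], dtype=float)
        slope, intercept = np.polyfit(m_arr, v_arr, 1, w=w_arr)
        line = (slope, intercept)
    for i, s in enumerate(sds):
        if s is not None:
            continue
        if line is not None:
            var = line[0] * means[i] + line[1]
            sds[i] = max(np.sqrt(max(var, 0.0)), 0.3 * global_sd)
        else:
            neighbors = [
                v for v in (sds[i - 1] if i > 0 else None,
                            sds[i + 1] if i + 1 < len(sds) else None)
                if v is not None
            ]
            sds[i] = max(neighbors) if neighbors else max(global_sd, 1e-12)
    return [float(s) for s in sds]


def _drop_se(y: np.ndarray, bounds: list[int], sds: list[float], i: int) -> float:
    """Standard error of the mean change across break i."""
    n1 = bounds[i + 1] - bounds[i]
    n2 = bounds[i + 2] - bounds[i + 1]
    return float(np.sqrt(sds[i] ** 2 / n1 + sds[i + 1] ** 2 / n2))


def _remove_outlier_bumps(
    y: np.ndarray,
    breaks: list[int],
    global_sd: float,
    max_len: int = 3,
    t_threshold: float = 4.0,
) -> list[int]:
    """Splice out short excursions that return to the surrounding level.

    Shot noise is heavier-tailed than Gaussian, so short outlier runs can
    look like significant level changes.  A real staircase never returns
    to its previous level: any interior segment of at most ``max_len``
    samples whose neighbors agree with each other (z below the threshold)
    is noise and both of its breaks are removed.
    """
    breaks = list(breaks)
    changed = True
    while changed and len(breaks) >= 2:
        changed = False
        bounds = [0, *breaks, y.size]
        sds = _segment_sds(y, bounds, global_sd)
        for i in range(1, len(bounds) - 2):
            a, b, c, d = bounds[i - 1], bounds[i], bounds[i + 1], bounds[i + 2]
            if c - b > max_len:
                continue
            ml, mr = float(np.mean(y[a:b])), float(np.mean(y[c:d]))
            se = np.sqrt(sds[i - 1] ** 2 / (b - a) + sds[i + 1] ** 2 / (d - c))
            if abs(ml - mr) / max(se, 1e-300) < t_threshold:
                breaks.remove(b)
                breaks.remove(c)
                changed = True
                break
    return breaks


def _refine_segments(
    y: np.ndarray,
    breaks: list[int],
    global_sd: float,
    penalty: float | None,
) -> list[int]:
    """Second-look split of each segment using its own noise estimate.

    The first segmentation pass uses a rolling noise SD, which is inflated
    where several steps fall inside one estimation window — exactly where
    close-spaced steps hide.  Per-segment SDs are free of that bias, so
    re-splitting each segment with its own SD resolves tight clusters while
    leaving honest segments untouched (breaks are only ever added).
    """
    bounds = [0, *breaks, y.size]
    sds = _segment_sds(y, bounds, global_sd)
    out = list(breaks)
    for (a, b), sd in zip(zip(bounds[:-1], bounds[1:]), sds):
        if b - a < 4:
            continue
        extra = segment_constant_dp(y[a:b], noise_sd=sd, penalty=penalty)
        out.extend(a + e for e in extra)
    return sorted(set(out))


def _drop_minor_upward_breaks(y: np.ndarray, breaks: list[int]) -> list[int]:
    """Remove upward level changes too small to be a second arrival.

    A bleaching staircase never rises; an upward change well below the
    dominant step height is residual noise, and keeping its break would
    contaminate the neighboring drop heights.  The break is removed (the
    short-lived high piece joins its left neighbor) and means recompute.
    """
    breaks = list(breaks)
    while True:
        bounds = [0, *breaks, y.size]
        means = [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
        changes = [means[i + 1] - means[i] for i in range(len(breaks))]
        max_down = max((-c for c in changes if c < 0), default=0.0)
        removable = [
            i for i, c in enumerate(changes) if 0 <= c < 0.5 * max_down
        ]
        if not removable:
            return breaks
        del breaks[removable[0]]


def _merge_insignificant(
    y: np.ndarray,
    breaks: list[int],
    global_sd: float,
    t_threshold: float,
) -> list[int]:
    """Merge adjacent segments whose mean change is statistically weak.

    The score is a z statistic on the segment means against per-segment
    noise SDs; the weakest change merges first until all survivors exceed
    the threshold.
    """
    breaks = list(breaks)
    while breaks:
        bounds = [0, *breaks, y.size]
        sds = _segment_sds(y, bounds, global_sd)
        scores = []
        for i in range(len(breaks)):
            a, b, c = bounds[i], bounds[i + 1], bounds[i + 2]
            dm = abs(float(np.mean(y[b:c])) - float(np.mean(y[a:b])))
            scores.append(dm / max(_drop_se(y, bounds, sds, i), 1e-300))
        weakest = int(np.argmin(scores))
        if scores[weakest] >= t_threshold:
            break
        del breaks[weakest]
    return breaks


def extract_trace(
    kymo: Kymograph,
    event: EventRecord,
    integration_px: int = 5,
) -> BleachTrace:
    """Per-line integrated intensity around the event position.

    Sums ``integration_px`` columns centered on the event; local background
    (median of flanking columns, scaled to the window width) is subtracted.
    Windows clipped at the image edge are narrowed and flagged.
    """
    img = kymo.channels[event.channel].astype(float)
    center = int(round(kymo.position_to_column(event.position_um)))
    half = integration_px // 2
    a, b = center - half, center + half + 1
    narrowed = a < 0 or b > kymo.width
    a, b = max(0, a), min(kymo.width, b)
    if b <= a:
        raise ValueError("event outside the image")
    width = b - a
    flank_w = max(2, integration_px)
    left = img[:, max(0, a - flank_w) : a]
    right = img[:, b : b + flank_w]
    flanks = np.hstack([x for x in (left, right) if x.size]) if (left.size or right.size) else None
    bg_per_px = np.median(flanks, axis=1) if flanks is not None else np.zeros(img.shape[0])
    trace = img[:, a:b].sum(axis=1) - bg_per_px * width
    times = np.arange(img.shape[0]) * kymo.line_time_s
    if narrowed:
        logger.info("extract_trace: window narrowed at image edge (event at %.2f um)",
                    event.position_um)
    return BleachTrace(time_s=times, intensity=trace, edge_narrowed=narrowed)


def count_steps(
    trace: BleachTrace,
    penalty: float | None = None,
    min_segment: int = 1,
    min_step_sd: float = 2.0,
    min_collapse_gap: int = 3,
) -> StepCountResult:
    """Count downward intensity steps by change-point segmentation.

    Steps are adjacent-segment mean drops of at least ``min_step_sd`` times
    the robust noise SD.  The penalty scales with the noise variance, making
    the count invariant to offset and rescaling of the trace.  Analysis stops
    at the first upward step (a second arrival), which truncates the usable
    prefix.
    """
    y = trace.intensity
    if y.size < 10:
        raise ValueError("trace too short (need >= 10 samples)")
    global_sd = robust_noise_sd(y)
    breaks = segment_constant_dp(y, noise_sd=rolling_noise_sd(y), penalty=penalty)
    breaks = _refine_segments(y, breaks, global_sd, penalty)
    breaks = _remove_outlier_bumps(y, breaks, global_sd)
    breaks = _merge_insignificant(y, breaks, global_sd, t_threshold=4.0)
    breaks = _drop_minor_upward_breaks(y, breaks)
    bounds = [0, *breaks, y.size]
    means = [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    seg_sds = _segment_sds(y, bounds, global_sd)

    changes = [means[i + 1] - means[i] for i in range(len(breaks))]
    max_down = max((-c for c in changes if c < 0), default=0.0)

    drops: list[tuple[float, float, float]] = []  # (time, height<0, SE)
    truncated_at: float | None = None
    for i, brk in enumerate(breaks):
        dh = changes[i]
        sd_here = max(seg_sds[i], seg_sds[i + 1])
        # an arrival (second molecule landing) rises by a full fluorophore
        # level; smaller upward wiggles are segmentation noise, not arrivals
        if dh > 0 and dh > max(min_step_sd * sd_here, 0.5 * max_down):
            truncated_at = float(trace.time_s[brk])
            break
        if dh < 0 and abs(dh) >= min_step_sd * sd_here:
            drops.append((float(trace.time_s[brk]), dh, _drop_se(y, bounds, seg_sds, i)))

    # Bleaching steps of one fluorophore species have equal expected height,
    # so a drop of k units is k coincident steps.  The unit height is chosen
    # by consensus across all drops; drops explained best as zero units
    # (segmentation debris) contribute no steps.
    step_times: list[float] = []
    step_heights: list[float] = []
    if drops:
        mults = _quantize_drops(
            [abs(dh) for _, dh, _ in drops], [sd for _, _, sd in drops]
        )
        for (t_s, dh, _), m in zip(drops, mults):
            if m == 0:
                continue
            step_times.extend([t_s] * m)
            step_heights.extend([dh / m] * m)
    resid = []
    for a, b, m in zip(bounds[:-1], bounds[1:], means):
        resid.extend(y[a:b] - m)
    return StepCountResult(
        n_steps=len(step_times),
        step_times_s=step_times,
        step_heights=step_heights,
        residual_sd=float(np.std(resid)),
        truncated_at_s=truncated_at,
    )


def oligomer_distribution(results: list[StepCountResult]) -> dict[int, float]:
    """Fractions of traces per step count.

    Traces truncated before any downward step (pure arrivals) carry no
    stoichiometry information and are excluded, with a log line.
    """
    if not results:
        raise ValueError("need at least one result")
    usable = [r for r in results if not (r.truncated_at_s is not None and r.n_steps == 0)]
    n_dropped = len(results) - len(usable)
    if n_dropped:
        logger.info("oligomer_distribution: dropped %d arrival-only traces", n_dropped)
    if not usable:
        return {}
    counts: dict[int, int] = {}
    for r in usable:
        counts[r.n_steps] = counts.get(r.n_steps, 0) + 1
    total = len(usable)
    return {k: counts[k] / total for k in sorted(counts)}
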