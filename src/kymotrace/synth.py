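"""Synthetic data generators with known ground truth.

Every simulator takes an explicit integer seed and is fully deterministic for
a given seed + parameter set.  Simulators return ground truth alongside the
data so downstream recovery tests can compare without peeking.

Free parameters not fixed by the emulated experiments (photon budgets,
background levels) default to values giving SNR ≈ 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from kymotrace.io import ForceExtensionCurve, Kymograph, Trajectory
from kymotrace.mechanics import EWLCParams, ewlc_length

__all__ = [
    "EmitterModel",
    "TetherModel",
    "simulate_trajectory",
    "render_kymograph",
    "simulate_fec",
    "simulate_dwells",
    "simulate_bleach_trace",
    "simulate_nucleation",
]

RISE_PER_BP_NM = 0.34


@dataclass
class EmitterModel:
    """Ground-truth motion and photophysics of one fluorescent emitter."""

    kind: str = "static"  # static | diffusive | directed
    D_true_um2_s: float = 0.0
    velocity_um_s: float = 0.0
    start_position_um: float = 0.0
    bind_time_s: float = 0.0
    dwell_mean_s: float = np.inf
    photons_per_line: float = 200.0
    bleach_mean_lines: float = np.inf
    n_fluorophores: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("static", "diffusive", "directed"):
            raise ValueError(f"unknown emitter kind {self.kind!r}")
        if self.D_true_um2_s < 0:
            raise ValueError("D_true must be >= 0")
        if self.dwell_mean_s <= 0:
            raise ValueError("dwell mean must be > 0")
        if self.photons_per_line <= 0:
            raise ValueError("photons_per_line must be > 0")


@dataclass
class TetherModel:
    """Geometry of the DNA tether: total length, internal ssDNA gap, obstacles."""

    total_bp: int = 48_502
    gap_start_nt: int = 30_536
    gap_end_nt: int = 35_910
    obstacle_positions_um: tuple[float, ...] = ()
    obstacle_bypass_prob: float = 0.0
    bead_margin_px: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gap_start_nt < self.gap_end_nt <= self.total_bp):
            raise ValueError("gap must satisfy 0 <= start < end <= total_bp")

    @property
    def length_um(self) -> float:
        return self.total_bp * RISE_PER_BP_NM / 1000.0

    @property
    def gap_nt(self) -> int:
        return self.gap_end_nt - self.gap_start_nt

    @property
    def gap_span_um(self) -> tuple[float, float]:
        scale = RISE_PER_BP_NM / 1000.0
        return (self.gap_start_nt * scale, self.gap_end_nt * scale)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (handles multiple bounces)."""
    width = hi - lo
    if width <= 0:
        raise ValueError("invalid reflection interval")
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def simulate_trajectory(
    model: EmitterModel,
    tether: TetherModel,
    n_lines: int,
    line_time_s: float,
    seed: int,
    traj_id: int = 0,
    channel: str = "eGFP",
) -> Trajectory:
    """Simulate one emitter's path along the tether.

    Diffusive motion uses Gaussian increments of variance ``2 D dt`` on a
    continuous coordinate, reflecting at tether ends and at obstacles
    (obstacles are bypassed with probability ``obstacle_bypass_prob`` per
    crossing attempt).  The path is truncated at the earlier of the dwell
    and photobleach draws.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if not (0.0 <= model.start_position_um <= tether.length_um):
        raise ValueError("start position outside tether")
    rng = np.random.default_rng(seed)

    n_keep = n_lines
    if np.isfinite(model.dwell_mean_s):
        dwell = rng.exponential(model.dwell_mean_s)
        n_keep = min(n_keep, max(2, int(np.ceil(dwell / line_time_s))))
    if np.isfinite(model.bleach_mean_lines):
        bleach = rng.exponential(model.bleach_mean_lines)
        n_keep = min(n_keep, max(2, int(np.ceil(bleach))))

    x = np.empty(n_keep)
    x[0] = model.start_position_um
    if model.kind == "static":
        x[:] = model.start_position_um
    elif model.kind == "directed":
        t = np.arange(n_keep) * line_time_s
        x = model.start_position_um + model.velocity_um_s * t
        x = np.array([_reflect(v, 0.0, tether.length_um) for v in x])
    else:
        sigma = np.sqrt(2.0 * model.D_true_um2_s * line_time_s)
        steps = rng.normal(0.0, sigma, size=n_keep - 1)
        obstacles = sorted(tether.obstacle_positions_um)
        for i, dx in enumerate(steps):
            prev = x[i]
            new = prev + dx
            for ob in obstacles:
                crossed = (prev - ob) * (new - ob) < 0
                if crossed and rng.random() >= tether.obstacle_bypass_prob:
                    new = 2 * ob - new  # mirror across the obstacle point
            x[i + 1] = _reflect(new, 0.0, tether.length_um)

    times = model.bind_time_s + np.arange(n_keep) * line_time_s
    return Trajectory(id=traj_id, channel=channel, times_s=times, positions_um=x)


def render_kymograph(
    trajs: Sequence[Trajectory],
    tether: TetherModel,
    psf_sigma_px: float = 1.3,
    background_counts: float = 10.0,
    pixel_size_nm: float = 100.0,
    line_time_s: float = 0.25,
    channels: dict[str, float] | None = None,
    seed: int = 0,
    n_lines: int | None = None,
    saturation_value: float = 65535.0,
) -> tuple[Kymograph, pd.DataFrame]:
    """Render trajectories into a noisy kymograph.

    Each trajectory contributes a 1D Gaussian profile (its emitter's
    ``photons_per_line`` is encoded in the trajectory via the channels map:
    ``channels`` maps channel name -> photons per line for trajectories of
    that channel).  Poisson noise is applied per pixel; bead margins are
    rendered saturated.  Returns the kymograph and a ground-truth table with
    columns trajectory_id, channel, frame, position_px, position_um.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    channels = channels or {"eGFP": 200.0}
    rng = np.random.default_rng(seed)
    width = int(np.ceil(tether.length_um * 1000.0 / pixel_size_nm)) + 2 * tether.bead_margin_px
    if n_lines is None:
        end = max((t.times_s[-1] for t in trajs), default=0.0)
        n_lines = max(2, int(np.ceil(end / line_time_s)) + 1)

    cols = np.arange(width)
    images = {ch: np.full((n_lines, width), float(background_counts)) for ch in channels}
    truth_rows = []
    for t in trajs:
        if t.channel not in channels:
            raise ValueError(f"trajectory channel {t.channel!r} not in channels map")
        photons = channels[t.channel]
        img = images[t.channel]
        frames = np.rint(t.times_s / line_time_s).astype(int)
        for f, x_um in zip(frames, t.positions_um):
            if not (0 <= f < n_lines):
                continue
            # pixel center of column c is (c + 0.5) px from the tether start
            c = x_um * 1000.0 / pixel_size_nm - 0.5 + tether.bead_margin_px
            profile = np.exp(-0.5 * ((cols - c) / psf_sigma_px) ** 2)
            img[f] += photons * profile / (psf_sigma_px * np.sqrt(2 * np.pi))
            truth_rows.append((t.id, t.channel, f, c, x_um))

    noisy = {}
    for ch, img in images.items():
        out = rng.poisson(img).astype(float)
        if tether.bead_margin_px:
            out[:, : tether.bead_margin_px] = saturation_value
            out[:, width - tether.bead_margin_px :] = saturation_value
        noisy[ch] = out

    kymo = Kymograph(
        channels=noisy,
        pixel_size_nm=pixel_size_nm,
        line_time_s=line_time_s,
        origin_offset=-tether.bead_margin_px,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["trajectory_id", "channel", "frame", "position_px", "position_um"],
    )
    return kymo, truth


def simulate_fec(
    tether: TetherModel,
    ewlc: EWLCParams,
    rips: Sequence[tuple[float, float]] = (),
    force_grid: np.ndarray | None = None,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
) -> tuple[ForceExtensionCurve, pd.DataFrame]:
    """eWLC force-extension curve with stepwise contour-length releases.

    ``rips`` is a list of (force_pN, delta_bp): at each rip force the contour
    length increases by ``delta_bp * rise_per_bp``.  Gaussian distance noise
    of ``noise_sd_nm`` is added.  Returns the curve and a truth table of the
    planted rips (force_pN, delta_bp, delta_Lc_nm).
    """
    if force_grid is None:
        force_grid = np.linspace(2.0, 40.0, 400)
    force_grid = np.asarray(force_grid, dtype=float)
    for f_rip, _ in rips:
        if not (force_grid.min() <= f_rip <= force_grid.max()):
            raise ValueError(f"rip force {f_rip} outside force grid")
    rng = np.random.default_rng(seed)

    rips_sorted = sorted(rips)
    extension_nm = np.empty_like(force_grid)
    for i, f in enumerate(force_grid):
        released_bp = sum(dbp for f_rip, dbp in rips_sorted if f >= f_rip)
        lc = ewlc.Lc_nm + released_bp * ewlc.rise_per_bp_nm
        extension_nm[i] = ewlc_length(f, ewlc.with_Lc(lc))
    if noise_sd_nm > 0:
        extension_nm = extension_nm + rng.normal(0.0, noise_sd_nm, size=extension_nm.size)

    order = np.argsort(extension_nm, kind="stable")
    curve = ForceExtensionCurve(
        distance_um=_strictly_increasing(extension_nm[order] / 1000.0),
        force_pN=force_grid[order],
    )
    truth = pd.DataFrame(
        [(f, dbp, dbp * ewlc.rise_per_bp_nm) for f, dbp in rips_sorted],
        columns=["force_pN", "delta_bp", "delta_Lc_nm"],
    )
    return curve, truth


def _strictly_increasing(x: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Nudge sorted values so ties become strictly increasing."""
    out = x.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def simulate_dwells(
    mean_s: float,
    n: int,
    frame_s: float = 0.25,
    observation_limit_s: float = np.inf,
    seed: int = 0,
) -> list[tuple[float, bool]]:
    """Exponential dwell times, frame-discretized and right-censored.

    Returns (duration_s, censored) pairs; censored dwells are clipped to the
    observation limit.
    """
    if mean_s <= 0:
        raise ValueError("mean_s must be > 0")
    rng = np.random.default_rng(seed)
    draws = rng.exponential(mean_s, size=n)
    out: list[tuple[float, bool]] = []
    for d in draws:
        censored = d > observation_limit_s
        d = min(d, observation_limit_s)
        d = np.ceil(d / frame_s) * frame_s  # event spans whole frames
        out.append((float(d), bool(censored)))
    return out


def simulate_bleach_trace(
    n_steps: int,
    photons_per_level: float = 100.0,
    frames_per_step_mean: float = 30.0,
    n_frames: int = 200,
    background: float = 20.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Staircase photobleaching trace for ``n_steps`` fluorophores.

    Intensity starts at ``background + n_steps * photons_per_level`` and drops
    by one level at each exponential bleaching time; Poisson noise optional.
    Returns (trace, truth) where truth holds the true step count and times.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = np.random.default_rng(seed)
    bleach_frames = np.sort(rng.exponential(frames_per_step_mean, size=n_steps))
    bleach_frames = np.clip(np.ceil(bleach_frames).astype(int), 1, None)
    # keep every step inside the trace so the true count is realized
    bleach_frames = np.minimum(
        bleach_frames, n_frames - 1 - np.arange(n_steps)[::-1]
    )
    bleach_frames = np.maximum.accumulate(bleach_frames)
    # distinct frames: shift collisions forward
    for i in range(1, n_steps):
        if bleach_frames[i] <= bleach_frames[i - 1]:
            bleach_frames[i] = bleach_frames[i - 1] + 1

    levels = np.full(n_frames, float(background))
    active = np.full(n_frames, n_steps)
    for bf in bleach_frames:
        active[bf:] -= 1
    levels = background + active * photons_per_level
    trace = rng.poisson(levels).astype(float) if noise else levels.astype(float)
    truth = {
        "n_steps": int(n_steps),
        "step_frames": [int(b) for b in bleach_frames],
        "photons_per_level": photons_per_level,
        "background": background,
    }
    return trace, truth


def simulate_nucleation(
    rate_per_knt_min: float,
    gap_knt: float,
    duration_s: float,
    seed: int = 0,
    junction_weight: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Homogeneous Poisson nucleation on a ssDNA gap.

    Event count ~ Poisson(rate * gap_knt * duration/60); positions uniform on
    [0, gap_knt] knt unless ``junction_weight = (edge_knt, mass)`` directs
    ``mass`` of the probability into the two outer ``edge_knt`` stretches.
    Returns a DataFrame with columns time_s, position_knt.
    """
    if rate_per_knt_min < 0 or gap_knt <= 0 or duration_s <= 0:
        raise ValueError("rate must be >= 0; gap and duration must be > 0")
    rng = np.random.default_rng(seed)
    mean = rate_per_knt_min * gap_knt * duration_s / 60.0
    n = rng.poisson(mean)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    if junction_weight is None:
        pos = rng.uniform(0.0, gap_knt, size=n)
    else:
        edge, mass = junction_weight
        if not (0 < edge < gap_knt / 2 and 0 <= mass <= 1):
            raise ValueError("junction_weight must be (edge_knt < gap/2, mass in [0,1])")
        at_edge = rng.random(n) < mass
        pos = np.where(
            at_edge,
            np.where(
                rng.random(n) < 0.5,
                rng.uniform(0.0, edge, size=n),
                rng.uniform(gap_knt - edge, gap_knt, size=n),
            ),
            rng.uniform(edge, gap_knt - edge, size=n),
        )
    return pd.DataFrame({"time_s": times, "position_knt": pos})
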