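"""Domain types and bit-exact readers/writers for the pipeline's file formats.

A kymograph is stored as a multi-page TIFF (one page per channel, in declared
order) with a JSON sidecar ``<stem>.json`` carrying ``pixel_size_nm``,
``line_time_s`` and ``channels``.  Trajectories and force-extension curves are
plain CSV at full double precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Kymograph",
    "Localization",
    "Trajectory",
    "ForceExtensionCurve",
    "RunConfig",
    "read_kymograph",
    "write_kymograph",
    "read_trajectories",
    "write_trajectories",
    "read_fec",
    "write_fec",
]


@dataclass
class Kymograph:
    """Multi-channel kymograph: rows are scan lines (time), columns position.

    Physical position of column ``c`` is ``(c + 0.5 + origin_offset) *
    pixel_size_nm`` — the half-pixel centers the coordinate inside the pixel,
    and ``origin_offset`` keeps coordinates stable after cropping.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float
    line_time_s: float
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("kymograph needs at least one channel")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise ValueError(f"channels must be 2D, got shape {first}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.line_time_s <= 0:
            raise ValueError("line_time_s must be > 0")
        for ch, a in self.channels.items():
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {ch!r} has non-finite intensities")
            if np.any(a < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")

    @property
    def n_lines(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    def column_position_um(self, column: float | np.ndarray) -> float | np.ndarray:
        """Physical position (μm) of a (possibly sub-pixel) column index."""
        return (np.asarray(column) + 0.5 + self.origin_offset) * self.pixel_size_nm / 1000.0

    def position_to_column(self, position_um: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`column_position_um`."""
        return np.asarray(position_um) * 1000.0 / self.pixel_size_nm - 0.5 - self.origin_offset

    def line_times_s(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_time_s


@dataclass(frozen=True)
class Localization:
    """One sub-pixel detection on one scan line."""

    frame: int
    position_px: float
    amplitude: float
    sigma_px: float
    background: float
    channel: str

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be > 0")


@dataclass
class Trajectory:
    """Time-ordered sub-pixel positions of one tracked particle.

    ``frames`` holds source scan-line indices when the trajectory comes from a
    kymograph; ``eligible`` flags samples usable for MSD analysis (samples in
    overlap-excluded stretches are flagged False by the linker).
    """

    id: int
    channel: str
    times_s: np.ndarray
    positions_um: np.ndarray
    frames: np.ndarray | None = None
    eligible: np.ndarray | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.times_s.shape != self.positions_um.shape:
            raise ValueError("times and positions must have the same length")
        if self.times_s.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)
        if self.eligible is not None:
            self.eligible = np.asarray(self.eligible, dtype=bool)

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    @property
    def dt_s(self) -> float:
        """Median sampling interval."""
        return float(np.median(np.diff(self.times_s)))


@dataclass
class ForceExtensionCurve:
    """Ordered (distance, force) samples from a single pull."""

    distance_um: np.ndarray
    force_pN: np.ndarray

    def __post_init__(self) -> None:
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.distance_um.shape != self.force_pN.shape:
            raise ValueError("distance and force must have the same length")
        if np.any(np.diff(self.distance_um) <= 0):
            raise ValueError("distances must be strictly increasing within a pull")
        if not np.all(np.isfinite(self.force_pN)):
            raise ValueError("forces must be finite")

    def __len__(self) -> int:
        return self.distance_um.size


@dataclass
class RunConfig:
    """All pipeline tunables with their default values (units in names).

    Defaults follow the published analysis where a value is stated there;
    remaining knobs are free parameters documented here.
    """

    seed: int | None = None
    # imaging geometry
    pixel_size_nm: float = 100.0
    line_time_s: float = 0.25
    # tracking
    window_frames: int = 3
    detect_threshold_sd: float = 3.0
    max_step_um: float = 0.5
    max_gap_frames: int = 3
    min_track_frames: int = 10
    sg_window: int = 51
    sg_order: int = 3
    overlap_radius_px: float = 3.0
    # diffusion
    fit_window_s: tuple[float, float] = (0.25, 2.0)
    slope_convention: str = "paper"
    static_threshold_um2_s: float = 0.01
    alpha_directed_margin: float = 0.2
    # kinetics
    event_threshold_sd: float = 3.0
    dwell_bin_s: float = 7.0
    nucleation_window_s: float = 60.0
    co_tolerance_lines: int = 1
    coloc_radius_px: float = 2.0
    profile_bin_nt: int = 200
    # photobleaching
    min_segment_lines: int = 3
    min_step_sd: float = 2.0
    # mechanics
    Lp_nm: float = 100.0
    S_pN: float = 1000.0
    T_K: float = 297.0
    rise_per_bp_nm: float = 0.34
    min_delta_Lc_nm: float = 10.0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "fit_window_s" in raw:
            raw["fit_window_s"] = tuple(raw["fit_window_s"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["fit_window_s"] = list(d["fit_window_s"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# kymograph TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write one TIFF page per channel plus a JSON metadata sidecar."""
    path = Path(path)
    names = list(kymo.channels)
    pages = np.stack([kymo.channels[ch] for ch in names])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_size_nm": kymo.pixel_size_nm,
        "line_time_s": kymo.line_time_s,
        "origin_offset": kymo.origin_offset,
        "channels": names,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_kymograph(
    path: str | Path,
    pixel_size_nm: float | None = None,
    line_time_s: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> Kymograph:
    """Read a multi-page TIFF kymograph.

    Metadata comes from the JSON sidecar when present; explicit arguments
    override it.  Metadata is never inferred — line time and pixel size must
    be supplied one way or the other.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    pixel_size_nm = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    line_time_s = line_time_s if line_time_s is not None else meta.get("line_time_s")
    channel_names = channel_names if channel_names is not None else meta.get("channels")
    if pixel_size_nm is None or line_time_s is None or channel_names is None:
        raise ValueError(
            "pixel_size_nm, line_time_s and channel names are required "
            "(from arguments or the JSON sidecar); they are never inferred"
        )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected 2D pages, got array of shape {pages.shape}")
    if pages.shape[0] != len(channel_names):
        raise ValueError(
            f"channel-count mismatch: file has {pages.shape[0]} pages, "
            f"{len(channel_names)} channel names declared"
        )
    channels = {ch: pages[i] for i, ch in enumerate(channel_names)}
    return Kymograph(
        channels=channels,
        pixel_size_nm=float(pixel_size_nm),
        line_time_s=float(line_time_s),
        origin_offset=int(meta.get("origin_offset", 0)),
    )


# ---------------------------------------------------------------------------
# trajectory CSV

_TRAJ_COLUMNS = ["trajectory_id", "channel", "frame", "time_s", "position_um"]


def write_trajectories(trajs: Sequence[Trajectory], path: str | Path) -> None:
    """CSV with header ``trajectory_id,channel,frame,time_s,position_um``."""
    rows = []
    for t in trajs:
        frames = t.frames if t.frames is not None else np.arange(len(t))
        for f, ts, x in zip(frames, t.times_s, t.positions_um):
            rows.append((t.id, t.channel, int(f), repr(float(ts)), repr(float(x))))
    df = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    df.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out: list[Trajectory] = []
    for (tid, ch), g in df.groupby(["trajectory_id", "channel"], sort=False):
        g = g  # preserved file order; ordering violations raise in Trajectory
        out.append(
            Trajectory(
                id=int(tid),
                channel=str(ch),
                times_s=g["time_s"].to_numpy(),
                positions_um=g["position_um"].to_numpy(),
                frames=g["frame"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# force-extension CSV

_FEC_COLUMNS = ["distance_um", "force_pN"]


def write_fec(curve: ForceExtensionCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "distance_um": [repr(float(v)) for v in curve.distance_um],
            "force_pN": [repr(float(v)) for v in curve.force_pN],
        }
    )
    df.to_csv(path, index=False)


def read_fec(path: str | Path) -> ForceExtensionCurve:
    """Read a force-extension CSV; NaN rows are dropped with a logged count."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_FEC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"force-extension CSV missing columns: {sorted(missing)}")
    n_before = len(df)
    df = df.dropna(subset=_FEC_COLUMNS)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("read_fec: dropped %d NaN rows from %s", n_dropped, path)
    return ForceExtensionCurve(
        distance_um=df["distance_um"].to_numpy(),
        force_pN=df["force_pN"].to_numpy(),
    )
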