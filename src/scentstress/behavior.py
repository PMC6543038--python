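"""Arena and elevated-plus-maze behavioral metrics.

Input is a per-frame position trace from video tracking of a rat in a 45 cm
inescapable cage with a scent pad at one end. Freezing is operationalized as a
sustained run of sub-threshold tracking speed; avoidance as distance from the
pad end along the long axis. The exposure phase (10 min after a 2 min
adaptation) is the analysis window for all summary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARENA_LENGTH_CM = 45.0
EXPOSURE_S = 600.0
N_ZONES = 12
FREEZE_SPEED_THRESHOLD = 1.0  # cm/s
FREEZE_MIN_BOUT_S = 2.0

__all__ = [
    "Arena",
    "TrackingTrace",
    "BehaviorSummary",
    "EPMResult",
    "compute_speed",
    "detect_freezing",
    "summarize_exposure",
    "occupancy_heatmap",
    "epm_score",
]


@dataclass(frozen=True)
class Arena:
    """Rectangular cage geometry; the pad sits at one end of the long (x) axis."""

    length_cm: float = ARENA_LENGTH_CM
    width_cm: float = 20.0
    pad_position: float = ARENA_LENGTH_CM  # x coordinate of the pad end wall

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if not 0 <= self.pad_position <= self.length_cm:
            raise ValueError("pad must lie within the arena's long axis")


@dataclass(frozen=True)
class TrackingTrace:
    """Uniformly sampled per-frame positions with per-frame phase labels."""

    subject_id: str
    rate: float  # samples/s
    x: np.ndarray  # cm, along the pad axis
    y: np.ndarray  # cm
    phase: np.ndarray  # {'habituation','adaptation','exposure'} per frame
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        phase = np.asarray(self.phase)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "phase", phase)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not (x.shape == y.shape == phase.shape) or x.ndim != 1:
            raise ValueError("x, y and phase must be aligned 1-D arrays")
        if np.any(x < -1e-9) or np.any(x > self.arena.length_cm + 1e-9):
            raise ValueError("x positions outside the arena")
        if np.any(y < -1e-9) or np.any(y > self.arena.width_cm + 1e-9):
            raise ValueError("y positions outside the arena")
        n_exp = int(np.sum(phase == "exposure"))
        if n_exp and abs(n_exp / self.rate - EXPOSURE_S) > 0.5:
            raise ValueError("exposure phase must span 600 s when present")

    @property
    def t(self) -> np.ndarray:
        """Frame times in seconds (frame k at k / rate)."""
        return np.arange(self.x.size) / self.rate

    @property
    def dist_to_pad(self) -> np.ndarray:
        return np.abs(self.x - self.arena.pad_position)


def compute_speed(trace: TrackingTrace) -> np.ndarray:
    """Per-frame speed (cm/s) by central differences, one-sided at the ends."""
    n = trace.x.size
    if n < 3:
        raise ValueError("need at least 3 frames to differentiate")
    pos = np.column_stack([trace.x, trace.y])
    vel = np.gradient(pos, 1.0 / trace.rate, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def detect_freezing(
    speed,
    rate: float,
    threshold: float = FREEZE_SPEED_THRESHOLD,
    min_bout: float = FREEZE_MIN_BOUT_S,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Classify frames as freezing and list freezing bouts.

    A frame is freezing iff it belongs to a maximal run of frames with
    speed < ``threshold`` whose duration is >= ``min_bout`` seconds. Returns
    ``(mask, bouts)`` with bouts as ``(start_s, end_s)`` half-open intervals in
    frame time, non-overlapping and ordered.
    """
    speed = np.asarray(speed, dtype=float).ravel()
    if speed.size == 0:
        raise ValueError("empty speed series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    min_frames = max(1, int(np.ceil(min_bout * rate - 1e-9)))

    sub = speed < threshold
    mask = np.zeros_like(sub)
    bouts: list[tuple[float, float]] = []
    # maximal sub-threshold runs
    padded = np.diff(np.concatenate([[0], sub.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_frames:
            mask[s:e] = True
            bouts.append((s / rate, e / rate))
    return mask, bouts


def _exposure_slice(trace: TrackingTrace) -> np.ndarray:
    idx = np.flatnonzero(trace.phase == "exposure")
    if idx.size == 0:
        raise ValueError("trace has no exposure phase")
    return idx


@dataclass(frozen=True)
class BehaviorSummary:
    """Exposure-phase freezing and avoidance metrics for one subject."""

    subject_id: str
    freezing_s: float
    freezing_pct: float
    freezing_per_min: np.ndarray  # seconds frozen in each exposure minute
    mean_dist_pad_cm: float
    zone_time_s: np.ndarray  # 12 zones, zone 0 adjacent to the pad
    zone_freezing_pct: np.ndarray  # percent of total freezing per zone
    distance_traveled_cm: float
    max_speed_cm_s: float
    mean_speed_mobile_cm_s: float


def summarize_exposure(trace: TrackingTrace, freeze_mask) -> BehaviorSummary:
    """All exposure-phase metrics given a per-frame freezing mask.

    Zones are 12 equal slices (3.75 cm) of the long axis indexed from the pad
    end; per-frame distance to the pad is |x - pad_position|; zone freezing is
    normalized by the total freezing time.
    """
    freeze_mask = np.asarray(freeze_mask, dtype=bool).ravel()
    if freeze_mask.size != trace.x.size:
        raise ValueError("freeze mask length does not match frame count")
    idx = _exposure_slice(trace)
    dt = 1.0 / trace.rate

    frozen = freeze_mask[idx]
    dist = trace.dist_to_pad[idx]
    speed = compute_speed(trace)[idx]

    duration = idx.size * dt
    freezing_s = float(frozen.sum() * dt)

    minute = np.minimum((np.arange(idx.size) * dt / 60.0).astype(int), 9)
    per_min = np.bincount(minute[frozen], minlength=10).astype(float) * dt

    zone_w = trace.arena.length_cm / N_ZONES
    zone = np.minimum((dist / zone_w).astype(int), N_ZONES - 1)
    zone_time = np.bincount(zone, minlength=N_ZONES).astype(float) * dt
    zone_freeze = np.bincount(zone[frozen], minlength=N_ZONES).astype(float) * dt
    zone_freeze_pct = (
        100.0 * zone_freeze / freezing_s if freezing_s > 0 else np.zeros(N_ZONES)
    )

    steps = np.hypot(np.diff(trace.x[idx]), np.diff(trace.y[idx]))
    mobile = ~frozen
    return BehaviorSummary(
        subject_id=trace.subject_id,
        freezing_s=freezing_s,
        freezing_pct=100.0 * freezing_s / duration,
        freezing_per_min=per_min,
        mean_dist_pad_cm=float(dist.mean()),
        zone_time_s=zone_time,
        zone_freezing_pct=zone_freeze_pct,
        distance_traveled_cm=float(steps.sum()),
        max_speed_cm_s=float(speed.max()),
        mean_speed_mobile_cm_s=float(speed[mobile].mean()) if mobile.any() else 0.0,
    )


def occupancy_heatmap(trace: TrackingTrace, bins: tuple[int, int] = (12, 6)) -> np.ndarray:
    """Exposure-phase occupancy time (s) on an (nx, ny) spatial grid.

    Total mass equals the exposure duration exactly.
    """
    nx, ny = bins
    if nx < 1 or ny < 1:
        raise ValueError("need at least one bin per axis")
    idx = _exposure_slice(trace)
    h, _, _ = np.histogram2d(
        trace.x[idx],
        trace.y[idx],
        bins=bins,
        range=[[0, trace.arena.length_cm], [0, trace.arena.width_cm]],
    )
    return h / trace.rate


@dataclass(frozen=True)
class EPMResult:
    """Elevated-plus-maze arm times (s) and the open-arm anxiety score."""

    subject_id: str
    open_s: float
    closed_s: float
    center_s: float

    def __post_init__(self) -> None:
        if min(self.open_s, self.closed_s, self.center_s) < 0:
            raise ValueError("arm times must be non-negative")

    @property
    def score(self) -> float:
        return epm_score(self.open_s, self.closed_s)


def epm_score(open_s: float, closed_s: float) -> float:
    """Open-arm preference open/(open+closed); lower means more anxious."""
    if open_s < 0 or closed_s < 0:
        raise ValueError("arm times must be non-negative")
    total = open_s + closed_s
    if total == 0:
        raise ValueError("score undefined: no time in either arm")
    return open_s / total
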