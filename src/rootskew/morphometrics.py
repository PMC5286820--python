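"""Per-root shape statistics for tilted-plate skewing/waving assays.

Roots grown on a tilted, impenetrable agar surface deviate from the gravity
vector (skewing) and undulate along their growth axis (waving).  Each traced
root is an ordered 2-D polyline from the position at gravistimulation to the
root tip, with coordinates in millimetres and y increasing in the direction
of gravity (down the plate face).  From a trace this module derives:

``length_mm``
    polyline arc length,
``hgi`` / ``vgi``
    horizontal / vertical growth index — net tip displacement along the
    horizontal / vertical axis divided by arc length.  For a straight root
    at angle theta from vertical, ``hgi = sin(theta)`` and
    ``vgi = cos(theta)``.  HGI is signed: positive toward the viewer's
    right on the plate face; traces imaged through the media carry
    ``view_flipped=True`` and are negated so all HGIs share one convention,
``straightness``
    start-to-tip chord length divided by arc length (1 = perfectly
    straight),
``wave_count`` / ``wd``
    number of full waves and wave density (waves per millimetre of root).

Wave counting works on the signed perpendicular deviation of the trace from
its start-to-tip chord: the deviation profile is smoothed by a centred
moving average and maximal runs of constant sign whose peak amplitude
reaches a threshold are counted as alternating half-waves; two half-waves
make one wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ECOTYPES = ("Col-0", "WS")
ANGLES = (45, 90, 135)


class InvalidTraceError(ValueError):
    """Raised when a root trace violates its structural invariants."""


class WaveConfigError(ValueError):
    """Raised for non-positive smoothing or amplitude parameters."""


@dataclass(frozen=True)
class RootTrace:
    """One traced primary root with its experimental metadata.

    ``points`` is an (n, 2) array of (x_mm, y_mm) ordered from the position
    at gravistimulation to the tip; y grows downward (with gravity).
    """

    trace_id: str
    ecotype: str
    angle_gp: int
    replicate: int
    points: np.ndarray
    view_flipped: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidTraceError(
                f"trace {self.trace_id!r}: points must be an (n, 2) array"
            )
        if pts.shape[0] < 2:
            raise InvalidTraceError(
                f"trace {self.trace_id!r}: needs at least 2 points"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidTraceError(
                f"trace {self.trace_id!r}: non-finite coordinates"
            )
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise InvalidTraceError(
                f"trace {self.trace_id!r}: consecutive points coincide"
            )
        object.__setattr__(self, "points", pts)

    def mirrored(self) -> "RootTrace":
        """The trace reflected about the vertical axis (x -> -x)."""
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        return replace(self, points=pts)


@dataclass(frozen=True)
class WaveConfig:
    """Smoothing/thresholding parameters for wave counting.

    smooth_frac: centred moving-average window as a fraction of the number
        of trace points (window never below ``min_window`` points).
    amplitude_threshold_mm: minimum absolute chord deviation for a
        half-wave to count; sub-threshold wiggle is treated as jitter.
    """

    smooth_frac: float = 0.05
    min_window: int = 3
    amplitude_threshold_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.smooth_frac <= 0 or self.min_window <= 0:
            raise WaveConfigError("smoothing window must be positive")
        if self.amplitude_threshold_mm <= 0:
            raise WaveConfigError("amplitude threshold must be positive")


@dataclass(frozen=True)
class MorphoMetrics:
    """Derived per-root statistics."""

    trace_id: str
    length_mm: float
    hgi: float
    vgi: float
    straightness: float
    wave_count: int
    wd: float


def arc_length(trace: RootTrace) -> float:
    """Polyline arc length in mm (sum of Euclidean segment lengths)."""
    seg = np.diff(trace.points, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def growth_indices(trace: RootTrace) -> tuple[float, float]:
    """(hgi, vgi): net tip displacement over arc length, per axis.

    HGI is negated for traces imaged through the media so the sign always
    refers to the plate face seen from the front.
    """
    length = arc_length(trace)
    if length <= 0.0:
        raise InvalidTraceError(f"trace {trace.trace_id!r}: zero length")
    dx = trace.points[-1, 0] - trace.points[0, 0]
    dy = trace.points[-1, 1] - trace.points[0, 1]
    hgi = dx / length
    if trace.view_flipped:
        hgi = -hgi
    return float(hgi), float(dy / length)


def horizontal_growth_index(trace: RootTrace) -> float:
    return growth_indices(trace)[0]


def straightness(trace: RootTrace) -> float:
    """Chord length / arc length, in (0, 1]; 1 iff the trace is straight."""
    length = arc_length(trace)
    chord = float(np.hypot(*(trace.points[-1] - trace.points[0])))
    return chord / length


def _chord_deviation(points: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of each point from the start-tip chord."""
    start, tip = points[0], points[-1]
    chord = tip - start
    norm = np.hypot(*chord)
    if norm == 0.0:
        # closed trace: measure against the dominant direction instead
        raise InvalidTraceError("start and tip coincide; chord undefined")
    rel = points - start
    return (chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def wave_density(
    trace: RootTrace, cfg: WaveConfig | None = None
) -> tuple[int, float]:
    """Count full waves and return (wave_count, waves per mm).

    A half-wave is a maximal run of same-sign smoothed chord deviation
    whose peak |deviation| reaches the amplitude threshold; consecutive
    qualifying runs of identical sign (possible when a sub-threshold dip
    is discarded between them) merge.  wave_count = half_waves // 2 and
    wd = wave_count / arc_length exactly.
    """
    cfg = cfg or WaveConfig()
    n = trace.points.shape[0]
    window = max(cfg.min_window, int(round(cfg.smooth_frac * n)))
    dev = _smooth(_chord_deviation(trace.points), window)

    signs = np.sign(dev)
    half_wave_signs: list[float] = []
    i = 0
    while i < n:
        s = signs[i]
        j = i
        while j < n and signs[j] == s:
            j += 1
        if s != 0 and np.max(np.abs(dev[i:j])) >= cfg.amplitude_threshold_mm:
            if not half_wave_signs or half_wave_signs[-1] != s:
                half_wave_signs.append(s)
        i = j

    wave_count = len(half_wave_signs) // 2
    length = arc_length(trace)
    return wave_count, wave_count / length


def compute_metrics(
    trace: RootTrace, cfg: WaveConfig | None = None
) -> MorphoMetrics:
    length = arc_length(trace)
    hgi, vgi = growth_indices(trace)
    wave_count, wd = wave_density(trace, cfg)
    return MorphoMetrics(
        trace_id=trace.trace_id,
        length_mm=length,
        hgi=hgi,
        vgi=vgi,
        straightness=straightness(trace),
        wave_count=wave_count,
        wd=wd,
    )


def metrics_table(
    traces: list[RootTrace], cfg: WaveConfig | None = None
) -> pd.DataFrame:
    """One row per trace: metadata plus all derived metrics.

    ``abs_hgi`` is included alongside the signed HGI because group
    summaries of skew magnitude should not cancel across roots skewing in
    opposite directions.
    """
    rows = []
    for tr in traces:
        m = compute_metrics(tr, cfg)
        rows.append(
            {
                "trace_id": tr.trace_id,
                "ecotype": tr.ecotype,
                "angle_gp": tr.angle_gp,
                "replicate": tr.replicate,
                "length_mm": m.length_mm,
                "hgi": m.hgi,
                "abs_hgi": abs(m.hgi),
                "vgi": m.vgi,
                "straightness": m.straightness,
                "wave_count": m.wave_count,
                "wd": m.wd,
            }
        )
    if not rows:
        raise InvalidTraceError("no traces supplied")
    return pd.DataFrame(rows)


METRIC_COLUMNS = (
    "length_mm",
    "hgi",
    "abs_hgi",
    "vgi",
    "straightness",
    "wave_count",
    "wd",
)
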