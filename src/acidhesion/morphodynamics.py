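"""Cell-shape metrics, area-oscillation timing, and kymograph protrusions.

Circularity is 4πA/P² (1 for a circle, → 0 for elongated or dendritic
shapes), with A the projected cell area and P the perimeter, computed
from an outline polygon (shoelace area, edge-sum perimeter) or a binary
mask.  Kymograph edge traces are segmented into protrusion events: a
rising ramp from a local minimum to its peak or to the onset of a
plateau; events shorter than 4 pixels in height are discarded.
Protrusion velocity is the ramp slope (converted to µm/min through the
pixel and frame calibrations) and lifetime is the ramp duration plus the
plateau duration, in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ShapeMeasure",
    "AreaSeries",
    "EdgeTrace",
    "ProtrusionEvent",
    "shape_metrics",
    "area_oscillation",
    "extract_edge_trace",
    "detect_protrusions",
    "summarize_protrusions",
]

#: Events shorter than this (pixels, start of ramp to peak) are neglected.
MIN_PROTRUSION_HEIGHT_PX = 4.0

#: A frame-to-frame step within ± this tolerance (px/frame) counts as plateau.
DEFAULT_PLATEAU_TOL = 0.5


@dataclass
class ShapeMeasure:
    cell_id: str
    condition: str
    area: float  # µm²
    perimeter: float  # µm
    circularity: float  # 4πA/P², raw (may exceed 1 slightly on masks)

    @property
    def circularity_clipped(self) -> float:
        """Circularity clipped to ≤ 1 for reporting."""
        return min(self.circularity, 1.0)


@dataclass
class AreaSeries:
    """Projected cell area over time with media-switch timestamps."""

    times: np.ndarray  # min, strictly increasing
    areas: np.ndarray  # µm²
    switch_times: np.ndarray  # min

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")


@dataclass
class EdgeTrace:
    """Membrane edge position along a 1-px kymograph line, one per frame."""

    positions: np.ndarray  # px
    pixel_size: float  # µm/px
    frame_interval: float  # s
    cell_id: str = "cell0"
    condition: str = ""
    interpolated: np.ndarray | None = None  # frames whose edge was filled in

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibrations must be positive")


@dataclass
class ProtrusionEvent:
    start_frame: int
    ramp_end_frame: int
    plateau_frames: int
    height_px: float
    velocity_px_per_frame: float
    velocity_um_per_min: float
    lifetime_s: float


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_is_simple(vertices: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon

        return Polygon(vertices).is_valid
    except Exception:  # pragma: no cover - shapely always present in practice
        return True


def shape_metrics(
    outline: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
    cell_id: str = "cell0",
    condition: str = "",
) -> ShapeMeasure:
    """Area, perimeter and circularity of a cell outline or binary mask.

    Polygons use the shoelace area and edge-sum perimeter; masks use the
    pixel-count area and a Crofton boundary-length perimeter (pixel-count
    perimeters bias circularity downward).  Self-intersecting polygons and
    multi-component masks are rejected.
    """
    if (outline is None) == (mask is None):
        raise ValueError("provide exactly one of outline or mask")
    if outline is not None:
        v = np.asarray(outline, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline must be an (n, 2) array with n ≥ 3")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if not _polygon_is_simple(v):
            raise ValueError("self-intersecting polygon")
        area = abs(_shoelace(v)) * pixel_size**2
        perim = float(np.sum(np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1)))
        perim *= pixel_size
    else:
        from scipy import ndimage
        from skimage.measure import perimeter_crofton

        m = np.asarray(mask).astype(bool)
        n_comp = ndimage.label(m)[1]
        if n_comp != 1:
            raise ValueError(f"mask must contain exactly one component, found {n_comp}")
        area = float(m.sum()) * pixel_size**2
        perim = float(perimeter_crofton(m, directions=4)) * pixel_size
    if area <= 0 or perim <= 0:
        raise ValueError("degenerate shape")
    return ShapeMeasure(
        cell_id=cell_id,
        condition=condition,
        area=area,
        perimeter=perim,
        circularity=4.0 * np.pi * area / perim**2,
    )


def area_oscillation(
    series: AreaSeries, window_min: float = 60.0, smooth_points: int = 3
) -> pd.DataFrame:
    """Time-to-peak and amplitude ratio of the area response to each switch.

    For every media switch, the area peak is located (on a 3-point
    smoothed series) within ``window_min`` minutes after the switch;
    time-to-peak is peak time minus switch time and the amplitude ratio
    is peak area over the pre-switch area.  A flat response flags
    time-to-peak as undefined (NaN) with ratio 1.
    """
    if series.switch_times.size == 0:
        raise ValueError("no media switches in series")
    kernel = np.ones(smooth_points) / smooth_points
    pad = smooth_points // 2
    smooth = np.convolve(np.pad(series.areas, pad, mode="edge"), kernel, mode="valid")
    rows = []
    for ts in series.switch_times:
        sel = (series.times >= ts) & (series.times <= ts + window_min)
        if series.times[sel].size < 3:
            raise ValueError(f"fewer than 3 samples within the window after switch at {ts}")
        if series.times[-1] < ts + window_min:
            warnings.warn(f"window after switch at {ts} min truncated at series end")
        t_win = series.times[sel]
        a_win = smooth[sel]
        pre_idx = np.flatnonzero(series.times <= ts)
        pre = smooth[pre_idx[-1]] if pre_idx.size else a_win[0]
        k = int(np.argmax(a_win))
        ratio = float(a_win[k] / pre)
        undefined = a_win[k] <= pre + 1e-12 * abs(pre)
        rows.append(
            {
                "switch_time_min": float(ts),
                "time_to_peak_min": float("nan") if undefined else float(t_win[k] - ts),
                "amplitude_ratio": 1.0 if undefined else ratio,
                "undefined_peak": bool(undefined),
            }
        )
    return pd.DataFrame(rows)


def extract_edge_trace(
    kymograph: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    threshold: float | None = None,
    spatial_smooth: int = 3,
    **trace_kwargs,
) -> EdgeTrace:
    """Edge position per frame from a 2D kymograph (rows = space, cols = frames).

    Per frame the edge is the outermost (largest row index) position with
    intensity above the threshold (Otsu when not given); a short spatial
    boxcar suppresses isolated suprathreshold noise pixels beyond the
    cell.  Frames with no suprathreshold pixel are interpolated from
    neighbors and flagged; an all-subthreshold kymograph is an error.
    """
    img = np.asarray(kymograph, dtype=float)
    if img.ndim != 2:
        raise ValueError("kymograph must be a 2D array")
    if spatial_smooth > 1:
        pad = spatial_smooth // 2
        kernel = np.ones(spatial_smooth) / spatial_smooth
        img = np.apply_along_axis(
            lambda col: np.convolve(np.pad(col, pad, mode="edge"), kernel, mode="valid"),
            0,
            img,
        )
    if threshold is None:
        from skimage.filters import threshold_otsu

        if np.ptp(img) == 0:
            raise ValueError("uniform kymograph: no edge detectable")
        threshold = float(threshold_otsu(img))
    above = img > threshold
    n_frames = img.shape[1]
    pos = np.full(n_frames, np.nan)
    for j in range(n_frames):
        rows = np.flatnonzero(above[:, j])
        if rows.size:
            pos[j] = rows[-1]
    missing = np.isnan(pos)
    if missing.all():
        raise ValueError("no suprathreshold pixels in any frame")
    if missing.any():
        good = np.flatnonzero(~missing)
        pos[missing] = np.interp(np.flatnonzero(missing), good, pos[good])
    return EdgeTrace(
        positions=pos,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        interpolated=missing,
        **trace_kwargs,
    )


def _label_steps(diffs: np.ndarray, tol: float) -> np.ndarray:
    """+1 rising, 0 plateau, −1 falling per frame-to-frame step."""
    lab = np.zeros(diffs.size, dtype=int)
    lab[diffs > tol] = 1
    lab[diffs < -tol] = -1
    return lab


def detect_protrusions(
    trace: EdgeTrace,
    min_height_px: float = MIN_PROTRUSION_HEIGHT_PX,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
    smooth_points: int = 3,
) -> list[ProtrusionEvent]:
    """Segment rising ramps (+ trailing plateaus) into protrusion events.

    Steps are classified on a lightly smoothed trace (rising if the step
    exceeds ``plateau_tol``); ramp boundaries are then refined by one step
    against the raw trace so that noiseless ramps are recovered exactly.
    Height is measured start-of-ramp to peak on the raw trace; events
    below ``min_height_px`` are discarded.  Velocity = height / ramp
    duration; lifetime = (ramp + plateau frames) × frame interval.
    """
    x = trace.positions
    if x.size < 2:
        raise ValueError("trace too short")
    kernel = np.ones(smooth_points) / smooth_points
    pad = smooth_points // 2
    xs = np.convolve(np.pad(x, pad, mode="edge"), kernel, mode="valid")
    d_raw = np.diff(x)
    d_s = np.diff(xs)
    lab = _label_steps(d_s, plateau_tol)

    events: list[ProtrusionEvent] = []
    n = lab.size
    i = 0
    while i < n:
        if lab[i] != 1:
            i += 1
            continue
        j = i
        while j < n and lab[j] == 1:
            j += 1
        start, end = i, j - 1  # inclusive step indices of the rising run
        # one-step raw refinement: smoothing can bleed the run by one step
        if d_raw[start] <= plateau_tol and start + 1 <= end and d_raw[start + 1] > plateau_tol:
            start += 1
        if d_raw[end] <= plateau_tol and end - 1 >= start and d_raw[end - 1] > plateau_tol:
            end -= 1
        # trailing plateau: steps flat on the raw OR the smoothed trace
        # (the OR bridges smoothing blur at the ramp/plateau boundary while
        # a clearly falling raw step still terminates the plateau)
        p = end + 1
        while p < n and (abs(d_raw[p]) <= plateau_tol or lab[p] == 0):
            p += 1
        plateau = p - (end + 1)

        ramp_frames = end - start + 1
        height = float(x[end + 1] - x[start])
        if ramp_frames >= 1 and height >= min_height_px:
            vel_px = height / ramp_frames
            vel_um_min = vel_px * trace.pixel_size / trace.frame_interval * 60.0
            events.append(
                ProtrusionEvent(
                    start_frame=start,
                    ramp_end_frame=end + 1,
                    plateau_frames=plateau,
                    height_px=height,
                    velocity_px_per_frame=vel_px,
                    velocity_um_per_min=vel_um_min,
                    lifetime_s=(ramp_frames + plateau) * trace.frame_interval,
                )
            )
        i = max(p, j)
    return events


def summarize_protrusions(
    events: pd.DataFrame,
    by_cell_first: bool = False,
) -> pd.DataFrame:
    """Mean velocity and lifetime ± SEM per condition.

    ``events`` needs columns ``condition``, ``velocity_um_per_min``,
    ``lifetime_s`` (and ``cell_id`` when ``by_cell_first``).  Events are
    the replication unit by default; ``by_cell_first`` averages within
    cells before pooling.
    """
    if events.empty:
        raise ValueError("no protrusion events supplied")
    df = events
    if by_cell_first:
        df = (
            events.groupby(["condition", "cell_id"], as_index=False)[
                ["velocity_um_per_min", "lifetime_s"]
            ].mean()
        )
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        v = grp["velocity_um_per_min"].to_numpy()
        lt = grp["lifetime_s"].to_numpy()
        rows.append(
            {
                "condition": cond,
                "n": n,
                "velocity_mean": float(v.mean()),
                "velocity_sem": float(v.std(ddof=1) / np.sqrt(n)),
                "lifetime_mean": float(lt.mean()),
                "lifetime_sem": float(lt.std(ddof=1) / np.sqrt(n)),
            }
        )
    return pd.DataFrame(rows)
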