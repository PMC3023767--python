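"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its config (which embeds the seed):
identical configs give identical outputs, and every generator returns
ground-truth labels alongside the data so downstream estimators can be
scored without any external dataset.

* :func:`simulate_force_curves` — AFM retraction curves: Gaussian
  baseline noise plus planted linear-ramp rupture events (slope −k_eff,
  depth −F_R, instantaneous return to baseline) drawn from a "specific"
  (high force, high stiffness) or "nonspecific" (low force, low
  stiffness) population.
* :func:`simulate_prw_tracks` — 2D persistent-random-walk tracks from a
  per-component Ornstein–Uhlenbeck velocity process discretized exactly
  over the frame interval, so the closed-form MSD holds at every lag.
* :func:`simulate_shapes` — closed polygons with exact area/perimeter.
* :func:`simulate_kymograph` — piecewise-linear membrane-edge traces
  with planted protrusion ramps and plateaus.
* :func:`simulate_headpiece_frames` — annotated coordinate frames in
  which two labeled atom groups separate along y by a known schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .force_spectroscopy import ForceCurve
from .migration import Track
from .morphodynamics import EdgeTrace
from .trajectory_metrics import FrameSet

__all__ = [
    "CurveSimConfig",
    "TrackSimConfig",
    "KymoSimConfig",
    "FrameSimConfig",
    "simulate_force_curves",
    "simulate_prw_tracks",
    "simulate_shapes",
    "simulate_kymograph",
    "simulate_headpiece_frames",
]

#: Displacement sampling step of simulated retraction curves (nm/sample).
CURVE_DX_NM = 1.0


def _check_dist(name: str, dist: tuple[float, float]) -> None:
    mean, sd = dist
    if not (np.isfinite(mean) and np.isfinite(sd)):
        raise ValueError(f"{name} has non-finite parameters")
    if sd < 0:
        raise ValueError(f"{name} has negative SD")


@dataclass
class CurveSimConfig:
    """Study conditions for simulated AFM retraction curves.

    Cantilever speed and spring constant default to the experimental
    protocol (retraction at 5 µm/s, k ≈ 25 pN/nm).  The specific
    population plants high-force, high-stiffness ruptures and the
    nonspecific population low-force, low-stiffness ones, so that the
    (F_R, F′) gate separates them.
    """

    n_curves: int = 100
    velocity: float = 5000.0  # nm/s
    spring_constant: float = 25.0  # pN/nm
    noise_sd: float = 5.0  # pN
    specific_fraction: float = 0.3
    specific_force_dist: tuple[float, float] = (90.0, 15.0)  # pN
    specific_stiffness_dist: tuple[float, float] = (0.8, 0.1)  # pN/nm
    nonspecific_force_dist: tuple[float, float] = (30.0, 10.0)  # pN
    nonspecific_stiffness_dist: tuple[float, float] = (0.2, 0.05)  # pN/nm
    events_per_curve_dist: dict[int, float] = field(
        default_factory=lambda: {0: 0.3, 1: 0.5, 2: 0.2}
    )
    samples_per_curve: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.specific_fraction <= 1.0:
            raise ValueError("specific_fraction must lie in [0, 1]")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and >= 0")
        for name in (
            "specific_force_dist",
            "specific_stiffness_dist",
            "nonspecific_force_dist",
            "nonspecific_stiffness_dist",
        ):
            _check_dist(name, getattr(self, name))
        if self.velocity <= 0 or self.spring_constant <= 0:
            raise ValueError("velocity and spring constant must be > 0")
        pmf = self.events_per_curve_dist
        if not pmf or any(k < 0 for k in pmf) or any(p < 0 for p in pmf.values()):
            raise ValueError("events_per_curve_dist must be a pmf over counts >= 0")
        if not np.isclose(sum(pmf.values()), 1.0):
            raise ValueError("events_per_curve_dist probabilities must sum to 1")
        if self.samples_per_curve < 200:
            raise ValueError("samples_per_curve too small to host events")


def _plant_events(
    rng: np.random.Generator, cfg: CurveSimConfig
) -> list[tuple[int, float, float, str]]:
    """Draw (min_index, F_R, k_eff, label) for one curve, non-overlapping.

    Minima are confined to the first 75 % of the trace (the final stretch
    stays baseline so detectors can estimate noise there) and successive
    events are separated by at least the next ramp length plus the
    post-rupture window, keeping ground truth unambiguous.
    """
    counts = np.array(sorted(cfg.events_per_curve_dist))
    probs = np.array([cfg.events_per_curve_dist[int(c)] for c in counts])
    n_events = int(rng.choice(counts, p=probs))
    if n_events == 0:
        return []
    events: list[tuple[int, float, float, str]] = []
    last_min = None
    limit = int(0.75 * cfg.samples_per_curve)
    for _ in range(n_events):
        specific = rng.random() < cfg.specific_fraction
        if specific:
            f_mu, f_sd = cfg.specific_force_dist
            k_mu, k_sd = cfg.specific_stiffness_dist
        else:
            f_mu, f_sd = cfg.nonspecific_force_dist
            k_mu, k_sd = cfg.nonspecific_stiffness_dist
        f_r = max(5.0, rng.normal(f_mu, f_sd))
        k_eff = max(0.05, rng.normal(k_mu, k_sd))
        ramp = int(np.ceil(f_r / (k_eff * CURVE_DX_NM)))
        lo = ramp + 40 if last_min is None else last_min + ramp + 120
        if lo >= limit:
            break
        idx = int(rng.integers(lo, limit))
        events.append((idx, f_r, k_eff, "specific" if specific else "nonspecific"))
        last_min = idx
    return events


def simulate_force_curves(
    config: CurveSimConfig,
    cell_id: str = "cell0",
    condition: str = "",
    curve_id_prefix: str = "curve",
) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Simulated retraction curves plus a ground-truth event table.

    Each curve is a Gaussian baseline at 0 pN; each planted event is a
    linear ramp of slope −k_eff reaching −F_R at the rupture minimum,
    followed by an instantaneous return to baseline.  The truth table has
    one row per planted event: curve id, minimum index, rupture position
    (nm), F_R (pN), k_eff (pN/nm) and the population label.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_curves)
    disp = CURVE_DX_NM * np.arange(config.samples_per_curve)
    curves: list[ForceCurve] = []
    truth_rows: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        events = _plant_events(rng, config)
        force = (
            rng.normal(0.0, config.noise_sd, size=config.samples_per_curve)
            if config.noise_sd > 0
            else np.zeros(config.samples_per_curve)
        )
        cid = f"{curve_id_prefix}{i:04d}"
        for idx, f_r, k_eff, label in events:
            ramp = int(np.ceil(f_r / (k_eff * CURVE_DX_NM)))
            start = max(0, idx - ramp)
            # linear ramp of slope −k_eff descending to exactly −F_R at the minimum
            seg = -f_r - k_eff * CURVE_DX_NM * np.arange(start - idx, 1)
            force[start : idx + 1] += seg
            truth_rows.append(
                {
                    "curve_id": cid,
                    "cell_id": cell_id,
                    "condition": condition,
                    "index_of_minimum": idx,
                    "position_nm": disp[idx],
                    "F_R_pN": f_r,
                    "k_eff_pN_per_nm": k_eff,
                    "label": label,
                }
            )
        curves.append(
            ForceCurve(
                displacement=disp.copy(),
                force=force,
                velocity=config.velocity,
                spring_constant=config.spring_constant,
                cell_id=cell_id,
                condition=condition,
                curve_id=cid,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "curve_id",
            "cell_id",
            "condition",
            "index_of_minimum",
            "position_nm",
            "F_R_pN",
            "k_eff_pN_per_nm",
            "label",
        ],
    )
    return curves, truth


@dataclass
class TrackSimConfig:
    """Study conditions for simulated persistent-random-walk tracks.

    Defaults mirror the migration experiments: 5-minute frame interval
    over 8 hours (96 frames + the initial position); S and P are the RMS
    speed and persistence time of the planted walk.
    """

    n_cells: int = 200
    S_true: float = 1.0  # µm/min
    P_true: float = 20.0  # min
    dt: float = 5.0  # min
    n_frames: int = 97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S_true <= 0 or self.P_true <= 0 or self.dt <= 0:
            raise ValueError("S_true, P_true and dt must be > 0")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")


def simulate_prw_tracks(
    config: TrackSimConfig, condition: str = "", ligand_ug_per_ml: float = float("nan")
) -> list[Track]:
    """2D tracks with an exponentially correlated velocity process.

    Each velocity component is a stationary Ornstein–Uhlenbeck process
    with autocovariance (S²/2)·e^(−t/P); position increments are drawn
    jointly with the velocity update from the exact integrated-OU
    distribution (not an Euler step), so the ensemble MSD equals
    2S²P[t − P(1 − e^(−t/P))] at every lag.
    """
    s2 = config.S_true**2 / 2.0  # per-component stationary velocity variance
    p = config.P_true
    dt = config.dt
    a = np.exp(-dt / p)
    var_v = s2 * (1.0 - a * a)
    var_i = 2.0 * s2 * p * (dt - p * (1.0 - a)) - s2 * p * p * (1.0 - a) ** 2
    cov_vi = s2 * p * (1.0 - a) ** 2
    # conditional draw: n_I = (cov/sd_v)·z1 + sqrt(var_I − cov²/var_v)·z2
    sd_v = np.sqrt(var_v)
    c1 = cov_vi / sd_v if sd_v > 0 else 0.0
    c2 = np.sqrt(max(var_i - (cov_vi**2 / var_v if var_v > 0 else 0.0), 0.0))

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)
    n_steps = config.n_frames - 1
    # vectorized over cells; 2 spatial components
    v = rng.normal(0.0, np.sqrt(s2), size=(config.n_cells, 2))
    pos = np.zeros((config.n_cells, config.n_frames, 2))
    for t in range(n_steps):
        z1 = rng.standard_normal((config.n_cells, 2))
        z2 = rng.standard_normal((config.n_cells, 2))
        incr = p * (1.0 - a) * v + c1 * z1 + c2 * z2
        pos[:, t + 1] = pos[:, t] + incr
        v = a * v + sd_v * z1
    return [
        Track(
            cell_id=f"cell{i:04d}",
            positions=pos[i],
            dt=dt,
            condition=condition,
            ligand_ug_per_ml=ligand_ug_per_ml,
        )
        for i in range(config.n_cells)
    ]


def simulate_shapes(kind: str, params: dict) -> tuple[np.ndarray, float, float]:
    """Closed simple polygon of a named family plus its exact A and perimeter.

    Kinds: ``rectangle`` (width, height), ``circle_ngon`` (radius,
    n_vertices), ``star`` (n_arms, r_outer, r_inner).  Truth values come
    from the closed-form area/perimeter of each family, not from the
    vertex list.
    """
    if kind == "rectangle":
        w, h = float(params["width"]), float(params["height"])
        if w <= 0 or h <= 0:
            raise ValueError("rectangle sides must be positive")
        verts = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
        return verts, w * h, 2.0 * (w + h)
    if kind == "circle_ngon":
        r = float(params["radius"])
        n = int(params.get("n_vertices", 1024))
        if r <= 0 or n < 3:
            raise ValueError("need radius > 0 and n_vertices >= 3")
        theta = 2.0 * np.pi * np.arange(n) / n
        verts = r * np.column_stack([np.cos(theta), np.sin(theta)])
        area = 0.5 * n * r * r * np.sin(2.0 * np.pi / n)
        perim = 2.0 * n * r * np.sin(np.pi / n)
        return verts, area, perim
    if kind == "star":
        n = int(params["n_arms"])
        r_o, r_i = float(params["r_outer"]), float(params["r_inner"])
        if n < 3 or r_i <= 0 or r_o <= r_i:
            raise ValueError("star needs n_arms >= 3 and r_outer > r_inner > 0")
        theta = np.pi * np.arange(2 * n) / n
        radii = np.where(np.arange(2 * n) % 2 == 0, r_o, r_i)
        verts = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        area = n * r_o * r_i * np.sin(np.pi / n)
        edge = np.sqrt(r_o**2 + r_i**2 - 2.0 * r_o * r_i * np.cos(np.pi / n))
        return verts, area, 2.0 * n * edge
    raise ValueError(f"unknown shape kind {kind!r}")


@dataclass
class KymoSimConfig:
    """Planted protrusion events on a membrane-edge trace.

    Kymograph frames arrive every 5 s by default (the imaging protocol);
    each event is (start_frame, slope px/frame, ramp_frames,
    plateau_frames); after the plateau the edge retracts linearly back to
    baseline at ``retraction_slope``.
    """

    n_frames: int = 300
    frame_interval: float = 5.0  # s
    pixel_size: float = 0.1  # µm/px
    events: list[tuple[int, float, int, int]] = field(default_factory=list)
    noise_sd: float = 0.0  # px
    baseline_px: float = 20.0
    retraction_slope: float = 2.0  # px/frame, magnitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("calibrations must be positive")
        spans = []
        for ev in self.events:
            start, slope, ramp, plateau = ev
            if ramp < 1:
                raise ValueError("ramp_frames must be >= 1")
            if not np.isfinite(slope) or slope <= 0:
                raise ValueError("event slope must be finite and > 0")
            if plateau < 0:
                raise ValueError("plateau_frames must be >= 0")
            retract = int(np.ceil(slope * ramp / self.retraction_slope))
            end = start + ramp + plateau + retract
            if end > self.n_frames - 1:
                raise ValueError("event extends past trace end")
            spans.append((start, end))
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError("overlapping events")


def simulate_kymograph(config: KymoSimConfig) -> tuple[EdgeTrace, pd.DataFrame]:
    """Edge trace (piecewise-linear schedule + noise) and its truth table.

    Truth lists per event: start frame, slope (px/frame), ramp and
    plateau durations (frames), and height = slope × ramp_frames (px).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    x = np.full(config.n_frames, config.baseline_px, dtype=float)
    rows = []
    for start, slope, ramp, plateau in sorted(config.events):
        height = slope * ramp
        retract = int(np.ceil(height / config.retraction_slope))
        t = start
        for k in range(1, ramp + 1):
            x[t + k] = config.baseline_px + slope * k
        t += ramp
        x[t + 1 : t + plateau + 1] = config.baseline_px + height
        t += plateau
        down = height / retract
        for k in range(1, retract + 1):
            x[t + k] = config.baseline_px + height - down * k
        rows.append(
            {
                "start_frame": start,
                "slope_px_per_frame": slope,
                "ramp_frames": ramp,
                "plateau_frames": plateau,
                "height_px": height,
            }
        )
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.size)
    trace = EdgeTrace(
        positions=x, pixel_size=config.pixel_size, frame_interval=config.frame_interval
    )
    return trace, pd.DataFrame(
        rows,
        columns=["start_frame", "slope_px_per_frame", "ramp_frames", "plateau_frames", "height_px"],
    )


_ELEMENT_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008, "MG": 24.305}


def _default_group(chain: str, resid_ranges: Sequence[tuple[int, int]], n_atoms: int, rng):
    """Pseudo-residue atom template: local coordinates, elements, resids."""
    elements = np.array(["C", "N", "O"])[np.arange(n_atoms) % 3]
    spans = [np.arange(lo, hi + 1) for lo, hi in resid_ranges]
    allres = np.concatenate(spans)
    # spread pseudo-atoms across the full residue span(s)
    resids = allres[np.linspace(0, allres.size - 1, n_atoms).round().astype(int)]
    local = rng.normal(0.0, 0.8, size=(n_atoms, 3))  # ~protein-domain scale, nm
    masses = np.array([_ELEMENT_MASSES[e] for e in elements])
    atoms = pd.DataFrame(
        {"chain": chain, "resid": resids, "element": elements, "mass": masses}
    )
    return local, atoms


@dataclass
class FrameSimConfig:
    """Two rigid labeled atom groups separating along y by a schedule.

    Group A emulates the β-propeller region (chain A, residues 250–438)
    and group B the hybrid region (chain B, residues 55–106 and 356–434);
    the per-frame center-of-mass Δy equals the schedule exactly before
    per-group rigid jitter is applied.  Frames are spaced 5 ps apart.
    """

    y_offset_schedule: np.ndarray = field(default_factory=lambda: np.full(100, 4.2))
    rigid_jitter_sd: float = 0.0  # nm
    n_replicates: int = 2
    frames_per_replicate: int | None = None
    atoms_per_group: int = 30
    frame_spacing_ps: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.y_offset_schedule = np.asarray(self.y_offset_schedule, dtype=float)
        if self.frames_per_replicate is None:
            self.frames_per_replicate = self.y_offset_schedule.size
        if self.y_offset_schedule.size != self.frames_per_replicate:
            raise ValueError("schedule length must equal frames_per_replicate")
        if self.atoms_per_group < 1:
            raise ValueError("groups must be non-empty")
        if self.rigid_jitter_sd < 0:
            raise ValueError("rigid_jitter_sd must be >= 0")
        if np.any(self.y_offset_schedule < 0):
            raise ValueError("y offsets must be non-negative")


def simulate_headpiece_frames(
    config: FrameSimConfig,
    schedules: Sequence[np.ndarray] | None = None,
    condition: str = "",
) -> tuple[list[FrameSet], pd.DataFrame]:
    """One FrameSet per replicate plus the true per-frame d series.

    ``schedules`` optionally supplies a distinct Δy schedule per
    replicate (defaults to the config schedule for every replicate).
    """
    ss = np.random.SeedSequence(config.seed)
    template_rng = np.random.default_rng(ss.spawn(1)[0])
    local_a, atoms_a = _default_group("A", [(250, 438)], config.atoms_per_group, template_rng)
    local_b, atoms_b = _default_group(
        "B", [(55, 106), (356, 434)], config.atoms_per_group, template_rng
    )
    local_a = local_a - (local_a * atoms_a["mass"].to_numpy()[:, None]).sum(0) / atoms_a[
        "mass"
    ].sum()
    local_b = local_b - (local_b * atoms_b["mass"].to_numpy()[:, None]).sum(0) / atoms_b[
        "mass"
    ].sum()
    atoms = pd.concat([atoms_a, atoms_b], ignore_index=True)

    if schedules is None:
        schedules = [config.y_offset_schedule] * config.n_replicates
    if len(schedules) != config.n_replicates:
        raise ValueError("one schedule per replicate required")

    children = ss.spawn(1 + config.n_replicates)[1:]
    framesets: list[FrameSet] = []
    truth_rows = []
    for r, (child, schedule) in enumerate(zip(children, schedules)):
        schedule = np.asarray(schedule, dtype=float)
        rng = np.random.default_rng(child)
        n_frames = schedule.size
        coords = np.empty((n_frames, 2 * config.atoms_per_group, 3))
        # arbitrary but reproducible x/z offsets of group B
        xz = rng.normal(0.0, 1.0, size=(n_frames, 2))
        for f in range(n_frames):
            com_b = np.array([xz[f, 0], schedule[f], xz[f, 1]])
            frame_a = local_a.copy()
            frame_b = local_b + com_b
            if config.rigid_jitter_sd > 0:
                frame_a = frame_a + rng.normal(0.0, config.rigid_jitter_sd, size=3)
                frame_b = frame_b + rng.normal(0.0, config.rigid_jitter_sd, size=3)
            coords[f, : config.atoms_per_group] = frame_a
            coords[f, config.atoms_per_group :] = frame_b
        rid = f"rep{r}"
        framesets.append(
            FrameSet(
                replicate_id=rid,
                coords=coords,
                atoms=atoms,
                frame_spacing_ps=config.frame_spacing_ps,
                condition=condition,
            )
        )
        for f in range(n_frames):
            truth_rows.append(
                {"replicate_id": rid, "frame": f, "d_true_nm": schedule[f]}
            )
    return framesets, pd.DataFrame(truth_rows)
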