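"""AFM force-spectroscopy event analysis.

Retraction force–displacement curves are scanned for unbinding events
(sharp upward jumps in force back toward the zero-force baseline, the
adhesion force being negative while the bond is loaded).  For every event
the analysis reports

* rupture force ``F_R`` — mean force over a post-rupture window minus the
  force minimum at rupture (pN);
* effective stiffness ``k_eff`` — magnitude of the least-squares slope of
  force vs. displacement immediately before rupture (pN/nm);
* effective loading rate ``F' = k_eff * v`` with ``v`` the cantilever
  retraction velocity (pN/s).

Events with ``F_R > 50 pN`` and ``F' > 2000 pN/s`` (strict inequalities,
quadrant II of the F_R–F' plane) are classified as specific
receptor–ligand unbindings; the per-cell specific binding frequency
``f_b`` is the fraction of a cell's events passing the gate, and
``f_b_rel`` is ``f_b`` normalized to the mean ``f_b`` of a reference
condition (e.g. pH 7.4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum number of samples a retraction trace must contain.
MIN_TRACE_SAMPLES = 16

#: Default pre-rupture slope-fit window (samples).
DEFAULT_M_PRE = 30
#: Default post-rupture baseline window (samples).
DEFAULT_M_POST = 50
#: Default smoothing window for jump detection (samples, odd).
DEFAULT_SMOOTH_WINDOW = 5
#: Refractory gap between successive detections (samples).
DEFAULT_REFRACTORY = 3


@dataclass
class ForceCurve:
    """One retraction record: force vs. displacement plus metadata."""

    displacement: np.ndarray  # nm, monotone increasing during retraction
    force: np.ndarray  # pN, baseline ~0, adhesion negative
    velocity: float  # cantilever retraction speed, nm/s
    spring_constant: float  # cantilever spring constant, pN/nm
    cell_id: str = "cell0"
    condition: str = ""
    curve_id: str = "curve0"

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if self.displacement.size < MIN_TRACE_SAMPLES:
            raise ValueError(
                f"trace too short: {self.displacement.size} < {MIN_TRACE_SAMPLES} samples"
            )
        if not (np.isfinite(self.displacement).all() and np.isfinite(self.force).all()):
            raise ValueError("non-finite samples in curve")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be > 0")


@dataclass
class GateThresholds:
    """Specificity gate in the (F_R, F') plane; both inequalities strict."""

    f_r_min: float = 50.0  # pN
    f_prime_min: float = 2000.0  # pN/s

    def __post_init__(self) -> None:
        if self.f_r_min <= 0 or self.f_prime_min <= 0:
            raise ValueError("gate thresholds must be > 0")


@dataclass
class RuptureEvent:
    """One detected unbinding event with its quantified observables."""

    curve_id: str
    cell_id: str
    condition: str
    index_of_minimum: int
    F_R: float  # pN
    k_eff: float  # pN/nm
    F_prime: float  # pN/s
    quadrant: str = ""  # "I".."IV"
    specific: bool = False
    quantifiable: bool = True


@dataclass
class CellBindingSummary:
    """Per-cell specific binding frequency."""

    cell_id: str
    condition: str
    n_events_total: int
    n_events_specific: int
    f_b: float
    f_b_rel: float = float("nan")


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    # reflect-pad so the smoothed trace keeps the original length
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def robust_noise_sd(force: np.ndarray, tail_fraction: float = 0.2) -> float:
    """Robust baseline-noise SD from the final ``tail_fraction`` of a trace.

    Uses 1.4826 × MAD of the tail after removing its median, which is
    insensitive to an occasional event sample leaking into the tail.
    """
    n_tail = max(8, int(round(tail_fraction * force.size)))
    tail = force[-n_tail:]
    mad = np.median(np.abs(tail - np.median(tail)))
    return float(1.4826 * mad)


def detect_ruptures(
    curve: ForceCurve,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    jump_threshold: float | None = None,
    refractory: int = DEFAULT_REFRACTORY,
) -> list[int]:
    """Indices of force minima immediately preceding an upward jump.

    A candidate is an index ``i`` where the smoothed force rises by at
    least the jump threshold within ≤ 3 samples.  The returned index is
    refined on the raw trace: the jump is localized as the largest raw
    rise over a ≤ 3-sample span inside the candidate region, and the
    minimum is the raw ``argmin`` over the three samples ending at the
    jump start.  ``jump_threshold=None`` selects the automatic threshold
    ``max(20 pN, 4 × robust noise SD of the final 20 % of the trace)``.

    Returns an ordered (possibly empty) list of minimum indices.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd positive integer")
    f = curve.force
    n = f.size
    if jump_threshold is None:
        jump_threshold = max(20.0, 4.0 * robust_noise_sd(f))
    elif jump_threshold <= 0:
        raise ValueError("jump_threshold must be > 0")

    fs = _moving_average(f, smooth_window)
    # Forward rise of the smoothed trace over a 3-sample span.  A 1-sample
    # jump of height F_R appears in the w-smoothed trace as a rise of
    # F_R·min(span, w)/w over that span, so the threshold is scaled by the
    # same attenuation factor: the test is on the underlying jump height.
    span = 3
    atten = min(span, smooth_window) / smooth_window
    rise = np.full(n, -np.inf)
    rise[: n - span] = fs[span:] - fs[:-span]
    candidate = rise >= jump_threshold * atten

    events: list[int] = []
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        # candidate region: contiguous run of suprathreshold rises
        j = i
        while j < n and candidate[j]:
            j += 1
        lo = max(0, i - smooth_window)
        hi = min(n - 1, j + smooth_window)
        # localize the jump on the raw trace
        best_rise, jump_start = -np.inf, lo
        for span in (1, 2, 3):
            seg = f[lo + span : hi + 1] - f[lo : hi + 1 - span]
            if seg.size:
                k = int(np.argmax(seg))
                if seg[k] > best_rise:
                    best_rise, jump_start = seg[k], lo + k
        # minimum: raw argmin over the 3 samples ending at the jump start
        a = max(0, jump_start - 2)
        idx = a + int(np.argmin(f[a : jump_start + 1]))
        if not events or idx - events[-1] > refractory:
            events.append(idx)
        i = j + refractory + 1
    return events


def rupture_force(
    curve: ForceCurve,
    event_index: int,
    m_post: int = DEFAULT_M_POST,
    next_event_index: int | None = None,
) -> float:
    """Rupture force: post-rupture mean force minus the force minimum.

    The post-rupture window starts one sample after the minimum and is
    truncated at the next event (or trace end).  Returns ``nan`` when
    fewer than 3 post-rupture samples are available (event flagged
    unquantifiable by :func:`analyze_curve`).
    """
    f = curve.force
    if not 0 <= event_index < f.size:
        raise IndexError("event index outside trace")
    start = event_index + 1
    stop = f.size if next_event_index is None else min(f.size, next_event_index)
    stop = min(stop, start + m_post)
    if stop - start < 3:
        return float("nan")
    return float(np.mean(f[start:stop]) - f[event_index])


def effective_loading_rate(
    curve: ForceCurve,
    event_index: int,
    m_pre: int = DEFAULT_M_PRE,
    prev_event_index: int | None = None,
) -> tuple[float, float]:
    """``(k_eff, F')`` from the pre-rupture slope.

    ``k_eff`` is the magnitude of the least-squares slope of force vs.
    displacement over the ``m_pre`` samples ending at the minimum
    (inclusive); ``F' = k_eff × v``.  Returns ``(nan, nan)`` when fewer
    than ``m_pre`` non-overlapping pre-samples exist.
    """
    start = event_index - m_pre + 1
    if prev_event_index is not None:
        start = max(start, prev_event_index + 1)
    if start < 0 or event_index + 1 - start < m_pre:
        return float("nan"), float("nan")
    x = curve.displacement[start : event_index + 1]
    y = curve.force[start : event_index + 1]
    slope = np.polyfit(x, y, 1)[0]
    k_eff = float(abs(slope))
    return k_eff, k_eff * curve.velocity


def classify_specific(
    f_r: float, f_prime: float, gate: GateThresholds | None = None
) -> tuple[str, bool]:
    """Quadrant of the (F_R, F') plane and the specificity flag.

    Quadrant II (specific) requires strictly ``F_R > f_r_min`` and
    ``F' > f_prime_min``; I: high F' only; IV: high F_R only; III: neither.
    """
    if not (np.isfinite(f_r) and np.isfinite(f_prime)):
        raise ValueError("non-finite F_R or F'")
    gate = gate or GateThresholds()
    high_fr = f_r > gate.f_r_min
    high_fp = f_prime > gate.f_prime_min
    if high_fr and high_fp:
        return "II", True
    if high_fp:
        return "I", False
    if high_fr:
        return "IV", False
    return "III", False


def analyze_curve(
    curve: ForceCurve,
    gate: GateThresholds | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    jump_threshold: float | None = None,
    m_pre: int = DEFAULT_M_PRE,
    m_post: int = DEFAULT_M_POST,
) -> list[RuptureEvent]:
    """Detect and quantify every rupture event on one retraction curve."""
    gate = gate or GateThresholds()
    idxs = detect_ruptures(curve, smooth_window, jump_threshold)
    events: list[RuptureEvent] = []
    for k, idx in enumerate(idxs):
        nxt = idxs[k + 1] if k + 1 < len(idxs) else None
        prev = idxs[k - 1] if k > 0 else None
        f_r = rupture_force(curve, idx, m_post, next_event_index=nxt)
        k_eff, f_prime = effective_loading_rate(curve, idx, m_pre, prev_event_index=prev)
        quantifiable = np.isfinite(f_r) and np.isfinite(k_eff)
        if quantifiable:
            quadrant, specific = classify_specific(f_r, f_prime, gate)
        else:
            quadrant, specific = "", False
        events.append(
            RuptureEvent(
                curve_id=curve.curve_id,
                cell_id=curve.cell_id,
                condition=curve.condition,
                index_of_minimum=idx,
                F_R=f_r,
                k_eff=k_eff,
                F_prime=f_prime,
                quadrant=quadrant,
                specific=specific,
                quantifiable=bool(quantifiable),
            )
        )
    return events


def events_to_frame(events: Sequence[RuptureEvent]) -> pd.DataFrame:
    """Tidy table of events, one row per event."""
    return pd.DataFrame(
        {
            "curve_id": [e.curve_id for e in events],
            "cell_id": [e.cell_id for e in events],
            "condition": [e.condition for e in events],
            "index_of_minimum": [e.index_of_minimum for e in events],
            "F_R_pN": [e.F_R for e in events],
            "k_eff_pN_per_nm": [e.k_eff for e in events],
            "F_prime_pN_per_s": [e.F_prime for e in events],
            "quadrant": [e.quadrant for e in events],
            "specific": [e.specific for e in events],
            "quantifiable": [e.quantifiable for e in events],
        }
    )


def binding_frequency(events: pd.DataFrame | Sequence[RuptureEvent]) -> list[CellBindingSummary]:
    """Per-cell specific binding frequency f_b = n_specific / n_total.

    Cells contributing zero events are impossible here by construction
    (cells enter through their events); callers tracking cells with no
    events should log them separately.
    """
    if not isinstance(events, pd.DataFrame):
        events = events_to_frame(events)
    if events.empty:
        raise ValueError("no events supplied")
    out: list[CellBindingSummary] = []
    for (cell, cond), grp in events.groupby(["cell_id", "condition"], sort=True):
        n_tot = len(grp)
        n_spec = int(grp["specific"].sum())
        out.append(
            CellBindingSummary(
                cell_id=str(cell),
                condition=str(cond),
                n_events_total=n_tot,
                n_events_specific=n_spec,
                f_b=n_spec / n_tot,
            )
        )
    return out


def relative_binding_frequency(
    summaries: Sequence[CellBindingSummary], reference_condition: str
) -> list[CellBindingSummary]:
    """Normalize each cell's f_b to the reference-condition mean f_b.

    The reference-condition mean of the returned ``f_b_rel`` is exactly 1.
    """
    ref = [s.f_b for s in summaries if s.condition == reference_condition]
    if not ref:
        raise ValueError(f"no cells in reference condition {reference_condition!r}")
    ref_mean = float(np.mean(ref))
    if ref_mean == 0:
        raise ValueError("reference-condition mean f_b is zero")
    return [
        CellBindingSummary(
            cell_id=s.cell_id,
            condition=s.condition,
            n_events_total=s.n_events_total,
            n_events_specific=s.n_events_specific,
            f_b=s.f_b,
            f_b_rel=s.f_b / ref_mean,
        )
        for s in summaries
    ]


def summarize_condition(
    summaries: Sequence[CellBindingSummary],
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean ± SEM of f_b and f_b_rel per condition (cell = replicate).

    With a single cell the mean is reported and the SEM is NaN.  When the
    full event table is passed, pooled quadrant occupancy fractions per
    condition are appended as columns ``frac_I`` .. ``frac_IV``.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    rows = []
    conditions = sorted({s.condition for s in summaries})
    for cond in conditions:
        fb = np.array([s.f_b for s in summaries if s.condition == cond])
        fbr = np.array([s.f_b_rel for s in summaries if s.condition == cond])
        n = fb.size
        if n < 2:
            warnings.warn(f"condition {cond!r} has a single cell; SEM undefined")
        row = {
            "condition": cond,
            "n_cells": n,
            "f_b_mean": float(fb.mean()),
            "f_b_sem": float(fb.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
            "f_b_rel_mean": float(np.nanmean(fbr)) if np.isfinite(fbr).any() else float("nan"),
            "f_b_rel_sem": float(np.nanstd(fbr, ddof=1) / np.sqrt(n))
            if n >= 2 and np.isfinite(fbr).all()
            else float("nan"),
        }
        if events is not None:
            ev = events[(events["condition"] == cond) & events["quantifiable"]]
            n_ev = len(ev)
            for q in ("I", "II", "III", "IV"):
                row[f"frac_{q}"] = float((ev["quadrant"] == q).sum() / n_ev) if n_ev else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
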