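"""Headpiece-opening and residue–ion distance metrics on coordinate frames.

The integrin headpiece "opens" when the hybrid domain swings away from
the β-propeller.  Opening is quantified per frame as the y-component
distance ``d = |COM_A.y − COM_B.y|`` between the center of mass of a
β-propeller region (α-chain residues 250–438 by default) and a hybrid
region (β-chain residues 55–106 and 356–434).  Residue–ion coordination
(e.g. ADMIDAS ion vs. ASP β127) uses the full 3D COM–COM distance.
Per-replicate distance series are binned into a replicate histogram:
each replicate is normalized to sum 1 independently, then per-bin mean
and SEM are taken across replicates.

Selections use a compact ``chain:lo-hi+lo-hi`` syntax, e.g.
``"A:250-438"`` or ``"B:55-106+356-434"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSet",
    "DistanceSeries",
    "ReplicateHistogram",
    "parse_selection",
    "group_com",
    "opening_distance",
    "opening_distance_series",
    "residue_ion_distance",
    "replicate_histogram",
    "DEFAULT_PROPELLER_SELECTION",
    "DEFAULT_HYBRID_SELECTION",
]

#: β-propeller region used for the opening distance (α chain, "A").
DEFAULT_PROPELLER_SELECTION = "A:250-438"
#: Hybrid-domain region used for the opening distance (β chain, "B").
DEFAULT_HYBRID_SELECTION = "B:55-106+356-434"


@dataclass
class FrameSet:
    """Ordered coordinate snapshots sharing one atom annotation table.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; ``atoms`` carries
    per-atom ``chain``, ``resid``, ``element`` and ``mass`` columns in the
    same order for every frame.
    """

    replicate_id: str
    coords: np.ndarray  # (n_frames, n_atoms, 3), nm
    atoms: pd.DataFrame  # columns: chain, resid, element, mass
    frame_spacing_ps: float = 5.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table length must match coordinate atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        required = {"chain", "resid", "mass"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, selection: str) -> np.ndarray:
        """Atom indices matching a ``chain:lo-hi+lo-hi`` selection string."""
        terms = parse_selection(selection)
        chains = self.atoms["chain"].to_numpy()
        resids = self.atoms["resid"].to_numpy()
        mask = np.zeros(len(self.atoms), dtype=bool)
        for chain, lo, hi in terms:
            mask |= (chains == chain) & (resids >= lo) & (resids <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        # report ranges with no atoms at all, to catch typos in residue numbering
        for chain, lo, hi in terms:
            if not np.any((chains == chain) & (resids >= lo) & (resids <= hi)):
                raise ValueError(
                    f"selection term {chain}:{lo}-{hi} matches no residues in frame set"
                )
        return idx


@dataclass
class DistanceSeries:
    replicate_id: str
    values: np.ndarray  # nm, one per frame
    condition: str = ""
    metric: str = "opening_distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ReplicateHistogram:
    bin_edges: np.ndarray  # nm
    per_replicate: np.ndarray  # (n_replicates, n_bins), each row sums to 1
    mean: np.ndarray
    sem: np.ndarray
    replicate_ids: list[str] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


_SELECTION_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*(\d+\s*-\s*\d+(?:\s*\+\s*\d+\s*-\s*\d+)*)\s*$")


def parse_selection(selection: str) -> list[tuple[str, int, int]]:
    """Parse ``chain:lo-hi+lo-hi[,chain:...]`` into (chain, lo, hi) terms."""
    terms: list[tuple[str, int, int]] = []
    for part in selection.split(","):
        m = _SELECTION_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse selection term {part!r}")
        chain = m.group(1)
        for rng in m.group(2).split("+"):
            lo_s, hi_s = rng.split("-")
            lo, hi = int(lo_s), int(hi_s)
            if hi < lo:
                raise ValueError(f"inverted residue range {rng!r} in {part!r}")
            terms.append((chain, lo, hi))
    return terms


def group_com(
    coords: np.ndarray, masses: np.ndarray | None = None, use_masses: bool = True
) -> np.ndarray:
    """Center of mass of an atom group; unweighted mean if masses unused."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty selection")
    if use_masses and masses is not None:
        m = np.asarray(masses, dtype=float)
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
        return (coords * m[:, None]).sum(axis=0) / m.sum()
    return coords.mean(axis=0)


def opening_distance(
    frames: FrameSet,
    frame_index: int,
    sel_a: str = DEFAULT_PROPELLER_SELECTION,
    sel_b: str = DEFAULT_HYBRID_SELECTION,
    use_masses: bool = True,
) -> float:
    """Headpiece-opening distance of one frame: |Δy| of the two group COMs."""
    ia, ib = frames.select(sel_a), frames.select(sel_b)
    masses = frames.atoms["mass"].to_numpy()
    com_a = group_com(frames.coords[frame_index, ia], masses[ia], use_masses)
    com_b = group_com(frames.coords[frame_index, ib], masses[ib], use_masses)
    return float(abs(com_a[1] - com_b[1]))


def opening_distance_series(
    frames: FrameSet,
    sel_a: str = DEFAULT_PROPELLER_SELECTION,
    sel_b: str = DEFAULT_HYBRID_SELECTION,
    use_masses: bool = True,
) -> DistanceSeries:
    """Per-frame opening distance for a whole replicate."""
    ia, ib = frames.select(sel_a), frames.select(sel_b)
    masses = frames.atoms["mass"].to_numpy()
    if use_masses:
        wa = masses[ia] / masses[ia].sum()
        wb = masses[ib] / masses[ib].sum()
    else:
        wa = np.full(ia.size, 1.0 / ia.size)
        wb = np.full(ib.size, 1.0 / ib.size)
    ya = frames.coords[:, ia, 1] @ wa
    yb = frames.coords[:, ib, 1] @ wb
    return DistanceSeries(
        replicate_id=frames.replicate_id,
        values=np.abs(ya - yb),
        condition=frames.condition,
        metric="opening_distance",
    )


def residue_ion_distance(
    frames: FrameSet,
    residue_selection: str,
    ion_selection: str,
    use_masses: bool = True,
) -> tuple[DistanceSeries, float, float]:
    """3D COM–COM distance per frame, plus the replicate mean and SEM.

    Unlike the opening distance this is the full Euclidean distance; it
    tracks e.g. loss of ADMIDAS-ion coordination by a protonated residue.
    """
    ir, ii = frames.select(residue_selection), frames.select(ion_selection)
    masses = frames.atoms["mass"].to_numpy()
    if use_masses:
        wr = masses[ir] / masses[ir].sum()
        wi = masses[ii] / masses[ii].sum()
    else:
        wr = np.full(ir.size, 1.0 / ir.size)
        wi = np.full(ii.size, 1.0 / ii.size)
    com_r = np.einsum("fas,a->fs", frames.coords[:, ir, :], wr)
    com_i = np.einsum("fas,a->fs", frames.coords[:, ii, :], wi)
    d = np.linalg.norm(com_r - com_i, axis=1)
    series = DistanceSeries(
        replicate_id=frames.replicate_id,
        values=d,
        condition=frames.condition,
        metric="residue_ion_distance",
    )
    n = d.size
    sem = float(d.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return series, float(d.mean()), sem


def replicate_histogram(
    series: Sequence[DistanceSeries],
    bin_width: float = 0.05,
    value_range: tuple[float, float] | None = None,
) -> ReplicateHistogram:
    """Replicate-averaged distance histogram with per-bin SEM.

    Each replicate is binned on shared edges and normalized to sum 1
    independently; mean and SEM are taken across replicates per bin.
    Values outside an explicit range extend the range (with a warning)
    so that the per-replicate normalization stays exact.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 replicates")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    allv = np.concatenate([s.values for s in series])
    lo = allv.min() if value_range is None else value_range[0]
    hi = allv.max() if value_range is None else value_range[1]
    if value_range is not None and (allv.min() < lo or allv.max() > hi):
        import warnings

        warnings.warn("values outside requested range; extending range")
        lo, hi = min(lo, allv.min()), max(hi, allv.max())
    # snap edges to multiples of the bin width for comparability across calls
    first = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - first) / bin_width + 1e-9)))
    edges = first + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:  # right-closed last bin
        edges = np.append(edges, edges[-1] + bin_width)

    freqs = np.empty((len(series), edges.size - 1))
    for i, s in enumerate(series):
        counts, _ = np.histogram(s.values, bins=edges)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"replicate {s.replicate_id!r} has no values in range")
        freqs[i] = counts / total
    mean = freqs.mean(axis=0)
    sem = freqs.std(axis=0, ddof=1) / np.sqrt(len(series))
    return ReplicateHistogram(
        bin_edges=edges,
        per_replicate=freqs,
        mean=mean,
        sem=sem,
        replicate_ids=[s.replicate_id for s in series],
    )
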