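"""Readers and writers for the pipeline's on-disk formats.

Conventions: tidy CSV with units encoded in column names (``_nm``,
``_pN``, ``_um``, ``_min`` …) and no implicit conversions; coordinate
frames as multi-model PDB (MODEL/ENDMDL records) or plain XYZ with a
sidecar JSON map assigning each atom a chain and residue id.  Writers
and readers round-trip losslessly at the precision written.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .force_spectroscopy import ForceCurve
from .migration import Track
from .trajectory_metrics import FrameSet

__all__ = [
    "write_curves",
    "read_curves",
    "write_tracks",
    "read_tracks",
    "write_frames_pdb",
    "write_frames_xyz",
    "read_frames",
    "read_polygon_csv",
    "write_polygon_csv",
    "read_config",
]

CURVE_COLUMNS = ["curve_id", "cell_id", "condition", "displacement_nm", "force_pN"]
CURVE_META_COLUMNS = ["curve_id", "velocity_nm_per_s", "spring_constant_pN_per_nm"]
TRACK_COLUMNS = ["cell_id", "condition", "frame", "x_um", "y_um"]

#: Standard atomic masses for the elements the frame writer emits.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "MG": 24.305,
    "MN": 54.938,
    "CA": 40.078,
}


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def write_curves(curves: Sequence[ForceCurve], curves_path, meta_path) -> None:
    """Long-format samples CSV plus a per-curve metadata CSV."""
    frames = []
    meta_rows = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "cell_id": c.cell_id,
                    "condition": c.condition,
                    "displacement_nm": c.displacement,
                    "force_pN": c.force,
                }
            )
        )
        meta_rows.append(
            {
                "curve_id": c.curve_id,
                "velocity_nm_per_s": c.velocity,
                "spring_constant_pN_per_nm": c.spring_constant,
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(curves_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def read_curves(curves_path, meta_path) -> list[ForceCurve]:
    df = pd.read_csv(curves_path)
    meta = pd.read_csv(meta_path)
    if "condition" in df.columns:
        df["condition"] = df["condition"].fillna("")
    _require_columns(df, CURVE_COLUMNS, "curves CSV")
    _require_columns(meta, CURVE_META_COLUMNS, "curve metadata CSV")
    meta = meta.set_index("curve_id")
    curves = []
    for cid, grp in df.groupby("curve_id", sort=False):
        if cid not in meta.index:
            raise SchemaError(f"curve {cid!r} missing from metadata CSV")
        m = meta.loc[cid]
        curves.append(
            ForceCurve(
                displacement=grp["displacement_nm"].to_numpy(),
                force=grp["force_pN"].to_numpy(),
                velocity=float(m["velocity_nm_per_s"]),
                spring_constant=float(m["spring_constant_pN_per_nm"]),
                cell_id=str(grp["cell_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
                curve_id=str(cid),
            )
        )
    return curves


def write_tracks(tracks: Sequence[Track], path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "condition": t.condition,
                    "ligand_ug_per_ml": t.ligand_ug_per_ml,
                    "frame": np.arange(t.n_frames),
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path, dt: float) -> list[Track]:
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, "tracks CSV")
    df["condition"] = df["condition"].fillna("")
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) != 1):
            raise SchemaError(f"track {cid!r} has non-consecutive frames")
        tracks.append(
            Track(
                cell_id=str(cid),
                positions=grp[["x_um", "y_um"]].to_numpy(),
                dt=dt,
                condition=str(grp["condition"].iloc[0]),
                ligand_ug_per_ml=float(grp["ligand_ug_per_ml"].iloc[0])
                if "ligand_ug_per_ml" in grp
                else float("nan"),
            )
        )
    return tracks


def write_frames_pdb(frames: FrameSet, path) -> None:
    """Multi-model PDB (MODEL/ENDMDL); coordinates converted nm → Å."""
    atoms = frames.atoms
    with open(path, "w") as fh:
        fh.write(f"REMARK   1 replicate {frames.replicate_id}\n")
        for f in range(frames.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(len(atoms)):
                el = str(atoms["element"].iloc[i]) if "element" in atoms else "C"
                x, y, z = frames.coords[f, i] * 10.0  # nm -> Å
                fh.write(
                    "ATOM  {serial:5d} {name:^4s} {res:>3s} {chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=i + 1,
                        name=f"{el}{i % 100}"[:4],
                        res="GLY",
                        chain=str(atoms["chain"].iloc[i])[:1],
                        resid=int(atoms["resid"].iloc[i]),
                        x=x,
                        y=y,
                        z=z,
                        occ=1.0,
                        b=0.0,
                        el=el[:2],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_frames_xyz(frames: FrameSet, xyz_path, sidecar_path) -> None:
    """Plain XYZ (one block per frame, nm) + JSON chain/resid sidecar."""
    atoms = frames.atoms
    with open(xyz_path, "w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"{len(atoms)}\nframe {f}\n")
            for i in range(len(atoms)):
                el = str(atoms["element"].iloc[i]) if "element" in atoms else "C"
                x, y, z = frames.coords[f, i]
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    sidecar = {
        "replicate_id": frames.replicate_id,
        "frame_spacing_ps": frames.frame_spacing_ps,
        "atoms": [
            {"chain": str(atoms["chain"].iloc[i]), "resid": int(atoms["resid"].iloc[i])}
            for i in range(len(atoms))
        ],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _read_frames_pdb(path, replicate_id: str | None) -> FrameSet:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("frames", str(path))
    models = list(structure)
    if not models:
        raise SchemaError("PDB file contains no MODEL records")
    rows = None
    coords = []
    for model in models:
        frame_atoms = []
        frame_rows = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    frame_atoms.append(atom.coord / 10.0)  # Å -> nm
                    el = (atom.element or "C").upper().strip()
                    frame_rows.append(
                        {
                            "chain": chain.id,
                            "resid": residue.id[1],
                            "element": el,
                            "mass": ATOMIC_MASSES.get(el, 12.011),
                        }
                    )
        if rows is None:
            rows = frame_rows
        elif len(frame_rows) != len(rows):
            raise SchemaError("mixed atom counts across PDB models")
        coords.append(np.asarray(frame_atoms))
    return FrameSet(
        replicate_id=replicate_id or Path(path).stem,
        coords=np.stack(coords),
        atoms=pd.DataFrame(rows),
    )


def _read_frames_xyz(xyz_path, sidecar_path, replicate_id: str | None) -> FrameSet:
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    atom_map = sidecar["atoms"]
    n_atoms = len(atom_map)
    coords = []
    elements = []
    with open(xyz_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        count = int(lines[i].strip())
        if count != n_atoms:
            raise SchemaError("XYZ frame atom count differs from sidecar map")
        block = lines[i + 2 : i + 2 + count]
        frame = np.empty((count, 3))
        frame_el = []
        for k, ln in enumerate(block):
            parts = ln.split()
            frame_el.append(parts[0].upper())
            frame[k] = [float(p) for p in parts[1:4]]
        coords.append(frame)
        elements = frame_el
        i += 2 + count
    atoms = pd.DataFrame(
        {
            "chain": [a["chain"] for a in atom_map],
            "resid": [int(a["resid"]) for a in atom_map],
            "element": elements,
            "mass": [ATOMIC_MASSES.get(e, 12.011) for e in elements],
        }
    )
    return FrameSet(
        replicate_id=replicate_id or sidecar.get("replicate_id", Path(xyz_path).stem),
        coords=np.stack(coords),
        atoms=atoms,
        frame_spacing_ps=float(sidecar.get("frame_spacing_ps", 5.0)),
    )


def read_frames(path, sidecar_path=None, replicate_id: str | None = None) -> FrameSet:
    """Read coordinate frames from multi-model PDB or XYZ(+JSON sidecar)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return _read_frames_pdb(path, replicate_id)
    if suffix == ".xyz":
        if sidecar_path is None:
            raise SchemaError("XYZ input requires a sidecar JSON group map")
        return _read_frames_xyz(path, sidecar_path, replicate_id)
    raise SchemaError(f"unsupported frame format {suffix!r}")


def write_polygon_csv(vertices: np.ndarray, path) -> None:
    pd.DataFrame(vertices, columns=["x_um", "y_um"]).to_csv(path, index=False)


def read_polygon_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "y_um"], "polygon CSV")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def read_config(path) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in {".yaml", ".yml"}:
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("run configuration must be a mapping")
    return cfg
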