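"""Reading and writing sessions.

On-disk layout (bound together by a ``session.json`` manifest):

- ``tracking.csv``  columns ``t,x,y,hd`` (header required, missing = empty)
- ``spikes.csv``    columns ``cell_id,tetrode_id,t``
- ``schedule.csv``  columns ``start,end,condition``
- one raw float32 vector per LFP channel plus the sampling rate recorded
  in the manifest

``write_session`` emits a canonical formatting (``%.10g`` floats), so
``write(load(p))`` is byte-identical on canonically written files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LFPTrace, Session, SpikeTrain, Trajectory, TrialSchedule, ValidationError

_FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """A session file could not be parsed."""


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas error types vary; report the file
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def load_session(path: str | Path) -> Session:
    """Load a session from a manifest file (or a directory containing one).

    Raises :class:`ParseError` on malformed files and
    :class:`parahd.core.ValidationError` on invariant violations.
    """
    path = Path(path)
    manifest_path = path / "session.json" if path.is_dir() else path
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    root = manifest_path.parent
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{manifest_path}: {exc}") from exc

    tr = _read_csv(root / manifest["tracking"], ["t", "x", "y", "hd"])
    trajectory = Trajectory(
        tr["t"].to_numpy(float), tr["x"].to_numpy(float),
        tr["y"].to_numpy(float), tr["hd"].to_numpy(float),
    )

    sc = _read_csv(root / manifest["schedule"], ["start", "end", "condition"])
    schedule = TrialSchedule(
        sc["start"].to_numpy(float), sc["end"].to_numpy(float),
        sc["condition"].to_numpy(object),
    )

    sp = _read_csv(root / manifest["spikes"], ["cell_id", "tetrode_id", "t"])
    cells = []
    for cell_id, grp in sp.groupby("cell_id", sort=True):
        tets = grp["tetrode_id"].unique()
        if tets.size > 1:
            raise ValidationError(f"cell {cell_id} assigned to several tetrodes")
        cells.append(SpikeTrain(str(cell_id), str(tets[0]), np.sort(grp["t"].to_numpy(float))))

    lfp = []
    for entry in manifest.get("lfp", []):
        samples = np.fromfile(root / entry["file"], dtype=np.float32).astype(float)
        lfp.append(LFPTrace(str(entry["tetrode_id"]), float(entry["fs"]), samples))

    return Session(trajectory, schedule, lfp=lfp, cells=cells,
                   meta=manifest.get("meta", {}))


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session in the canonical on-disk layout; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    traj = session.trajectory
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y, "hd": traj.hd}).to_csv(
        out / "tracking.csv", index=False, float_format=_FLOAT_FMT, na_rep="")

    pd.DataFrame({
        "start": session.schedule.starts,
        "end": session.schedule.ends,
        "condition": session.schedule.conditions,
    }).to_csv(out / "schedule.csv", index=False, float_format=_FLOAT_FMT)

    rows = [
        pd.DataFrame({"cell_id": c.cell_id, "tetrode_id": c.tetrode_id, "t": c.times})
        for c in sorted(session.cells, key=lambda c: c.cell_id)
    ]
    spikes = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["cell_id", "tetrode_id", "t"])
    spikes.to_csv(out / "spikes.csv", index=False, float_format=_FLOAT_FMT)

    lfp_entries = []
    for trace in session.lfp:
        fname = f"lfp_{trace.tetrode_id}.f32"
        trace.samples.astype(np.float32).tofile(out / fname)
        lfp_entries.append({"tetrode_id": trace.tetrode_id, "fs": trace.fs, "file": fname})

    manifest = {
        "tracking": "tracking.csv",
        "spikes": "spikes.csv",
        "schedule": "schedule.csv",
        "lfp": lfp_entries,
        "meta": session.meta,
    }
    manifest_path = out / "session.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
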