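"""File formats: track CSV, field snapshots, phase-diagram CSV, manifest.

All coordinates in files are dimensionless chamber units with the origin at
the cell-entry wall and ``y`` increasing toward the chemoattractant
reservoir; every writer states this in a comment header.  Track tables are
CSV with required columns ``cell_id, frame, t, x, y`` (extra columns such as
``theta`` ride along); values round-trip losslessly at 12 significant
digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import TRACK_COLUMNS

__all__ = ["read_tracks", "write_tracks", "write_snapshot", "read_snapshot",
           "write_phase_diagram", "write_manifest", "verify_manifest"]

log = logging.getLogger(__name__)

_HEADER_NOTE = ("coordinates are dimensionless chamber units; origin at the "
                "cell-entry wall, y increases toward the cAMP reservoir")


def write_tracks(tracks: pd.DataFrame, path) -> Path:
    """Write a track table as CSV (comment header + column header)."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# {_HEADER_NOTE}\n")
        tracks.to_csv(f, index=False, float_format="%.12g")
    return path


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track CSV.

    Leading ``#`` comment lines are skipped.  Raises a ``ValueError`` naming
    the offending line for missing columns, duplicated ``(cell_id, frame)``
    rows, or frames that fail to increase within a cell's rows.
    """
    path = Path(path)
    n_comments = 0
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=n_comments)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no header row found") from None
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.astype({"cell_id": np.int64, "frame": np.int64,
                    "t": float, "x": float, "y": float})

    def lineno(i: int) -> int:
        return i + n_comments + 2  # comments + header, 1-based

    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: line {lineno(i)}: duplicate "
                         f"(cell_id, frame) = ({df['cell_id'].iat[i]}, "
                         f"{df['frame'].iat[i]})")
    same = df["cell_id"].eq(df["cell_id"].shift())
    nonmono = same & (df["frame"].diff() <= 0)
    if nonmono.any():
        i = int(np.flatnonzero(nonmono.to_numpy())[0])
        raise ValueError(f"{path}: line {lineno(i)}: frames not increasing "
                         f"for cell {df['cell_id'].iat[i]}")
    return df


def write_snapshot(values: np.ndarray, path, *, h: float, t: float) -> Path:
    """Write one field snapshot as plain text.

    Layout: row-major text matrix whose rows are the ``j`` (``y``) index and
    columns the ``i`` (``x``) index, i.e. the transpose of the in-memory
    ``(Nx, Ny)`` array; recorded in the header together with ``h`` and the
    snapshot time.
    """
    path = Path(path)
    nx, ny = values.shape
    np.savetxt(path, values.T, fmt="%.9e", header=(
        f"{_HEADER_NOTE}\n"
        f"t={t:.12g} h={h:.12g} Nx={nx} Ny={ny}\n"
        "rows: j (y index, 0 = entry wall); columns: i (x index)"))
    return path


def read_snapshot(path) -> tuple[np.ndarray, dict]:
    """Read a snapshot written by :func:`write_snapshot`.

    Returns the in-memory ``(Nx, Ny)`` array and the header attributes.
    """
    attrs: dict = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    key, val = tok.split("=", 1)
                    try:
                        attrs[key] = float(val) if "." in val or "e" in val \
                            else int(val)
                    except ValueError:
                        pass
    return np.loadtxt(path).T, attrs


def write_phase_diagram(runs: pd.DataFrame, path) -> Path:
    """Per-realization sweep results: beta, kdeg, rep, u_bar, rho_max, label."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# {_HEADER_NOTE}\n")
        runs.to_csv(f, index=False, float_format="%.12g")
    return path


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path, *, config: dict, seed, t_start: float, t_end: float,
                   outputs: list) -> Path:
    """JSON run manifest: config echo, seed, version, output checksums."""
    from . import __version__
    path = Path(path)
    manifest = {
        "version": __version__,
        "config": config,
        "seed": seed,
        "t_start": t_start,
        "t_end": t_end,
        "outputs": [{"path": Path(p).name, "sha256": _sha256(Path(p))}
                    for p in outputs],
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def verify_manifest(path) -> bool:
    """Re-hash the listed outputs; True iff every checksum matches."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    for entry in manifest["outputs"]:
        target = path.parent / entry["path"]
        if not target.exists() or _sha256(target) != entry["sha256"]:
            log.warning("manifest mismatch for %s", target)
            return False
    return True
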