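"""Plain-text file formats: trace CSV + JSON sidecars, cohort / kinship /
feature / results tables with provenance headers."""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ergtwin.cohort import Session
from ergtwin.forward_model import Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_session",
    "read_session",
    "write_table",
    "read_table",
    "write_kinship",
    "read_kinship",
]

_FLOAT_FMT = "%.17g"  # exact double round-trip for traces


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9.+-]+", "_", text)


def write_trace(trace: Trace, path: Path) -> Path:
    """One sweep as two-column CSV (time_ms, voltage_uV) plus a JSON
    sidecar with the sweep metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_ms,voltage_uV\n")
        for t, v in zip(trace.times, trace.volts):
            fh.write(f"{t:.17g},{v:.17g}\n")
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(trace.meta, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return path


def read_trace(path: Path) -> Trace:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    meta: Dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Trace(arr[:, 0], arr[:, 1], meta)


def write_session(session: Session, directory: Path) -> Path:
    """All sweeps of one subject, one CSV+JSON pair per sweep, plus the
    generator log."""
    directory = Path(directory) / session.subject_id
    directory.mkdir(parents=True, exist_ok=True)
    for sw in session.sweeps:
        name = "{}_{}_{:02d}.csv".format(
            _slug(sw.meta["stimulus"]), sw.meta["eye"], sw.meta["sweep"]
        )
        write_trace(sw, directory / name)
    with open(directory / "session_log.json", "w") as fh:
        json.dump(session.log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return directory


def read_session(directory: Path) -> Session:
    directory = Path(directory)
    sweeps = [
        read_trace(p)
        for p in sorted(directory.glob("*.csv"))
    ]
    log_path = directory / "session_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}
    return Session(subject_id=directory.name, sweeps=sweeps, log=log)


def write_table(
    df: pd.DataFrame,
    path: Path,
    provenance: Optional[Dict[str, str]] = None,
    index: bool = True,
    float_format: str = "%.10g",
) -> Path:
    """CSV with '#'-prefixed provenance header lines (config hash, seed,
    version) so every output file is traceable to its inputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index, float_format=float_format, lineterminator="\n")
    return path


def read_table(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_kinship(
    K: np.ndarray, ids: Sequence[str], path: Path,
    provenance: Optional[Dict[str, str]] = None,
) -> Path:
    df = pd.DataFrame(K, index=list(ids), columns=list(ids))
    df.index.name = "subject_id"
    return write_table(df, path, provenance, float_format="%.6g")


def read_kinship(path: Path):
    df = read_table(path)
    return df.to_numpy(dtype=float), list(df.index)


def write_jsonl(records: Iterable[Dict], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
    return path
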