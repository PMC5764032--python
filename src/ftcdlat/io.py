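"""Plain-text file formats for recordings, cohort tables and results.

All tables are tab-separated with a single leading comment line carrying the
schema name, version and any scalar attributes, e.g.::

    # ftcdlat-recording v1  child_id=P0001-1  sampling_rate=25.0
    time_s  left_cm_s   right_cm_s
    ...

Recording files hold only the sampled channels; talk-onset markers, validity
flags and word counts live in the cohort-level trial-metadata table (columns
child_id, trial_index, talk_onset_s, valid_flag, word_count). Floats are
written with Python's shortest round-trip representation, so read(write(x))
is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ftcd import RawRecording

SCHEMA_VERSION = 1


def _header(schema: str, **attrs) -> str:
    parts = [f"# ftcdlat-{schema} v{SCHEMA_VERSION}"]
    parts += [f"{k}={v}" for k, v in attrs.items()]
    return "\t".join(parts) + "\n"


def _read_header(path: Path, schema: str) -> dict:
    with open(path) as fh:
        line = fh.readline()
    if not line.startswith(f"# ftcdlat-{schema} v"):
        raise ValidationError(f"{path}: not a ftcdlat-{schema} file")
    attrs = {}
    for tok in line.strip().split("\t")[1:]:
        k, _, v = tok.partition("=")
        attrs[k] = v
    return attrs


def write_recording(rec: RawRecording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header("recording", child_id=rec.child_id, sampling_rate=rec.sampling_rate))
        fh.write("time_s\tleft_cm_s\tright_cm_s\n")
        # 17 significant digits: exact binary64 round trip
        np.savetxt(fh, np.column_stack([rec.time, rec.left, rec.right]),
                   fmt="%.17g", delimiter="\t")


def read_recording(path: str | Path, trials: pd.DataFrame) -> RawRecording:
    """Read a recording file; per-trial annotations come from the trial table."""
    path = Path(path)
    attrs = _read_header(path, "recording")
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    child_id = attrs["child_id"]
    sub = trials[trials["child_id"] == child_id].sort_values("trial_index")
    return RawRecording(
        child_id=child_id,
        sampling_rate=float(attrs["sampling_rate"]),
        time=df["time_s"].to_numpy(),
        left=df["left_cm_s"].to_numpy(),
        right=df["right_cm_s"].to_numpy(),
        markers=sub["talk_onset_s"].to_numpy(dtype=float),
        trial_validity=sub["valid_flag"].to_numpy(dtype=bool),
        word_counts=sub["word_count"].to_numpy(dtype=int),
    )


def write_table(df: pd.DataFrame, path: str | Path, schema: str, **attrs) -> None:
    with open(path, "w") as fh:
        fh.write(_header(schema, **attrs))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    _read_header(Path(path), schema)
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results_json(results: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
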