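"""Recording persistence: a columnar Parquet table plus a JSON sidecar.

The table holds the four sampled columns (time_s, airflow_V, dia_V, abd_V)
in float64, which round-trips bit-exactly. The sidecar carries the
acquisition metadata under fixed field names: fs, t_inj1_end, t_inj2_end,
fio2, feo2, calibration, body_mass_kg, seed, preset — plus n_samples and
schema_version for integrity checking. The generation breath plan is
in-memory state and is not serialized.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pyarrow as pa
import pyarrow.parquet as pq

from .synth import Recording

SCHEMA_VERSION = 1
REQUIRED_FIELDS = (
    "fs", "t_inj1_end", "t_inj2_end", "fio2", "feo2",
    "calibration", "body_mass_kg", "seed", "preset",
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording to ``path`` (Parquet) with its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = rec.n_samples
    table = pa.table(
        {
            "time_s": np.arange(n) / rec.fs,
            "airflow_V": np.asarray(rec.airflow, dtype=np.float64),
            "dia_V": np.asarray(rec.dia_raw, dtype=np.float64),
            "abd_V": np.asarray(rec.abd_raw, dtype=np.float64),
        }
    )
    pq.write_table(table, path)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "n_samples": n,
        "fs": rec.fs,
        "t_inj1_end": rec.t_inj1_end,
        "t_inj2_end": rec.t_inj2_end,
        "fio2": rec.fio2,
        "feo2": rec.feo2,
        "calibration": [list(p) for p in rec.calibration],
        "body_mass_kg": rec.body_mass_kg,
        "seed": rec.seed,
        "preset": rec.preset,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises a format error naming the offending field on a malformed sidecar
    or a channel-length mismatch.
    """
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    try:
        meta = json.loads(sidecar_file.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar: {exc}") from exc
    for key in REQUIRED_FIELDS:
        if key not in meta:
            raise ValueError(f"missing required field {key}")

    table = pq.read_table(path)
    cols = {}
    for name in ("airflow_V", "dia_V", "abd_V"):
        if name not in table.column_names:
            raise ValueError(f"missing required field {name}")
        cols[name] = np.asarray(table.column(name))
    n_expected = meta.get("n_samples")
    for name, arr in cols.items():
        if n_expected is not None and arr.size != n_expected:
            raise ValueError(
                f"channel length mismatch: {name} has {arr.size} samples, "
                f"sidecar declares {n_expected}"
            )
    feo2 = meta["feo2"]
    if isinstance(feo2, list):
        feo2 = [list(seg) for seg in feo2]
    return Recording(
        fs=meta["fs"],
        airflow=cols["airflow_V"],
        dia_raw=cols["dia_V"],
        abd_raw=cols["abd_V"],
        t_inj1_end=meta["t_inj1_end"],
        t_inj2_end=meta["t_inj2_end"],
        fio2=meta["fio2"],
        feo2=feo2,
        calibration=tuple(tuple(p) for p in meta["calibration"]),
        body_mass_kg=meta["body_mass_kg"],
        seed=meta["seed"],
        preset=meta["preset"],
    )
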