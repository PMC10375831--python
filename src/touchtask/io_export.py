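"""Session serialization: canonical JSON plus CSV, HDF5 and NWB exports.

The canonical on-disk form is a human-readable JSON document (schema
below, versioned with semantic versioning; readers accept same-major
versions). CSV, HDF5 and NWB exports are derived views that re-import
to a record equal to the original — exactly for HDF5 and NWB, and up
to the single documented lossy field for CSV (nested device metadata
is dropped).

JSON schema (top level)::

    {
      "spec_version": "1.0.0",
      "session":  {session_id, animal_id, start_timestamp, duration_s,
                   complete, screen: {width_px, height_px, width_mm, height_mm}},
      "protocol": {name, params},
      "device":   {host, peripherals},
      "trials":   [one object per trial],
      "events":   [one object per raw touch event]
    }

The NWB export writes the NWB 2.x HDF5 layout directly: the trial log
becomes a ``/intervals/trials`` dynamic table with ``start_time``,
``stop_time``, ``outcome``, ``target_side`` and ``is_correction``
columns (plus the remaining trial fields), subject metadata lives under
``/general/subject``, and the raw touch stream under
``/acquisition/touch_events``. Outcomes and stimulus parameters are
table columns rather than acquisition time series, since no physiology
is recorded.
"""

from __future__ import annotations

import json
import math
import uuid
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .core import (
    SPEC_VERSION,
    ScreenGeometry,
    SessionRecord,
    TouchEvent,
    TrialOutcome,
    TrialRecord,
)


class SchemaError(ValueError):
    """A session document violating the schema; ``pointer`` names the field."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


class VersionError(ValueError):
    pass


_TRIAL_COLUMNS = [
    "index", "outcome", "target_side", "is_correction", "go",
    "iti_duration", "trial_start_t", "stimulus_onset_t",
    "response_t", "response_x", "response_y",
    "trial_end_t", "uncued_touch_count", "reward_volume_ul",
]


def _check_version(version: str, pointer: str = "spec_version") -> None:
    try:
        major = int(str(version).split(".")[0])
    except (ValueError, AttributeError):
        raise VersionError(f"unparseable spec_version {version!r}") from None
    ours = int(SPEC_VERSION.split(".")[0])
    if major != ours:
        raise VersionError(
            f"{pointer}: unsupported schema version {version!r} "
            f"(this reader accepts {ours}.x)"
        )


def session_to_dict(rec: SessionRecord) -> dict:
    """Render a record into the canonical JSON document structure."""
    return {
        "spec_version": rec.spec_version,
        "session": {
            "session_id": rec.session_id,
            "animal_id": rec.animal_id,
            "start_timestamp": rec.start_timestamp,
            "duration_s": rec.duration_s,
            "complete": rec.complete,
            "screen": rec.screen.model_dump(),
        },
        "protocol": {"name": rec.protocol_name, "params": rec.protocol_params},
        "device": rec.device_metadata,
        "trials": [t.model_dump(mode="json") for t in rec.trials],
        "events": [e.model_dump(mode="json") for e in rec.events],
    }


def dict_to_session(doc: dict) -> SessionRecord:
    """Parse and validate a canonical JSON document into a record."""
    if not isinstance(doc, dict):
        raise SchemaError("", "document must be a JSON object")
    for key in ("spec_version", "session", "protocol", "trials", "events"):
        if key not in doc:
            raise SchemaError(key, "required key missing")
    _check_version(doc["spec_version"])
    session = doc["session"]
    for key in ("session_id", "animal_id", "start_timestamp", "duration_s", "screen"):
        if key not in session:
            raise SchemaError(f"session/{key}", "required key missing")
    protocol = doc["protocol"]
    for key in ("name", "params"):
        if key not in protocol:
            raise SchemaError(f"protocol/{key}", "required key missing")
    try:
        return SessionRecord(
            session_id=session["session_id"],
            animal_id=session["animal_id"],
            protocol_name=protocol["name"],
            protocol_params=protocol["params"],
            screen=ScreenGeometry(**session["screen"]),
            start_timestamp=session["start_timestamp"],
            duration_s=session["duration_s"],
            trials=[TrialRecord(**t) for t in doc["trials"]],
            events=[TouchEvent(**e) for e in doc["events"]],
            device_metadata=doc.get("device", {}),
            spec_version=doc["spec_version"],
            complete=session.get("complete", True),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError("", f"invalid field content: {exc}") from exc


def write_json(rec: SessionRecord, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(session_to_dict(rec), indent=2) + "\n")
    return path


def read_json(path) -> SessionRecord:
    with open(path) as fh:
        doc = json.load(fh)
    return dict_to_session(doc)


# ---------------------------------------------------------------------------
# CSV

def _trials_frame(rec: SessionRecord) -> pd.DataFrame:
    rows = []
    for t in rec.trials:
        rows.append({
            "index": t.index,
            "outcome": t.outcome.value,
            "target_side": t.target_side,
            "is_correction": t.is_correction,
            "go": t.go,
            "iti_duration": t.iti_duration,
            "trial_start_t": t.trial_start_t,
            "stimulus_onset_t": t.stimulus_onset_t,
            "response_t": t.response_t,
            "response_x": None if t.response_xy is None else t.response_xy[0],
            "response_y": None if t.response_xy is None else t.response_xy[1],
            "trial_end_t": t.trial_end_t,
            "uncued_touch_count": t.uncued_touch_count,
            "reward_volume_ul": t.reward_volume_ul,
        })
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def export_csv(rec: SessionRecord, path) -> Path:
    """Write one row per trial, with events and flat session metadata in
    sibling files (``<stem>_events.csv``, ``<stem>_session.csv``).

    Dialect: UTF-8, comma, header row; nested values in the session
    sidecar are JSON-encoded per cell. Nested device metadata is the one
    lossy field of this format.
    """
    path = Path(path)
    # %.17g keeps doubles bit-exact through the text round trip
    _trials_frame(rec).to_csv(path, index=False, float_format="%.17g")
    events = pd.DataFrame(
        [{"x": e.x, "y": e.y, "t": e.t, "phase": e.phase} for e in rec.events],
        columns=["x", "y", "t", "phase"],
    )
    events.to_csv(path.with_name(path.stem + "_events.csv"), index=False,
                  float_format="%.17g")
    meta = {
        "spec_version": rec.spec_version,
        "session_id": rec.session_id,
        "animal_id": rec.animal_id,
        "protocol_name": rec.protocol_name,
        "start_timestamp": rec.start_timestamp,
        "duration_s": rec.duration_s,
        "complete": rec.complete,
        "screen": rec.screen.model_dump(),
        "protocol_params": rec.protocol_params,
    }
    side = pd.DataFrame(
        [{"key": k, "value_json": json.dumps(v)} for k, v in meta.items()]
    )
    side.to_csv(path.with_name(path.stem + "_session.csv"), index=False)
    return path


def _opt(v):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def read_csv_session(path) -> SessionRecord:
    """Re-import a CSV export (device metadata comes back empty)."""
    path = Path(path)
    trials_df = pd.read_csv(path, float_precision="round_trip")
    events_df = pd.read_csv(path.with_name(path.stem + "_events.csv"),
                            float_precision="round_trip")
    side = pd.read_csv(path.with_name(path.stem + "_session.csv"))
    meta = {row["key"]: json.loads(row["value_json"]) for _, row in side.iterrows()}
    _check_version(meta.get("spec_version", ""))
    trials = []
    for _, r in trials_df.iterrows():
        rx, ry = _opt(r["response_x"]), _opt(r["response_y"])
        go = _opt(r["go"])
        trials.append(TrialRecord(
            index=int(r["index"]),
            outcome=TrialOutcome(r["outcome"]),
            target_side=r["target_side"],
            is_correction=bool(r["is_correction"]),
            go=None if go is None else bool(go),
            iti_duration=float(r["iti_duration"]),
            trial_start_t=float(r["trial_start_t"]),
            stimulus_onset_t=_opt(r["stimulus_onset_t"]),
            response_t=_opt(r["response_t"]),
            response_xy=None if rx is None else (float(rx), float(ry)),
            trial_end_t=float(r["trial_end_t"]),
            uncued_touch_count=int(r["uncued_touch_count"]),
            reward_volume_ul=float(r["reward_volume_ul"]),
        ))
    events = [
        TouchEvent(x=float(r["x"]), y=float(r["y"]), t=float(r["t"]), phase=r["phase"])
        for _, r in events_df.iterrows()
    ]
    return SessionRecord(
        session_id=meta["session_id"], animal_id=meta["animal_id"],
        protocol_name=meta["protocol_name"],
        protocol_params=meta["protocol_params"],
        screen=ScreenGeometry(**meta["screen"]),
        start_timestamp=meta["start_timestamp"],
        duration_s=meta["duration_s"], trials=trials, events=events,
        device_metadata={}, spec_version=meta["spec_version"],
        complete=meta["complete"],
    )


# ---------------------------------------------------------------------------
# HDF5

_STR = h5py.string_dtype(encoding="utf-8")


def _trial_arrays(rec: SessionRecord) -> dict[str, np.ndarray]:
    df = _trials_frame(rec)
    out: dict[str, np.ndarray] = {}
    out["index"] = df["index"].to_numpy(dtype=np.int64)
    out["outcome"] = df["outcome"].to_numpy(dtype=object)
    out["target_side"] = df["target_side"].to_numpy(dtype=object)
    out["is_correction"] = df["is_correction"].to_numpy(dtype=np.int8)
    out["go"] = np.array(
        [-1 if g is None else int(g) for g in df["go"]], dtype=np.int8
    )
    for col in ("iti_duration", "trial_start_t", "stimulus_onset_t",
                "response_t", "response_x", "response_y", "trial_end_t",
                "reward_volume_ul"):
        out[col] = df[col].to_numpy(dtype=np.float64, na_value=np.nan)
    out["uncued_touch_count"] = df["uncued_touch_count"].to_numpy(dtype=np.int64)
    return out


def _trials_from_arrays(cols: dict[str, np.ndarray]) -> list[TrialRecord]:
    n = len(cols["index"])
    trials = []
    for i in range(n):
        def f(name):
            v = float(cols[name][i])
            return None if math.isnan(v) else v

        rx, ry = f("response_x"), f("response_y")
        go = int(cols["go"][i])
        trials.append(TrialRecord(
            index=int(cols["index"][i]),
            outcome=TrialOutcome(_as_str(cols["outcome"][i])),
            target_side=_as_str(cols["target_side"][i]),
            is_correction=bool(cols["is_correction"][i]),
            go=None if go < 0 else bool(go),
            iti_duration=float(cols["iti_duration"][i]),
            trial_start_t=float(cols["trial_start_t"][i]),
            stimulus_onset_t=f("stimulus_onset_t"),
            response_t=f("response_t"),
            response_xy=None if rx is None else (rx, ry),
            trial_end_t=float(cols["trial_end_t"][i]),
            uncued_touch_count=int(cols["uncued_touch_count"][i]),
            reward_volume_ul=float(cols["reward_volume_ul"][i]),
        ))
    return trials


def _as_str(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def export_hdf5(rec: SessionRecord, path) -> Path:
    """Write groups /session (attrs), /trials (columnar), /events."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["spec_version"] = rec.spec_version
        g = f.create_group("session")
        g.attrs["session_id"] = rec.session_id
        g.attrs["animal_id"] = rec.animal_id
        g.attrs["protocol_name"] = rec.protocol_name
        g.attrs["start_timestamp"] = rec.start_timestamp
        g.attrs["duration_s"] = rec.duration_s
        g.attrs["complete"] = bool(rec.complete)
        g.attrs["screen_json"] = json.dumps(rec.screen.model_dump())
        g.attrs["protocol_params_json"] = json.dumps(rec.protocol_params)
        g.attrs["device_metadata_json"] = json.dumps(rec.device_metadata)
        tg = f.create_group("trials")
        for name, arr in _trial_arrays(rec).items():
            tg.create_dataset(name, data=arr,
                              dtype=_STR if arr.dtype == object else arr.dtype)
        eg = f.create_group("events")
        eg.create_dataset("x", data=np.array([e.x for e in rec.events], dtype=np.float64))
        eg.create_dataset("y", data=np.array([e.y for e in rec.events], dtype=np.float64))
        eg.create_dataset("t", data=np.array([e.t for e in rec.events], dtype=np.float64))
        eg.create_dataset("phase", data=np.array([e.phase for e in rec.events], dtype=object),
                          dtype=_STR)
    return path


def read_hdf5_session(path) -> SessionRecord:
    with h5py.File(path, "r") as f:
        _check_version(_as_str(f.attrs["spec_version"]))
        g = f["session"]
        cols = {name: f["trials"][name][()] for name in f["trials"]}
        trials = _trials_from_arrays(cols) if len(cols["index"]) else []
        ev = f["events"]
        events = [
            TouchEvent(x=float(x), y=float(y), t=float(t), phase=_as_str(p))
            for x, y, t, p in zip(ev["x"][()], ev["y"][()], ev["t"][()], ev["phase"][()])
        ]
        return SessionRecord(
            session_id=_as_str(g.attrs["session_id"]),
            animal_id=_as_str(g.attrs["animal_id"]),
            protocol_name=_as_str(g.attrs["protocol_name"]),
            protocol_params=json.loads(_as_str(g.attrs["protocol_params_json"])),
            screen=ScreenGeometry(**json.loads(_as_str(g.attrs["screen_json"]))),
            start_timestamp=_as_str(g.attrs["start_timestamp"]),
            duration_s=float(g.attrs["duration_s"]),
            trials=trials,
            events=events,
            device_metadata=json.loads(_as_str(g.attrs["device_metadata_json"])),
            spec_version=_as_str(f.attrs["spec_version"]),
            complete=bool(g.attrs["complete"]),
        )


# ---------------------------------------------------------------------------
# NWB (written directly in the NWB 2.x HDF5 layout)

NWB_VERSION = "2.6.0"


def _object_id(*parts: str) -> str:
    return str(uuid.uuid5(uuid.NAMESPACE_URL, "touchtask:" + ":".join(parts)))


def export_nwb(rec: SessionRecord, path) -> Path:
    """Write an NWB-layout HDF5 file for the session.

    Requires complete metadata (animal_id and start_timestamp); trials
    become the ``/intervals/trials`` table with start/stop times,
    outcome, target side and correction flag alongside the remaining
    trial fields, and the raw touch stream is stored under
    ``/acquisition/touch_events``.
    """
    if not rec.animal_id:
        raise ValueError("NWB export requires a non-empty animal_id")
    if not rec.start_timestamp:
        raise ValueError("NWB export requires a start_timestamp")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["namespace"] = "core"
        f.attrs["neurodata_type"] = "NWBFile"
        f.attrs["nwb_version"] = NWB_VERSION
        f.attrs["object_id"] = _object_id(rec.session_id)
        f.create_dataset("identifier", data=rec.session_id, dtype=_STR)
        f.create_dataset(
            "session_description",
            data=f"touchscreen operant session ({rec.protocol_name})", dtype=_STR,
        )
        f.create_dataset("session_start_time", data=rec.start_timestamp, dtype=_STR)
        f.create_dataset("timestamps_reference_time", data=rec.start_timestamp, dtype=_STR)
        f.create_dataset("file_create_date", data=[rec.start_timestamp], dtype=_STR)

        gen = f.create_group("general")
        gen.create_dataset("session_id", data=rec.session_id, dtype=_STR)
        subj = gen.create_group("subject")
        subj.attrs["namespace"] = "core"
        subj.attrs["neurodata_type"] = "Subject"
        subj.attrs["object_id"] = _object_id(rec.session_id, "subject")
        subj.create_dataset("subject_id", data=rec.animal_id, dtype=_STR)
        subj.create_dataset("species", data="Mus musculus", dtype=_STR)
        gen.create_dataset("protocol", data=rec.protocol_name, dtype=_STR)
        gen.create_dataset("protocol_parameters_json",
                           data=json.dumps(rec.protocol_params), dtype=_STR)
        gen.create_dataset("devices_json",
                           data=json.dumps(rec.device_metadata), dtype=_STR)
        gen.create_dataset("screen_json",
                           data=json.dumps(rec.screen.model_dump()), dtype=_STR)
        gen.create_dataset("source_spec_version", data=rec.spec_version, dtype=_STR)
        gen.create_dataset("session_duration_s", data=float(rec.duration_s))
        gen.create_dataset("session_complete", data=np.int8(rec.complete))

        iv = f.create_group("intervals")
        tr = iv.create_group("trials")
        tr.attrs["namespace"] = "core"
        tr.attrs["neurodata_type"] = "TimeIntervals"
        tr.attrs["object_id"] = _object_id(rec.session_id, "trials")
        tr.attrs["description"] = "behavioural trials"
        arrays = _trial_arrays(rec)
        colmap = {
            "start_time": arrays["trial_start_t"],
            "stop_time": arrays["trial_end_t"],
            "outcome": arrays["outcome"],
            "target_side": arrays["target_side"],
            "is_correction": arrays["is_correction"],
            "go": arrays["go"],
            "iti_duration": arrays["iti_duration"],
            "stimulus_onset_time": arrays["stimulus_onset_t"],
            "response_time": arrays["response_t"],
            "response_x": arrays["response_x"],
            "response_y": arrays["response_y"],
            "uncued_touch_count": arrays["uncued_touch_count"],
            "reward_volume_ul": arrays["reward_volume_ul"],
        }
        tr.attrs["colnames"] = list(colmap)
        tr.create_dataset("id", data=arrays["index"])
        for name, arr in colmap.items():
            ds = tr.create_dataset(
                name, data=arr, dtype=_STR if arr.dtype == object else arr.dtype
            )
            ds.attrs["description"] = name

        acq = f.create_group("acquisition")
        te = acq.create_group("touch_events")
        te.attrs["description"] = "raw touchscreen contact stream"
        te.create_dataset("x", data=np.array([e.x for e in rec.events], dtype=np.float64))
        te.create_dataset("y", data=np.array([e.y for e in rec.events], dtype=np.float64))
        te.create_dataset("timestamps",
                          data=np.array([e.t for e in rec.events], dtype=np.float64))
        te.create_dataset("phase",
                          data=np.array([e.phase for e in rec.events], dtype=object),
                          dtype=_STR)
    return path


def read_nwb_session(path) -> SessionRecord:
    with h5py.File(path, "r") as f:
        gen = f["general"]
        tr = f["intervals/trials"]
        cols = {
            "index": tr["id"][()],
            "outcome": tr["outcome"][()],
            "target_side": tr["target_side"][()],
            "is_correction": tr["is_correction"][()],
            "go": tr["go"][()],
            "iti_duration": tr["iti_duration"][()],
            "trial_start_t": tr["start_time"][()],
            "stimulus_onset_t": tr["stimulus_onset_time"][()],
            "response_t": tr["response_time"][()],
            "response_x": tr["response_x"][()],
            "response_y": tr["response_y"][()],
            "trial_end_t": tr["stop_time"][()],
            "uncued_touch_count": tr["uncued_touch_count"][()],
            "reward_volume_ul": tr["reward_volume_ul"][()],
        }
        trials = _trials_from_arrays(cols) if len(cols["index"]) else []
        te = f["acquisition/touch_events"]
        events = [
            TouchEvent(x=float(x), y=float(y), t=float(t), phase=_as_str(p))
            for x, y, t, p in zip(te["x"][()], te["y"][()],
                                  te["timestamps"][()], te["phase"][()])
        ]
        version = _as_str(gen["source_spec_version"][()])
        _check_version(version)
        return SessionRecord(
            session_id=_as_str(f["identifier"][()]),
            animal_id=_as_str(f["general/subject/subject_id"][()]),
            protocol_name=_as_str(gen["protocol"][()]),
            protocol_params=json.loads(_as_str(gen["protocol_parameters_json"][()])),
            screen=ScreenGeometry(**json.loads(_as_str(gen["screen_json"][()]))),
            start_timestamp=_as_str(f["session_start_time"][()]),
            duration_s=float(gen["session_duration_s"][()]),
            trials=trials,
            events=events,
            device_metadata=json.loads(_as_str(gen["devices_json"][()])),
            spec_version=version,
            complete=bool(int(gen["session_complete"][()])),
        )


# ---------------------------------------------------------------------------

_EXPORTERS = {"csv": export_csv, "hdf5": export_hdf5, "nwb": export_nwb}
_READERS = {"csv": read_csv_session, "hdf5": read_hdf5_session,
            "nwb": read_nwb_session, "json": read_json}


def export(rec: SessionRecord, fmt: str, path) -> Path:
    """Export a session to one of csv / hdf5 / nwb."""
    try:
        writer = _EXPORTERS[fmt]
    except KeyError:
        raise ValueError(
            f"unknown export format {fmt!r}; available: {sorted(_EXPORTERS)}"
        ) from None
    return writer(rec, path)


def read_session(path, fmt: Optional[str] = None) -> SessionRecord:
    """Read a session back from any supported format (inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"json": "json", "csv": "csv", "h5": "hdf5",
               "hdf5": "hdf5", "nwb": "nwb"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    return _READERS[fmt](path)
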