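"""File formats: SNIRF-style HDF5 recordings, YAML configs, provenance.

Recordings are stored in an HDF5 layout modelled on SNIRF (per-subject
``nirs`` groups holding a ``dataTimeSeries`` block plus a measurement
list), restricted to what the pipeline consumes: two wavelengths per
channel, a long/short separation class, and task annotations as stim
groups.  Reading validates the recording invariants (positive intensity,
both wavelengths, ordered annotations) and raises descriptive errors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from dyadsync.types import (
    ChannelInfo,
    DyadRecording,
    SubjectRecording,
    TaskAnnotation,
)

FORMAT_TAG = "dyadsync-snirf-style-1"


def write_recording(rec: DyadRecording, path: str | Path) -> Path:
    """Write a dyadic recording to a SNIRF-style HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_TAG
        f.attrs["dyad_id"] = rec.dyad_id
        f.attrs["fs"] = rec.fs
        for name, sub in rec.subjects.items():
            g = f.create_group(f"nirs_{name}")
            g.create_dataset("dataTimeSeries", data=sub.intensity)
            g.create_dataset("wavelengths", data=np.asarray(sub.wavelengths))
            g.create_dataset("source", data=[c.source for c in sub.channels])
            g.create_dataset("detector", data=[c.detector for c in sub.channels])
            g.create_dataset(
                "separation",
                data=[c.separation.encode() for c in sub.channels],
            )
            g.create_dataset(
                "region", data=[c.region.encode() for c in sub.channels]
            )
        stim = f.create_group("stim")
        stim.create_dataset(
            "task", data=[a.task.encode() for a in rec.annotations]
        )
        stim.create_dataset("start", data=[a.start for a in rec.annotations])
        stim.create_dataset("end", data=[a.end for a in rec.annotations])
    return path


def read_recording(path: str | Path) -> DyadRecording:
    """Read a recording written by :func:`write_recording`, validating it."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FORMAT_TAG:
            raise ValueError(f"{path}: not a {FORMAT_TAG} file")
        subjects = {}
        for name in ("child", "mother"):
            key = f"nirs_{name}"
            if key not in f:
                raise ValueError(f"{path}: missing subject group {key!r}")
            g = f[key]
            intensity = np.asarray(g["dataTimeSeries"])
            wavelengths = tuple(float(w) for w in np.asarray(g["wavelengths"]))
            if intensity.ndim != 3 or intensity.shape[1] != 2 or len(wavelengths) != 2:
                bad = intensity.shape[1] if intensity.ndim == 3 else "?"
                raise ValueError(
                    f"{path}: subject {name!r} must carry exactly 2 wavelengths "
                    f"per channel (found {bad})"
                )
            channels = [
                ChannelInfo(
                    subject=name,
                    source=int(s),
                    detector=int(d),
                    separation=sep.decode(),
                    region=reg.decode(),
                )
                for s, d, sep, reg in zip(
                    g["source"], g["detector"], g["separation"], g["region"]
                )
            ]
            subjects[name] = SubjectRecording(
                intensity=intensity, channels=channels, wavelengths=wavelengths
            )
        annotations = [
            TaskAnnotation(task.decode(), float(s), float(e))
            for task, s, e in zip(f["stim/task"], f["stim/start"], f["stim/end"])
        ]
        rec = DyadRecording(
            dyad_id=str(f.attrs["dyad_id"]),
            fs=float(f.attrs["fs"]),
            subjects=subjects,
            annotations=annotations,
        )
    rec.validate_intensity()
    return rec


# ---------------------------------------------------------------------------
# configs and provenance
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(cfg, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_provenance(out_dir: str | Path, cfg: dict, seed: int | None) -> Path:
    from dyadsync import __version__

    out = Path(out_dir) / "provenance.json"
    out.write_text(
        json.dumps(
            {
                "software": "dyadsync",
                "version": __version__,
                "config_hash": config_hash(cfg),
                "seed": seed,
            },
            indent=2,
        )
    )
    return out
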