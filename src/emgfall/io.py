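"""Disk formats: delimited-text recordings with JSON sidecars, manifests,
and HDF5 feature containers.

A recording ``NAME.tsv`` holds one column per channel with a muscle-name
header row; ``NAME.json`` carries {subject_id, gesture, fs_hz,
burst_intervals}. A dataset directory has one such pair per recording plus
a ``manifest.json`` index.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .types import EmgRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_features_h5",
]

_FLOAT_FMT = "%.6e"


def write_recording(rec: EmgRecording, path: str | Path) -> Path:
    """Write ``path``.tsv (+.json sidecar); returns the .tsv path."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    header = "\t".join(rec.channel_names)
    np.savetxt(path, rec.samples, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")
    sidecar = {
        "subject_id": rec.subject_id,
        "gesture": rec.gesture,
        "fs_hz": rec.fs_hz,
        "burst_intervals": [list(b) for b in rec.bursts],
        "rec_id": rec.rec_id or path.stem,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path, *, expect_channels: int | None = None) -> EmgRecording:
    """Read a .tsv/.json pair back into an :class:`EmgRecording`."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar: expected {sidecar_path}")
    with open(path) as fh:
        names = tuple(fh.readline().rstrip("\n").split("\t"))
    samples = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if samples.shape[1] != len(names):
        raise ValueError(
            f"{path}: header line 1 names {len(names)} channels but rows have {samples.shape[1]}"
        )
    if expect_channels is not None and samples.shape[1] != expect_channels:
        raise ValueError(
            f"{path}: expected {expect_channels} channels, file has {samples.shape[1]} (header line 1)"
        )
    meta = json.loads(sidecar_path.read_text())
    return EmgRecording(
        samples=samples,
        fs_hz=float(meta["fs_hz"]),
        subject_id=int(meta["subject_id"]),
        gesture=meta.get("gesture"),
        channel_names=names,
        bursts=[tuple(b) for b in meta.get("burst_intervals", [])],
        rec_id=meta.get("rec_id", path.stem),
    )


def write_dataset(recordings: list[EmgRecording], out_dir: str | Path) -> Path:
    """Write every recording plus a manifest.json index; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        p = write_recording(rec, out / f"{rec.rec_id}.tsv")
        entries.append(
            {
                "file": p.name,
                "rec_id": rec.rec_id,
                "subject_id": rec.subject_id,
                "gesture": rec.gesture,
                "n_samples": rec.n_samples,
            }
        )
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"recordings": entries}, indent=1))
    return manifest


def read_dataset(dir_path: str | Path) -> list[EmgRecording]:
    """Load every recording listed in a dataset directory's manifest."""
    dir_path = Path(dir_path)
    manifest = dir_path / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"missing dataset manifest: {manifest}")
    entries = json.loads(manifest.read_text())["recordings"]
    return [read_recording(dir_path / e["file"]) for e in entries]


def write_features_h5(path: str | Path, bundles: list[dict], *, attrs: dict | None = None) -> Path:
    """Store per-segment feature bundles (spm + td tensors) in one HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for i, item in enumerate(bundles):
            g = f.create_group(f"segment_{i:05d}")
            g.create_dataset("spm", data=item["spm"])
            g.create_dataset("td", data=item["td"])
            g.attrs["rec_id"] = item.get("rec_id", "")
            g.attrs["label"] = item.get("label", -1)
            seg = item["segment"]
            g.attrs["start_sample"] = seg.start_sample
            g.attrs["end_sample"] = seg.end_sample
    return path
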