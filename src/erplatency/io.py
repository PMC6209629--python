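"""Readers and writers for group containers, results, and run manifests.

Three group-average dialects are supported:

* **hdf5** — one 3-D dataset ``data`` shaped [subject, channel, time] with
  attribute arrays ``subject_ids``, ``channel_names``, ``times``;
* **per-subject delimited** — a directory of tab-separated channels × time
  matrices (one file per subject) plus a JSON sidecar ``metadata.json``;
* **toolbox-struct** — MATLAB ``.mat`` files as produced by the common
  analysis toolboxes: a struct with the group matrix in the field ``data``
  or ``individual`` (configurable via ``datafield``), or a cell array of
  per-subject structs with the matrix in ``avg``.

Results go out as tidy tab-separated text (columns ``unit_id``, ``measure``,
``value``, ``found``, ``aggregate``) with a JSON run manifest alongside.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .model import ConfigError, GroupAverages, ResultsTable

__all__ = [
    "RunManifest",
    "load_group",
    "save_group",
    "save_results",
    "load_results",
]

_DIALECTS = ("hdf5", "delimited", "toolbox")


@dataclass
class RunManifest:
    """Provenance record written alongside every result file."""

    inputs: list[str] = field(default_factory=list)
    dialect: Optional[str] = None
    effective_config: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        record = dataclasses.asdict(self)
        if not record["timestamp"]:
            record["timestamp"] = datetime.datetime.now(
                datetime.timezone.utc
            ).isoformat()
        path.write_text(json.dumps(record, indent=2, default=str) + "\n")
        return path


def _detect_dialect(path: Path) -> str:
    if path.is_dir():
        return "delimited"
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".mat":
        return "toolbox"
    raise ConfigError(
        f"cannot infer dialect of {path}; supported: {', '.join(_DIALECTS)} "
        f"(HDF5 file, directory of per-subject TSVs, MATLAB struct)"
    )


def _load_hdf5(path: Path) -> GroupAverages:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ConfigError(f"{path} has no dataset 'data'")
        data = np.asarray(f["data"])
        attrs = f["data"].attrs
        subject_ids = attrs.get("subject_ids")
        channel_names = attrs.get("channel_names")
        times = attrs.get("times")
    return GroupAverages(
        data=data,
        subject_ids=None if subject_ids is None else [int(s) for s in subject_ids],
        channel_names=None
        if channel_names is None
        else [c.decode() if isinstance(c, bytes) else str(c) for c in channel_names],
        time_axis=None if times is None else np.asarray(times, dtype=float),
    )


def _save_hdf5(group: GroupAverages, path: Path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=group.data)
        if group.subject_ids is not None:
            dset.attrs["subject_ids"] = np.asarray(group.subject_ids, dtype=int)
        if group.channel_names is not None:
            dset.attrs["channel_names"] = [str(c) for c in group.channel_names]
        if group.time_axis is not None:
            dset.attrs["times"] = np.asarray(group.time_axis, dtype=float)


def _load_delimited(path: Path) -> GroupAverages:
    meta_path = path / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    files = meta.get("files")
    if files is None:
        files = sorted(p.name for p in path.glob("*.tsv"))
    if not files:
        raise ConfigError(f"no per-subject .tsv files found in {path}")
    mats = []
    for name in files:
        mat = pd.read_csv(path / name, sep="\t", index_col=0).to_numpy(dtype=float)
        if mats and mat.shape != mats[0].shape:
            raise ConfigError(
                f"{name} has shape {mat.shape} (channels × time), expected "
                f"{mats[0].shape} like the first subject file"
            )
        mats.append(mat)
    return GroupAverages(
        data=np.stack(mats),
        subject_ids=meta.get("subject_ids"),
        channel_names=meta.get("channel_names"),
        time_axis=meta.get("times"),
    )


def _save_delimited(group: GroupAverages, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    labels = group.subject_ids or list(range(1, group.n_subjects + 1))
    chans = group.channel_names or [
        f"ch{i + 1}" for i in range(group.n_channels)
    ]
    files = []
    for i, lbl in enumerate(labels):
        name = f"subject_{lbl:02d}.tsv" if isinstance(lbl, int) else f"subject_{lbl}.tsv"
        frame = pd.DataFrame(group.data[i], index=chans)  # channels × time
        frame.to_csv(path / name, sep="\t", index_label="channel")
        files.append(name)
    meta = {
        "files": files,
        "subject_ids": group.subject_ids,
        "channel_names": group.channel_names,
        "times": None
        if group.time_axis is None
        else np.asarray(group.time_axis).tolist(),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def _squeeze_field(struct, name: str):
    try:
        return getattr(struct, name)
    except AttributeError:
        return None


def _load_toolbox(path: Path, datafield: Optional[str]) -> GroupAverages:
    raw = loadmat(path, squeeze_me=True, struct_as_record=False)
    candidates = {k: v for k, v in raw.items() if not k.startswith("__")}
    if not candidates:
        raise ConfigError(f"{path} contains no variables")
    var = next(iter(candidates.values()))

    # cell array of per-subject structs with an 'avg' field
    if isinstance(var, np.ndarray) and var.dtype == object:
        mats = []
        for entry in np.ravel(var):
            avg = _squeeze_field(entry, datafield or "avg")
            if avg is None:
                raise ConfigError(
                    f"per-subject struct lacks field {datafield or 'avg'!r}"
                )
            mats.append(np.atleast_2d(np.asarray(avg, dtype=float)))
        if len({m.shape for m in mats}) > 1:
            raise ConfigError("per-subject averages differ in shape")
        return GroupAverages(data=np.stack(mats))

    # single struct with a 3-D group matrix
    fields = [datafield] if datafield else ["data", "individual", "avg"]
    data = None
    for name in fields:
        if name is None:
            continue
        data = _squeeze_field(var, name)
        if data is not None:
            break
    if data is None:
        raise ConfigError(
            f"{path}: none of the fields {fields!r} found in the struct; "
            f"set datafield to the correct name"
        )
    times = _squeeze_field(var, "times")
    sub_num = _squeeze_field(var, "subNum")
    chan_names = _squeeze_field(var, "chanNames")
    if chan_names is None:
        chan_names = _squeeze_field(var, "chanName")
    return GroupAverages(
        data=np.asarray(data, dtype=float),
        subject_ids=None if sub_num is None else np.atleast_1d(sub_num).tolist(),
        channel_names=None
        if chan_names is None
        else [str(c) for c in np.atleast_1d(chan_names)],
        time_axis=None if times is None else np.asarray(times, dtype=float),
    )


def _save_toolbox(group: GroupAverages, path: Path) -> None:
    struct: dict = {"data": group.data}
    if group.subject_ids is not None:
        struct["subNum"] = np.asarray(group.subject_ids)
    if group.channel_names is not None:
        struct["chanNames"] = np.asarray(group.channel_names, dtype=object)
    if group.time_axis is not None:
        struct["times"] = np.asarray(group.time_axis)
    savemat(path, {"avgs": struct})


def load_group(
    path: str | Path, dialect: str = "auto", datafield: Optional[str] = None
) -> GroupAverages:
    """Load a group container; dimension order is subject × channel × time.

    ``dialect`` is ``'auto'`` (from the path), ``'hdf5'``, ``'delimited'``
    (directory of per-subject TSVs) or ``'toolbox'`` (MATLAB struct;
    ``datafield`` overrides the group-matrix field name).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect == "hdf5":
        return _load_hdf5(path)
    if dialect == "delimited":
        return _load_delimited(path)
    if dialect == "toolbox":
        return _load_toolbox(path, datafield)
    raise ConfigError(
        f"unknown dialect {dialect!r}; supported: {', '.join(_DIALECTS)}"
    )


def save_group(group: GroupAverages, path: str | Path, dialect: str = "auto") -> Path:
    """Write a group container in any supported dialect (for fixtures/tests)."""
    path = Path(path)
    if dialect == "auto":
        dialect = _detect_dialect(path) if (path.suffix or path.is_dir()) else "hdf5"
    if dialect == "hdf5":
        _save_hdf5(group, path)
    elif dialect == "delimited":
        _save_delimited(group, path)
    elif dialect == "toolbox":
        _save_toolbox(group, path)
    else:
        raise ConfigError(
            f"unknown dialect {dialect!r}; supported: {', '.join(_DIALECTS)}"
        )
    return path


def save_results(
    results: ResultsTable,
    path: str | Path,
    manifest: Optional[RunManifest] = None,
) -> tuple[Path, Path]:
    """Write the tidy results table (TSV) and its manifest JSON.

    Returns ``(results path, manifest path)``; the manifest lands next to
    the table as ``<stem>.manifest.json``.
    """
    path = Path(path)
    if results.table.empty:
        raise ValueError("refusing to write an empty results table")
    path.parent.mkdir(parents=True, exist_ok=True)
    results.table.to_csv(path, sep="\t", index=False)
    manifest = manifest or RunManifest()
    manifest.effective_config = manifest.effective_config or results.annotation
    manifest.outputs = sorted(set(manifest.outputs + [str(path)]))
    manifest_path = manifest.write(path.with_suffix(".manifest.json"))
    return path, manifest_path


def load_results(path: str | Path) -> ResultsTable:
    """Round-trip reader for :func:`save_results` output."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"unit_id": str})
    manifest_path = path.with_suffix(".manifest.json")
    annotation = {}
    if manifest_path.exists():
        annotation = json.loads(manifest_path.read_text()).get("effective_config", {})
    return ResultsTable(table=table, annotation=annotation)
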