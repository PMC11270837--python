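"""Readers and writers for PLUMED-style text formats and run manifests.

COLVAR files are whitespace-delimited with a ``#! FIELDS name1 name2 ...``
header; HILLS files use ``#! FIELDS time center sigma height biasfactor``.
Transition tables are TSV with columns ``time`` and ``transitioned`` (0/1).
A run manifest (YAML) ties an ensemble directory together: per-trajectory
COLVAR filenames, the transition table, the inverse temperature and the
seed/settings the ensemble was produced with.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import BiasTrace, Ensemble, NoDataError, TransitionRecord

__all__ = [
    "ColvarFormatError",
    "read_colvar",
    "write_colvar",
    "read_transition_table",
    "write_transition_table",
    "read_hills",
    "write_hills",
    "RunManifest",
    "read_manifest",
    "write_manifest",
    "load_ensemble",
    "save_ensemble",
]

_HEADER = "#! FIELDS"


class ColvarFormatError(ValueError):
    """Malformed COLVAR/HILLS file; message carries the offending line."""


def _read_table(path: str, required: tuple[str, ...]) -> dict[str, np.ndarray]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_HEADER):
            raise ColvarFormatError(f"{path}:1: missing '#! FIELDS' header")
        names = first[len(_HEADER):].split()
        for col in required:
            if col not in names:
                raise ColvarFormatError(f"{path}:1: required column {col!r} missing")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(names):
                raise ColvarFormatError(
                    f"{path}:{lineno}: expected {len(names)} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ColvarFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise NoDataError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    return {name: data[:, j] for j, name in enumerate(names)}


def read_colvar(
    path: str,
    beta: float = 1.0,
    time_field: str = "time",
    bias_field: str = "bias",
    strict: bool = True,
) -> BiasTrace:
    """Parse a COLVAR-style file into a BiasTrace (extra columns ignored)."""
    cols = _read_table(path, (time_field, bias_field))
    t = cols[time_field]
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3  # header + 1-based + offset
        raise ColvarFormatError(f"{path}:{bad}: time column is not strictly increasing")
    return BiasTrace(t, cols[bias_field], beta=beta, strict=strict)


def write_colvar(path: str, trace: BiasTrace, position: np.ndarray | None = None) -> None:
    fields = ["time", "bias"] if position is None else ["time", "position", "bias"]
    with open(path, "w") as fh:
        fh.write(f"{_HEADER} {' '.join(fields)}\n")
        for i in range(trace.times.size):
            row = [trace.times[i]]
            if position is not None:
                row.append(position[i])
            row.append(trace.values[i])
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_transition_table(path: str) -> list[TransitionRecord]:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError as exc:
        raise NoDataError(f"{path}: empty transition table") from exc
    for col in ("time", "transitioned"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise NoDataError(f"{path}: no rows")
    return [
        TransitionRecord(time=float(t), transitioned=bool(int(c)))
        for t, c in zip(df["time"], df["transitioned"])
    ]


def write_transition_table(path: str, records: list[TransitionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("time\ttransitioned\n")
        for r in records:
            fh.write(f"{r.time:.17g}\t{int(r.transitioned)}\n")


def read_hills(path: str):
    cols = _read_table(path, ("time", "center", "sigma", "height"))
    return cols


def write_hills(path: str, times, centers, sigmas, heights, biasfactor: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_HEADER} time center sigma height biasfactor\n")
        for t, c, s, h in zip(times, centers, np.broadcast_to(sigmas, np.shape(times)), heights):
            fh.write(f"{t:.17g} {c:.17g} {s:.17g} {h:.17g} {biasfactor:.17g}\n")


@dataclass
class RunManifest:
    """Layout of one ensemble directory (paths relative to the manifest)."""

    transition_table: str
    colvar_files: list[str]
    beta: float = 1.0
    seed: int = 0
    label: str = ""
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def write_manifest(path: str, manifest: RunManifest) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "transition_table": manifest.transition_table,
                "colvar_files": list(manifest.colvar_files),
                "beta": float(manifest.beta),
                "seed": int(manifest.seed),
                "label": manifest.label,
                "settings": manifest.settings,
            },
            fh,
            sort_keys=False,
        )


def read_manifest(path: str) -> RunManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    return RunManifest(
        transition_table=raw["transition_table"],
        colvar_files=list(raw["colvar_files"]),
        beta=float(raw.get("beta", 1.0)),
        seed=int(raw.get("seed", 0)),
        label=str(raw.get("label", "")),
        settings=dict(raw.get("settings", {})),
    )


def load_ensemble(manifest_path: str) -> Ensemble:
    """Read an ensemble directory; every listed file must exist and parse."""
    man = read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    records = read_transition_table(os.path.join(base, man.transition_table))
    if len(man.colvar_files) != len(records):
        raise ValueError(
            f"{manifest_path}: {len(man.colvar_files)} colvar files for "
            f"{len(records)} records"
        )
    # file inputs are general (e.g. flooding biases nonzero at t=0)
    traces = [
        read_colvar(os.path.join(base, f), beta=man.beta, strict=False)
        for f in man.colvar_files
    ]
    return Ensemble(records, traces, label=man.label)


def save_ensemble(directory: str, ensemble: Ensemble, seed: int = 0,
                  settings: dict | None = None) -> str:
    """Write an ensemble as COLVAR files + transition table + manifest;
    returns the manifest path."""
    os.makedirs(directory, exist_ok=True)
    colvar_files = []
    for i, trace in enumerate(ensemble.traces):
        name = f"colvar_{i:04d}.dat"
        write_colvar(os.path.join(directory, name), trace)
        colvar_files.append(name)
    write_transition_table(os.path.join(directory, "transitions.tsv"), ensemble.records)
    man = RunManifest(
        transition_table="transitions.tsv",
        colvar_files=colvar_files,
        beta=ensemble.beta,
        seed=seed,
        label=ensemble.label,
        settings=settings or {},
    )
    path = os.path.join(directory, "manifest.yaml")
    write_manifest(path, man)
    return path
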