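"""File readers and writers for the pipeline's text formats.

Units are declared in file headers and validated on read: times in ns for
trajectory-derived traces, min or s for assay time series, distances and
coordinates in Å, energies in kcal mol^-1. Silent unit conversion between
the assay (min^-1) and transition-state-theory (s^-1) layers is a real
failure mode, so every schema is explicit.

Formats
-------
* distance trace: CSV with header ``time_ns,distance_A``
* umbrella window: text file with ``# key: value`` header lines
  (center, force_constant, temperature, bias_convention) followed by one
  sampled R value (Å) per line
* free-energy profile: TSV with columns bin_center, g, stderr, count
* multi-model PDB: fixed-column ATOM/MODEL/ENDMDL records (via biotite)
* cycle model: JSON or YAML with states/reactions keys
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cycle import CycleModel
from .errors import InvalidInputError
from .ionpair import DistanceTrace, LabelledFrame
from .umbrella import FreeEnergyProfile, UmbrellaWindow

__all__ = [
    "read_distance_trace",
    "write_distance_trace",
    "read_umbrella_window",
    "write_umbrella_window",
    "write_profile",
    "read_profile",
    "read_pdb_models",
    "read_cycle_model",
    "write_cycle_model",
]


def read_distance_trace(path) -> DistanceTrace:
    """Read a (time_ns, distance_A) CSV; extra columns warn and are ignored."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: empty file") from exc
    required = {"time_ns", "distance_A"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - required
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {sorted(extra)}", stacklevel=2)
    for col in required:
        bad = df[df[col].isna() | ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise InvalidInputError(
                f"{path}: malformed value in column {col} at line "
                f"{int(bad.index[0]) + 2}"  # +2: header plus 1-based
            )
    return DistanceTrace(
        times=df["time_ns"].to_numpy(float), distances=df["distance_A"].to_numpy(float)
    )


def write_distance_trace(trace: DistanceTrace, path) -> None:
    pd.DataFrame({"time_ns": trace.times, "distance_A": trace.distances}).to_csv(
        path, index=False
    )


def read_umbrella_window(path) -> UmbrellaWindow:
    """Read one umbrella-window file (header keys + one sample per line)."""
    path = Path(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise InvalidInputError(f"{path}:{lineno}: bad header line {raw!r}")
            key, value = (s.strip() for s in body.split(":", 1))
            meta[key] = value
        else:
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path}:{lineno}: bad sample value {line!r}"
                ) from exc
    for key in ("center", "force_constant"):
        if key not in meta:
            raise InvalidInputError(f"{path}: missing header key {key!r}")
    return UmbrellaWindow(
        center=float(meta["center"]),
        force_constant=float(meta["force_constant"]),
        samples=np.asarray(samples),
        temperature=float(meta.get("temperature", 310.0)),
        bias_convention=meta.get("bias_convention", "half_k"),
    )


def write_umbrella_window(window: UmbrellaWindow, path) -> None:
    lines = [
        f"# center: {float(window.center)!r}",
        f"# force_constant: {float(window.force_constant)!r}",
        f"# temperature: {float(window.temperature)!r}",
        f"# bias_convention: {window.bias_convention}",
    ]
    lines += [repr(float(s)) for s in window.samples]
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile(profile: FreeEnergyProfile, path) -> None:
    pd.DataFrame(
        {
            "bin_center": profile.bin_centers,
            "g": profile.g,
            "stderr": profile.stderr,
            "count": profile.counts.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_profile(path) -> FreeEnergyProfile:
    df = pd.read_csv(path, sep="\t")
    return FreeEnergyProfile(
        bin_centers=df["bin_center"].to_numpy(float),
        g=df["g"].to_numpy(float),
        stderr=df["stderr"].to_numpy(float),
        counts=df["count"].to_numpy(float),
    )


def read_pdb_models(path) -> list[LabelledFrame]:
    """Read a text PDB into one LabelledFrame per MODEL.

    Fixed-column parsing via biotite; alternate locations resolve to the
    highest-occupancy conformer (first-listed, i.e. 'A', on ties). Frame
    times are the model index in ns (a PDB carries no time axis). Duplicate
    atom labels within a model are an error.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(altloc="occupancy")  # AtomArrayStack
    frames = []
    for m in range(stack.stack_depth()):
        arr = stack[m]
        if np.any(~np.isfinite(arr.coord)):
            raise InvalidInputError(f"{path}: missing/invalid coordinates in model {m + 1}")
        atoms: dict = {}
        for i in range(arr.array_length()):
            label = (
                str(arr.chain_id[i]),
                int(arr.res_id[i]),
                str(arr.res_name[i]),
                str(arr.atom_name[i]),
            )
            if label in atoms:
                raise InvalidInputError(
                    f"{path}: duplicate atom label {label} in model {m + 1}"
                )
            atoms[label] = np.asarray(arr.coord[i], dtype=float)
        frames.append(LabelledFrame(frame_time=float(m), atoms=atoms))
    if not frames:
        raise InvalidInputError(f"{path}: no models found")
    return frames


def read_cycle_model(path) -> CycleModel:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return CycleModel.from_dict(data)


def write_cycle_model(model: CycleModel, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))
    else:
        path.write_text(model.to_json() + "\n")
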