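"""Plain-text trace files and configuration round-trips.

Traces travel as whitespace-delimited ASCII, one file per trace, in the
dialect background-corrected traces are commonly exported in: optional
``#``-prefixed (or any non-numeric) header lines, then one row per frame
with a 0-based frame index, DD, DA and -- for ALEX data -- AA columns, plus
an optional single-letter label column for simulated ground truth.  Two
intensity columns mean non-ALEX, three mean ALEX.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .simulate import SimulationParams
from .trace import CLASSES, LabeledTrace, Trace


class TraceParseError(ValueError):
    pass


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_trace_file(path) -> tuple[Trace, dict]:
    """Parse one ASCII trace file; returns the trace and its header metadata.

    Raises :class:`TraceParseError` naming the offending line for ragged
    rows, non-numeric cells in the data block, or an empty file.
    """
    path = Path(path)
    header: dict = {}
    rows: list[list[float]] = []
    labels: list[str] = []
    n_cols: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            first_numeric = _is_number(tokens[0])
            if not first_numeric or line.startswith("#"):
                text = line.lstrip("#").strip()
                if ":" in text:
                    key, _, val = text.partition(":")
                    header[key.strip()] = val.strip()
                elif text:
                    header[f"line{lineno}"] = text
                continue
            has_label = not _is_number(tokens[-1])
            numeric = tokens[:-1] if has_label else tokens
            if any(not _is_number(t) for t in numeric):
                raise TraceParseError(
                    f"{path.name}:{lineno}: non-numeric cell in data block"
                )
            if has_label and tokens[-1] not in CLASSES:
                raise TraceParseError(
                    f"{path.name}:{lineno}: unknown label {tokens[-1]!r}"
                )
            if n_cols is None:
                n_cols = len(tokens)
            elif len(tokens) != n_cols:
                raise TraceParseError(
                    f"{path.name}:{lineno}: ragged row "
                    f"({len(tokens)} columns, expected {n_cols})"
                )
            rows.append([float(t) for t in numeric])
            if has_label:
                labels.append(tokens[-1])
    if not rows:
        raise TraceParseError(f"{path.name}: no data rows found")
    data = np.asarray(rows)
    n_numeric = data.shape[1]
    if n_numeric not in (3, 4):
        raise TraceParseError(
            f"{path.name}: expected frame + 2 or 3 intensity columns, "
            f"got {n_numeric} numeric columns"
        )
    frames = data[:, 0]
    if not np.array_equal(frames, np.arange(len(frames))):
        raise TraceParseError(
            f"{path.name}: frame indices must be contiguous from 0"
        )
    trace = Trace(
        dd=data[:, 1],
        da=data[:, 2],
        aa=data[:, 3] if n_numeric == 4 else None,
        source_id=path.stem,
    )
    if labels:
        header["labels"] = labels
    return trace, header


def read_traces(path, pattern: str = "*.txt") -> list[Trace]:
    """Read every trace file in a directory (or a single file)."""
    path = Path(path)
    files = [path] if path.is_file() else sorted(path.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no trace files matching {pattern} under {path}")
    return [read_trace_file(f)[0] for f in files]


def write_trace_file(
    trace: Trace,
    path,
    labels: Optional[Sequence[str]] = None,
    header: Optional[dict] = None,
) -> None:
    path = Path(path)
    cols = ["frame", "DD", "DA"] + (["AA"] if trace.is_alex else [])
    if labels is not None:
        cols.append("label")
    with open(path, "w") as fh:
        fh.write(f"# columns: {' '.join(cols)}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        stack = trace.channel_stack()
        for i in range(trace.n_frames):
            vals = " ".join(f"{v:.10g}" for v in stack[i])
            row = f"{i} {vals}"
            if labels is not None:
                row += f" {labels[i]}"
            fh.write(row + "\n")


def write_traces(
    traces: Sequence[Trace] | Sequence[LabeledTrace],
    out_dir,
    include_labels: bool = False,
) -> list[Path]:
    """One file per trace (``trace_00000.txt`` ...); returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, item in enumerate(traces):
        if isinstance(item, LabeledTrace):
            trace = item.trace
            labels = item.labels.hard_symbols() if include_labels else None
        else:
            trace, labels = item, None
        p = out_dir / f"trace_{i:05d}.txt"
        write_trace_file(trace, p, labels=labels)
        written.append(p)
    return written


def write_manifest(dataset: Sequence[LabeledTrace], path) -> None:
    """JSON manifest of the latent generative config per trace."""
    records = [
        {"trace": f"trace_{i:05d}", **lt.config.to_dict()}
        for i, lt in enumerate(dataset)
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def save_training_arrays(dataset: Sequence[LabeledTrace], path, alex: bool = True) -> None:
    """Compact binary bundle of stacked model inputs/targets for training.

    Stores the normalized (N, T, C) input stack, the (N, T, 6) smoothed
    targets and the hard labels in one compressed ``.npz`` -- faster to
    reload than thousands of text files when iterating on training.
    """
    from .trace import stack_dataset

    x, y = stack_dataset(dataset, alex=alex)
    hard = np.stack([lt.labels.hard for lt in dataset]) if len(dataset) else np.empty((0, 0))
    np.savez_compressed(path, x=x, y=y, hard=hard)


def load_training_arrays(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with np.load(path, allow_pickle=False) as data:
        return data["x"], data["y"], data["hard"]


def load_params(path) -> SimulationParams:
    """SimulationParams from a JSON (or simple YAML-compatible) config file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml  # pyyaml is a soft dependency used only for YAML configs

        data = yaml.safe_load(text)
    return SimulationParams.from_dict(data)


def save_params(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
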