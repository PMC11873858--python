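"""File formats: response matrices, draws, summaries, manifests, trace data.

The single on-disk dialect for response data is comma-delimited text, one
row per respondent, one integer score per item, with an optional header
row.  Missing responses are not supported and raise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CategorySpace, InvalidParameterError, ResponseMatrix

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "response_report",
    "write_manifest",
    "write_trace_csv",
    "plot_traces",
]


def _has_header(path: Path) -> bool:
    first = path.open().readline()
    tokens = [t.strip() for t in first.split(",")]
    try:
        [int(t) for t in tokens]
        return False
    except ValueError:
        return True


def read_response_matrix(path, space: CategorySpace | None = None) -> ResponseMatrix:
    """Read and validate a response CSV.

    Ragged rows, non-integer entries and out-of-range scores raise with
    the offending location named (1-based data rows).
    """
    path = Path(path)
    space = space or CategorySpace()
    header = 0 if _has_header(path) else None
    try:
        frame = pd.read_csv(path, header=header, dtype=str)
    except pd.errors.ParserError as exc:
        raise InvalidParameterError(f"{path}: ragged or malformed CSV ({exc})") from exc
    values = np.empty(frame.shape, dtype=np.int64)
    for (r, c), cell in np.ndenumerate(frame.to_numpy()):
        try:
            v = int(str(cell).strip())
        except (TypeError, ValueError):
            raise InvalidParameterError(
                f"{path}: non-integer score {cell!r} at row {r + 1}, column {c + 1}"
            ) from None
        if not 0 <= v <= space.h:
            raise InvalidParameterError(
                f"{path}: score {v} outside 0..{space.h} at row {r + 1}, "
                f"column {c + 1}"
            )
        values[r, c] = v
    return ResponseMatrix(values, space)


def write_response_matrix(data: ResponseMatrix, path, header: bool = True) -> None:
    frame = pd.DataFrame(
        data.scores, columns=[f"item{j + 1}" for j in range(data.n_items)]
    )
    frame.to_csv(path, index=False, header=header)


def response_report(data: ResponseMatrix) -> dict:
    """Shape and category-frequency summary of a validated matrix."""
    counts = np.stack(
        [
            np.bincount(data.scores[:, j], minlength=data.space.n_categories)
            for j in range(data.n_items)
        ]
    )
    return {
        "n_persons": data.n_persons,
        "n_items": data.n_items,
        "n_categories": data.space.n_categories,
        "middle_share": float(data.middle_mask.mean()),
        "category_frequencies": (counts / max(data.n_persons, 1)).tolist(),
    }


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(out_dir, *, command: str, seed: int, config, input_path=None) -> Path:
    """Record everything needed to reproduce a run byte-for-byte."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
        "version": __version__,
        "input": str(input_path) if input_path else None,
        "input_sha256": _sha256(input_path) if input_path else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def write_trace_csv(draws_frame: pd.DataFrame, path) -> None:
    """Tidy trace export: one row per (draw, parameter, value)."""
    tidy = draws_frame.reset_index(names="draw").melt(
        id_vars="draw", var_name="parameter", value_name="value"
    )
    tidy.to_csv(path, index=False)


def plot_traces(draws_frame: pd.DataFrame, parameters, path) -> None:
    """Render trace-plot panels for the named parameters to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    parameters = list(parameters)
    fig, axes = plt.subplots(
        len(parameters), 1, figsize=(7, 1.8 * len(parameters)), squeeze=False
    )
    for ax, name in zip(axes[:, 0], parameters):
        ax.plot(draws_frame[name].to_numpy(), lw=0.6)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("retained draw")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
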