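"""CSV input/output for experiments and call tables.

Two files describe an experiment:

* a *peaks* file — columns ``probe_id, size_bp, is_reference`` followed by one
  intensity column per run id;
* a *meta* file — columns ``run_id, group, subject_id, replicate_index``.

All files are comma-separated UTF-8 with a header row and "." as the decimal
separator.  Missing intensity cells are not permitted: MLPA peak exports are
dense, and absent peaks must be encoded as 0 upstream (they are then caught by
the all-zero-probe validity flag).  Group labels are read case-insensitively
and written canonically as ``control``/``case``.  Replicate structure is taken
from the metadata only, never inferred from run-id naming.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .model import CALL_COLUMNS, CNACallTable, MLPAExperiment, ProbePanel, SampleMeta

_PEAK_FIXED = ["probe_id", "size_bp", "is_reference"]
_META_COLS = ["run_id", "group", "subject_id", "replicate_index"]
_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no"}


def _parse_bool(value, context: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"{context}: cannot parse boolean {value!r}")


def read_experiment(peaks_path, meta_path) -> MLPAExperiment:
    """Read a peaks/metadata CSV pair into a validated experiment."""
    peaks = _read_csv(peaks_path)
    meta = _read_csv(meta_path)
    for col in _PEAK_FIXED:
        if col not in peaks.columns:
            raise FormatError(f"peaks file missing column {col!r}")
    for col in _META_COLS:
        if col not in meta.columns:
            raise FormatError(f"metadata file missing column {col!r}")
    run_cols = [c for c in peaks.columns if c not in _PEAK_FIXED]
    if not run_cols:
        raise FormatError("peaks file has no run columns")
    meta_runs = [str(r) for r in meta["run_id"]]
    missing = [r for r in run_cols if r not in meta_runs]
    if missing:
        raise FormatError(f"run(s) present in peaks but absent from metadata: {missing}")
    extra = [r for r in meta_runs if r not in run_cols]
    if extra:
        raise FormatError(f"run(s) present in metadata but absent from peaks: {extra}")

    panel = ProbePanel(
        probe_ids=tuple(str(p) for p in peaks["probe_id"]),
        sizes_bp=_numeric(peaks["size_bp"], "size_bp"),
        is_reference=np.array(
            [_parse_bool(v, f"probe {p}") for p, v in zip(peaks["probe_id"], peaks["is_reference"])]
        ),
    )
    meta = meta.set_index(meta["run_id"].astype(str))
    samples = []
    for run in run_cols:  # preserve peaks-file column order
        row = meta.loc[run]
        samples.append(
            SampleMeta(
                run_id=run,
                group=str(row["group"]),
                subject_id=str(row["subject_id"]),
                replicate_index=int(row["replicate_index"]),
            )
        )
    values = np.column_stack([_numeric(peaks[run], f"run {run}") for run in run_cols])
    return MLPAExperiment(panel=panel, samples=tuple(samples), intensities=values)


def write_experiment(exp: MLPAExperiment, peaks_path, meta_path) -> None:
    """Write the peaks/metadata CSV pair; inverse of :func:`read_experiment`."""
    peaks = pd.DataFrame(
        {
            "probe_id": list(exp.panel.probe_ids),
            "size_bp": exp.panel.sizes_bp,
            "is_reference": exp.panel.is_reference,
        }
    )
    for j, run in enumerate(exp.run_ids):
        peaks[run] = exp.intensities[:, j]
    peaks.to_csv(peaks_path, index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "run_id": [s.run_id for s in exp.samples],
            "group": [s.group for s in exp.samples],
            "subject_id": [s.subject_id for s in exp.samples],
            "replicate_index": [s.replicate_index for s in exp.samples],
        }
    )
    meta.to_csv(meta_path, index=False)


def write_calls(calls: CNACallTable, path) -> None:
    """Write a call table as CSV with a stable column order."""
    calls.frame.to_csv(path, index=False, columns=CALL_COLUMNS, float_format="%.17g")


def read_calls(path, method: str | None = None) -> CNACallTable:
    """Read a call table written by :func:`write_calls`."""
    frame = _read_csv(path)
    missing = [c for c in CALL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"calls file missing column(s): {missing}")
    if len(frame):
        frame["is_reference"] = [
            _parse_bool(v, f"probe {p}") for p, v in zip(frame["probe_id"], frame["is_reference"])
        ]
        frame["probe_id"] = frame["probe_id"].astype(str)
        frame["case_unit"] = frame["case_unit"].astype(str)
        frame["method"] = frame["method"].astype(str)
    else:
        frame = pd.DataFrame(columns=CALL_COLUMNS)
    if method is None:
        methods = frame["method"].unique().tolist() if len(frame) else []
        method = methods[0] if len(methods) == 1 else "mixed"
    return CNACallTable(frame=frame, method=method)


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        return pd.read_csv(
            path,
            dtype={"probe_id": str, "run_id": str, "subject_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _numeric(column: pd.Series, context: str) -> np.ndarray:
    try:
        return pd.to_numeric(column, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable number in {context}: {exc}") from exc
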