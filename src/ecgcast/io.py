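"""Readers and writers: WFDB format-212 records, CSV signals, model files.

The WFDB reader covers what the MIT-BIH Arrhythmia Database uses: a
plain-text header (``.hea``) plus a format-212 signal file (``.dat``)
in which two 12-bit two's-complement samples are packed into 3 bytes.
Sample values convert to physical units as (adu - baseline) / gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import EmbeddingParams
from .rbf import RbfModel
from .signal import InvalidInputError, Signal

__all__ = [
    "WfdbRecordMeta",
    "WfdbParseError",
    "read_wfdb_header",
    "read_wfdb_212",
    "write_wfdb_212",
    "read_csv_signal",
    "write_csv_signal",
    "save_model",
    "load_model",
]


class WfdbParseError(ValueError):
    """Malformed WFDB header or signal file."""


@dataclass
class WfdbSignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str


@dataclass
class WfdbRecordMeta:
    record_name: str
    n_signals: int
    fs: float
    n_samples: int
    signals: list[WfdbSignalSpec]


def read_wfdb_header(header_path: str | Path) -> WfdbRecordMeta:
    """Parse a WFDB ``.hea`` file (format-212 signal lines only)."""
    path = Path(header_path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise WfdbParseError(f"{path}: empty header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise WfdbParseError(f"{path}: malformed record line {lines[0]!r}")
    try:
        name = rec[0].split("/")[0]
        n_signals = int(rec[1])
        fs = float(rec[2]) if len(rec) > 2 else 250.0
        n_samples = int(rec[3]) if len(rec) > 3 else 0
    except ValueError as exc:
        raise WfdbParseError(f"{path}: malformed record line {lines[0]!r}") from exc

    specs: list[WfdbSignalSpec] = []
    for ln in lines[1: 1 + n_signals]:
        f = ln.split()
        if len(f) < 3:
            raise WfdbParseError(f"{path}: malformed signal line {ln!r}")
        try:
            fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
            gain_field = f[2].split("/")[0]  # "200(1024)/mV" or "200"
            if "(" in gain_field:
                gain = float(gain_field[: gain_field.index("(")])
                baseline = int(gain_field[gain_field.index("(") + 1: -1])
            else:
                gain = float(gain_field)
                baseline = int(f[4]) if len(f) > 4 else 0  # adc_zero
            if gain == 0:
                gain = 200.0  # WFDB default for an unspecified gain
        except ValueError as exc:
            raise WfdbParseError(f"{path}: malformed signal line {ln!r}") from exc
        desc = " ".join(f[8:]) if len(f) > 8 else ""
        specs.append(
            WfdbSignalSpec(
                file_name=f[0], fmt=fmt, gain=gain, baseline=baseline,
                description=desc,
            )
        )
    if len(specs) != n_signals:
        raise WfdbParseError(f"{path}: expected {n_signals} signal lines")
    for s in specs:
        if s.fmt != 212:
            raise WfdbParseError(f"{path}: unsupported signal format {s.fmt}")
        if s.gain <= 0:
            raise WfdbParseError(f"{path}: non-positive gain")
    return WfdbRecordMeta(
        record_name=name, n_signals=n_signals, fs=fs,
        n_samples=n_samples, signals=specs,
    )


def _decode_212(data: bytes, n_values: int) -> np.ndarray:
    """Unpack ``n_values`` 12-bit two's-complement samples from packed
    3-byte pairs (value order as stored: low sample first)."""
    n_triplets = (n_values + 1) // 2
    if len(data) < 3 * n_triplets:
        raise IOError(
            f"truncated format-212 data: need {3 * n_triplets} bytes, "
            f"have {len(data)} (short at byte offset {len(data)})"
        )
    b = np.frombuffer(data[: 3 * n_triplets], dtype=np.uint8).reshape(-1, 3)
    first = b[:, 0].astype(np.int32) | ((b[:, 1] & 0x0F).astype(np.int32) << 8)
    second = b[:, 2].astype(np.int32) | ((b[:, 1] & 0xF0).astype(np.int32) << 4)
    vals = np.empty(2 * n_triplets, dtype=np.int32)
    vals[0::2] = first
    vals[1::2] = second
    vals[vals >= 2048] -= 4096
    return vals[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    """Inverse of :func:`_decode_212`; values must fit in 12 bits signed."""
    v = np.asarray(values, dtype=np.int64)
    if np.any((v < -2048) | (v > 2047)):
        raise InvalidInputError("format 212 requires samples in [-2048, 2047]")
    if v.size % 2:
        v = np.concatenate([v, [0]])
    u = np.where(v < 0, v + 4096, v).astype(np.uint16)
    first, second = u[0::2], u[1::2]
    out = np.empty((first.size, 3), dtype=np.uint8)
    out[:, 0] = first & 0xFF
    out[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
    out[:, 2] = second & 0xFF
    return out.tobytes()


def read_wfdb_212(
    header_path: str | Path,
    channel: int = 0,
    start: int = 0,
    count: int | None = None,
) -> Signal:
    """Read a window of one channel from a format-212 WFDB record.

    Returns amplitudes in mV via (adu - baseline) / gain.  ``count``
    defaults to the rest of the record; ``count=0`` yields an empty
    array (bypassing the usual minimum-length check is not needed
    because a zero-length window is rejected by :class:`Signal`).
    """
    meta = read_wfdb_header(header_path)
    if not (0 <= channel < meta.n_signals):
        raise InvalidInputError(
            f"channel {channel} out of range (record has {meta.n_signals})"
        )
    if count is None:
        count = meta.n_samples - start
    if start < 0 or count < 0 or (
        meta.n_samples and start + count > meta.n_samples
    ):
        raise InvalidInputError(
            f"window [{start}, {start + count}) outside record "
            f"of {meta.n_samples} samples"
        )
    spec = meta.signals[channel]
    dat_path = Path(header_path).parent / spec.file_name
    data = dat_path.read_bytes()

    nsig = meta.n_signals
    # values are stored frame-interleaved: value index = sample*nsig + channel
    n_values_needed = (start + count) * nsig
    vals = _decode_212(data, n_values_needed)
    adu = vals[channel::nsig][start: start + count]
    mv = (adu - spec.baseline) / spec.gain
    return Signal(samples=mv, fs=meta.fs, name=f"{meta.record_name}:{channel}")


def write_wfdb_212(
    directory: str | Path,
    record_name: str,
    signals_adu: np.ndarray,
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
    descriptions: list[str] | None = None,
) -> Path:
    """Write a (synthetic) format-212 record: ``.hea`` + ``.dat``.

    ``signals_adu`` is an (n_signals, n_samples) integer array in adu.
    Intended for fixtures and round-trip tests; returns the header path.
    """
    directory = Path(directory)
    sig = np.atleast_2d(np.asarray(signals_adu))
    nsig, nsamp = sig.shape
    descriptions = descriptions or [f"ch{i}" for i in range(nsig)]
    dat_name = f"{record_name}.dat"
    interleaved = sig.T.reshape(-1)
    (directory / dat_name).write_bytes(_encode_212(interleaved))
    lines = [f"{record_name} {nsig} {fs:g} {nsamp}"]
    for i in range(nsig):
        lines.append(
            f"{dat_name} 212 {gain:g}({baseline})/mV 12 {baseline} "
            f"{int(sig[i, 0])} 0 0 {descriptions[i]}"
        )
    header = directory / f"{record_name}.hea"
    header.write_text("\n".join(lines) + "\n")
    return header


def read_csv_signal(
    path: str | Path,
    column: str | int = 0,
    fs: float | None = None,
) -> Signal:
    """Read one numeric column (by name or position) as a Signal."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InvalidInputError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise InvalidInputError(f"{path}: no data rows")
    if isinstance(column, int):
        if column >= df.shape[1]:
            raise InvalidInputError(f"{path}: no column index {column}")
        series = df.iloc[:, column]
        # a header-less numeric file puts the first value in the header
        try:
            first = [float(df.columns[column])]
        except (TypeError, ValueError):
            first = []
    else:
        if column not in df.columns:
            raise InvalidInputError(f"{path}: no column named {column!r}")
        series = df[column]
        first = []
    values = pd.to_numeric(series, errors="coerce")
    bad = values.index[values.isna() & series.notna()]
    if len(bad):
        raise InvalidInputError(
            f"{path}: non-numeric value at data row {int(bad[0]) + 1}"
        )
    if values.isna().any():
        raise InvalidInputError(
            f"{path}: missing value at data row {int(values.index[values.isna()][0]) + 1}"
        )
    samples = np.concatenate([first, values.to_numpy(dtype=float)])
    return Signal(samples=samples, fs=fs, name=path.stem)


def write_csv_signal(path: str | Path, signal: Signal, column: str = "value") -> None:
    pd.DataFrame({column: signal.samples}).to_csv(path, index=False)


def _model_to_dict(model) -> dict:
    from .predictor import HybridModel  # local import to avoid a cycle

    assert isinstance(model, HybridModel)
    return {
        "format": "ecgcast-hybrid-model",
        "version": 1,
        "config": {
            "vmd": asdict(model.config.vmd),
            **{
                k: v
                for k, v in asdict(model.config).items()
                if k != "vmd"
            },
        },
        "split_index": model.split_index,
        "omega": model.vmd_result.omega.tolist(),
        "modes": model.vmd_result.modes.tolist(),
        "vmd_iterations": model.vmd_result.iterations,
        "vmd_converged": model.vmd_result.converged,
        "vmd_final_increment": model.vmd_result.final_increment,
        "signal": {
            "samples": model.signal.samples.tolist(),
            "fs": model.signal.fs,
            "name": model.signal.name,
        },
        "per_imf": [
            {
                "m": rec.params.m,
                "tau": rec.params.tau,
                "degenerate": rec.degenerate,
                "constant_value": rec.constant_value,
                "scale_min": rec.scale_min,
                "scale_range": rec.scale_range,
                "model": None
                if rec.model is None
                else {
                    "centers": rec.model.centers.tolist(),
                    "sigma": rec.model.sigma,
                    "weights": rec.model.weights.tolist(),
                    "spread": rec.model.spread,
                },
            }
            for rec in model.per_imf
        ],
    }


def save_model(path: str | Path, model) -> None:
    """Serialize a fitted hybrid model to structured text (JSON).

    Floats are written with full repr precision, so a load reproduces
    the model bit-exactly.
    """
    Path(path).write_text(json.dumps(_model_to_dict(model)))


def load_model(path: str | Path):
    from .predictor import HybridConfig, HybridModel, ImfRecord
    from .vmd import VmdConfig, VmdResult

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ecgcast-hybrid-model":
        raise InvalidInputError(f"{path}: not an ecgcast model file")
    cfg_doc = dict(doc["config"])
    vmd_cfg = VmdConfig(**cfg_doc.pop("vmd"))
    config = HybridConfig(vmd=vmd_cfg, **cfg_doc)
    vmd_result = VmdResult(
        modes=np.array(doc["modes"], dtype=float),
        omega=np.array(doc["omega"], dtype=float),
        iterations=doc["vmd_iterations"],
        converged=doc["vmd_converged"],
        final_increment=doc["vmd_final_increment"],
    )
    signal = Signal(
        samples=np.array(doc["signal"]["samples"], dtype=float),
        fs=doc["signal"]["fs"],
        name=doc["signal"]["name"],
    )
    per_imf = []
    for rec in doc["per_imf"]:
        model = None
        if rec["model"] is not None:
            model = RbfModel(
                centers=np.array(rec["model"]["centers"], dtype=float),
                sigma=rec["model"]["sigma"],
                weights=np.array(rec["model"]["weights"], dtype=float),
                spread=rec["model"]["spread"],
            )
        per_imf.append(
            ImfRecord(
                params=EmbeddingParams(m=rec["m"], tau=rec["tau"]),
                model=model,
                degenerate=rec["degenerate"],
                constant_value=rec["constant_value"],
                scale_min=rec["scale_min"],
                scale_range=rec["scale_range"],
            )
        )
    return HybridModel(
        per_imf=per_imf,
        vmd_result=vmd_result,
        split_index=doc["split_index"],
        config=config,
        signal=signal,
    )
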