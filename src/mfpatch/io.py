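"""Plain-text recording files and result artifacts.

Recording format: UTF-8 text with ``# key: value`` header comment lines
followed by one current sample (amperes) per line, e.g. ::

    # condition: control
    # replicate: 1
    # sampling_interval_s: 5e-05
    # voltage_mV: -100.0
    -1.02343770574628572e-12
    ...

``sampling_interval_s`` is required for single-column files.  A two-column
``time<TAB>current`` layout is also accepted; there the sampling interval
may be inferred from the time column.  Writes are canonical (sorted header
keys, 17-significant-digit scientific notation) so a write/read round trip
preserves samples and metadata bit-exactly and diffs are deterministic.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np

from .exceptions import FormatError, InputError
from .recording import Recording

__all__ = ["read_recording", "write_recording", "write_manifest"]

_KNOWN_KEYS = {
    "sampling_interval_s": float,
    "voltage_mV": float,
    "replicate": int,
    "condition": str,
    "incubation_min": float,
}


def _format_meta(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_recording(path) -> Recording:
    """Parse a recording file into a validated :class:`Recording`.

    Unknown header keys are preserved in ``Recording.extra``.  Errors cite
    the offending 1-based line number.
    """
    meta: dict[str, str] = {}
    samples: list[float] = []
    times: list[float] = []
    two_column = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise FormatError(
                        f"{path}: malformed header at line {lineno}: {line!r}"
                    )
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
                continue
            fields = line.replace(",", "\t").split()
            if two_column is None:
                two_column = len(fields) == 2
            if len(fields) != (2 if two_column else 1):
                raise FormatError(
                    f"{path}: inconsistent column count at line {lineno}"
                )
            try:
                row = [float(f) for f in fields]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric sample at line {lineno}: {line!r}"
                ) from None
            if two_column:
                times.append(row[0])
                samples.append(row[1])
            else:
                samples.append(row[0])

    if "sampling_interval_s" in meta:
        try:
            dt = float(meta.pop("sampling_interval_s"))
        except ValueError:
            raise FormatError(f"{path}: sampling_interval_s is not numeric") from None
    elif two_column and len(times) >= 2:
        dt = float(times[1] - times[0])
    else:
        raise FormatError(f"{path}: missing required header 'sampling_interval_s'")

    kwargs: dict = {}
    extra: dict = {}
    for key, value in meta.items():
        if key in _KNOWN_KEYS:
            caster = _KNOWN_KEYS[key]
            try:
                kwargs[key.replace("sampling_interval_s", "dt")] = caster(value)
            except ValueError:
                raise FormatError(f"{path}: header {key} is not {caster.__name__}") from None
        else:
            extra[key] = value
    try:
        return Recording(
            values=np.asarray(samples, dtype=float), dt=dt, extra=extra, **kwargs
        )
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_recording(r: Recording, path) -> None:
    """Write a recording in the canonical single-column text format.

    Header keys are emitted in sorted order; samples use 17-significant-digit
    scientific notation, which round-trips IEEE doubles exactly.
    """
    meta: dict[str, object] = {"sampling_interval_s": float(r.dt)}
    if r.voltage_mV is not None:
        meta["voltage_mV"] = float(r.voltage_mV)
    if r.replicate is not None:
        meta["replicate"] = int(r.replicate)
    if r.condition is not None:
        meta["condition"] = str(r.condition)
    if r.incubation_min is not None:
        meta["incubation_min"] = float(r.incubation_min)
    meta.update(r.extra)
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {_format_meta(meta[key])}\n")
        for v in r.values:
            fh.write(f"{v:.17e}\n")


def write_tsv(path, columns: dict[str, Iterable], float_format: str = ".17g") -> None:
    """Write named columns as a TSV with deterministic float formatting."""
    names = list(columns)
    cols = [list(columns[n]) for n in names]
    n_rows = len(cols[0]) if cols else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(n_rows):
            cells = []
            for col in cols:
                v = col[i]
                if isinstance(v, (float, np.floating)):
                    cells.append("nan" if np.isnan(v) else format(float(v), float_format))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def write_manifest(path, manifest: dict) -> None:
    """Write a JSON run manifest (sorted keys, schema-versioned)."""
    payload = {"schema_version": 1, **manifest}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
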