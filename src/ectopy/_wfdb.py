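"""Minimal reader/writer for the WFDB physiological-signal format.

Supports the subset of the format family needed for single/two-lead
ambulatory ECG work: text headers (``.hea``), signal files (``.dat``) in
formats 212, 16 and 80, and MIT-format annotation files (``.atr`` or any
other extension). Sample values convert to/from physical units through the
per-signal gain and baseline declared in the header.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalSpec",
    "WfdbHeader",
    "read_header",
    "read_signals",
    "read_annotations",
    "write_record",
    "write_annotations",
    "ANNOTATION_CODES",
    "SYMBOL_TO_CODE",
]


@dataclass
class SignalSpec:
    """One signal line of a WFDB header."""

    file_name: str
    fmt: int
    gain: float = 200.0       # adu per physical unit
    baseline: int = 0
    units: str = "mV"
    adc_res: int = 12
    adc_zero: int = 0
    init_value: int = 0
    checksum: int = 0
    block_size: int = 0
    description: str = ""


@dataclass
class WfdbHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalSpec] = field(default_factory=list)


def _parse_gain_field(tok: str) -> tuple[float, int | None, str]:
    """Parse ``gain(baseline)/units`` with all parts optional."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = None
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_header(path: str) -> WfdbHeader:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    record_name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        toks = ln.split()
        fmt = int(toks[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = _parse_gain_field(toks[2]) if len(toks) > 2 else (200.0, None, "mV")
        adc_res = int(toks[3]) if len(toks) > 3 else 12
        adc_zero = int(toks[4]) if len(toks) > 4 else 0
        init_value = int(toks[5]) if len(toks) > 5 else adc_zero
        checksum = int(toks[6]) if len(toks) > 6 else 0
        block_size = int(toks[7]) if len(toks) > 7 else 0
        description = " ".join(toks[8:]) if len(toks) > 8 else ""
        signals.append(SignalSpec(
            file_name=toks[0], fmt=fmt, gain=gain,
            baseline=baseline if baseline is not None else adc_zero,
            units=units, adc_res=adc_res, adc_zero=adc_zero,
            init_value=init_value, checksum=checksum,
            block_size=block_size, description=description))
    return WfdbHeader(record_name, n_sig, fs, n_samples, signals)


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = len(b) // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_triplets, dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    out[out > 2047] -= 4096
    return out[:n_values]


def read_signals(header_path: str) -> tuple[WfdbHeader, np.ndarray]:
    """Read all channels; returns (header, physical array shape (n, n_sig)).

    Physical units are whatever the header declares (mV for standard ECG
    records); unit conversion is the caller's concern.
    """
    hdr = read_header(header_path)
    base_dir = os.path.dirname(os.path.abspath(header_path))
    # group channels by dat file (all mitdb records share one dat per record)
    dat_files: dict[str, list[int]] = {}
    for idx, spec in enumerate(hdr.signals):
        dat_files.setdefault(spec.file_name, []).append(idx)
    phys = np.empty((hdr.n_samples, hdr.n_sig), dtype=np.float64)
    for fname, idxs in dat_files.items():
        specs = [hdr.signals[i] for i in idxs]
        fmt = specs[0].fmt
        n_ch = len(idxs)
        with open(os.path.join(base_dir, fname), "rb") as fh:
            raw = fh.read()
        n_values = hdr.n_samples * n_ch if hdr.n_samples else None
        if fmt == 212:
            if n_values is None:
                n_values = (len(raw) // 3) * 2
            adus = _decode_212(raw, n_values)
        elif fmt == 16:
            adus = np.frombuffer(raw, dtype="<i2").astype(np.int32)
            if n_values is not None:
                adus = adus[:n_values]
        elif fmt == 80:
            adus = np.frombuffer(raw, dtype=np.uint8).astype(np.int32) - 128
            if n_values is not None:
                adus = adus[:n_values]
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt}")
        n = len(adus) // n_ch
        if hdr.n_samples == 0:
            hdr.n_samples = n
            phys = np.empty((n, hdr.n_sig), dtype=np.float64)
        adus = adus[: n * n_ch].reshape(n, n_ch)
        for k, (i, spec) in enumerate(zip(idxs, specs)):
            phys[:, i] = (adus[:, k] - spec.baseline) / spec.gain
    return hdr, phys


# -- MIT annotation format ---------------------------------------------------

# Annotation-code table (code -> mnemonic) for the codes that occur in
# arrhythmia-database work.
ANNOTATION_CODES: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {v: k for k, v in ANNOTATION_CODES.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_annotations(path: str) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file.

    Returns a list of ``(sample_index, symbol)`` pairs in file order;
    non-annotation pseudo-entries (NUM/SUB/CHN/AUX fields) are consumed
    silently.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            long_iv = (hi << 16) | lo
            if long_iv >= 1 << 31:
                long_iv -= 1 << 32
            t += long_iv
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += interval + (interval & 1)
        else:
            t += interval
            out.append((t, ANNOTATION_CODES.get(code, "?")))
    return out


def write_annotations(path: str, annotations: list[tuple[int, str]]) -> None:
    """Write ``(sample_index, symbol)`` pairs as an MIT-format file."""
    buf = bytearray()
    prev = 0
    for sample, symbol in annotations:
        code = SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no annotation code for symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta >= 1024:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
    buf += struct.pack("<H", 0)
    with open(path, "wb") as fh:
        fh.write(buf)


def write_record(
    path_stem: str,
    samples_uv: np.ndarray,
    fs: float,
    lead_label: str = "ECG",
    annotations: list[tuple[int, str]] | None = None,
    ann_ext: str = "atr",
) -> None:
    """Write a single-channel record as format-16 WFDB files.

    ``samples_uv`` is stored with gain 1000 adu/mV so one adu equals one μV;
    values outside the int16 range are clipped.
    """
    record = os.path.basename(path_stem)
    adus = np.clip(np.round(samples_uv), -32768, 32767).astype("<i2")
    checksum = int(np.sum(adus.astype(np.int64)) % 65536)
    if checksum >= 32768:
        checksum -= 65536
    with open(path_stem + ".hea", "w") as fh:
        fh.write(f"{record} 1 {fs:g} {len(adus)}\n")
        fh.write(
            f"{record}.dat 16 1000(0)/mV 16 0 {int(adus[0]) if len(adus) else 0}"
            f" {checksum} 0 {lead_label}\n"
        )
    with open(path_stem + ".dat", "wb") as fh:
        fh.write(adus.tobytes())
    if annotations is not None:
        write_annotations(path_stem + "." + ann_ext, annotations)
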