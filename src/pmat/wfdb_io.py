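"""Minimal reader/writer for PhysioNet WFDB records (.hea/.dat/.atr).

Covers what the annotated arrhythmia databases need: header parsing with
per-signal gain/baseline/units, signal formats 16 (little-endian int16)
and 212 (packed 12-bit pairs), and the MIT annotation format including
the SKIP/NUM/SUB/CHN/AUX pseudo-annotations.  Samples are returned in
physical units: ``(adc - baseline) / gain``.

Writing targets fixtures: format 16 signals and plain annotation streams,
readable both by this module and by standard WFDB tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# MIT annotation code <-> display symbol (standard PhysioNet table)
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass
class Header:
    record_name: str
    n_signals: int
    sampling_rate: float
    n_samples: int
    signals: list[SignalSpec]


def _parse_gain(token: str) -> tuple[float, int | None, str]:
    """Parse 'gain(baseline)/units'; zero/absent gain defaults to 200."""
    units = "mV"
    if "/" in token:
        token, units = token.split("/", 1)
    baseline = None
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(token) if token else 0.0
    if gain == 0.0:
        gain = 200.0
    return gain, baseline, units


def read_header(path: str | Path) -> Header:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    if len(first) < 2:
        raise IOError(f"malformed header line in {path}: {lines[0]!r}")
    name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fmt = int("".join(ch for ch in tok[1] if ch.isdigit()) or "8")
        gain, baseline, units = _parse_gain(tok[2]) if len(tok) > 2 \
            else (200.0, None, "mV")
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalSpec(
            filename=tok[0], fmt=fmt, gain=gain,
            baseline=adc_zero if baseline is None else baseline,
            units=units, description=description))
    return Header(name, n_sig, fs, n_samples, signals)


def _read_fmt16(raw: bytes, n_sig: int) -> np.ndarray:
    data = np.frombuffer(raw, dtype="<i2")
    return data[: (data.size // n_sig) * n_sig].reshape(-1, n_sig)


def _read_fmt212(raw: bytes, n_sig: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    s1 = b[:, 2] | ((b[:, 1] >> 4) << 8)
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(s0.size * 2, dtype=np.int32)
    flat[0::2], flat[1::2] = s0, s1
    return flat[: (flat.size // n_sig) * n_sig].reshape(-1, n_sig)


def read_signals(header: Header, directory: str | Path) -> np.ndarray:
    """All leads in physical units, shape (n_samples, n_signals)."""
    directory = Path(directory)
    raw = (directory / header.signals[0].filename).read_bytes()
    fmt = header.signals[0].fmt
    if fmt == 16:
        adc = _read_fmt16(raw, header.n_signals)
    elif fmt == 212:
        adc = _read_fmt212(raw, header.n_signals)
    else:
        raise IOError(f"unsupported signal format {fmt}")
    if header.n_samples:
        adc = adc[:header.n_samples]
    out = np.empty(adc.shape, dtype=float)
    for i, spec in enumerate(header.signals):
        out[:, i] = (adc[:, i] - spec.baseline) / spec.gain
    return out


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """(sample, symbol) pairs from a MIT-format annotation file."""
    raw = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP and interval == 0:
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            pending_skip = (high << 16) | low
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
        elif code == _AUX:
            i += interval + (interval % 2)
        elif code in (_NUM, _SUB, _CHN):
            pass
        else:
            time += interval + pending_skip
            pending_skip = 0
            if code in CODE_TO_SYMBOL:
                out.append((time, CODE_TO_SYMBOL[code]))
    return out


def write_record(directory: str | Path, name: str, samples: np.ndarray,
                 sampling_rate: float,
                 annotations: list[tuple[int, str]] | None = None,
                 lead_names: tuple[str, ...] = ("MLII",),
                 gain: float = 1000.0, units: str = "mV") -> None:
    """Write a .hea/.dat (format 16) and optional .atr triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sig = np.atleast_2d(np.asarray(samples, dtype=float))
    if sig.shape[0] < sig.shape[1]:
        sig = sig.T
    n_samp, n_sig = sig.shape
    adc = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")

    lines = [f"{name} {n_sig} {sampling_rate:g} {n_samp}"]
    for i in range(n_sig):
        checksum = int(adc[:, i].astype(np.int64).sum() % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(
            f"{name}.dat 16 {gain:g}(0)/{units} 16 0 "
            f"{int(adc[0, i])} {checksum} 0 {lead_names[i]}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    adc.reshape(-1).tofile(directory / f"{name}.dat")

    if annotations is not None:
        write_annotations(directory / f"{name}.atr", annotations)


def write_annotations(path: str | Path,
                      annotations: list[tuple[int, str]]) -> None:
    parts = bytearray()
    prev = 0
    for sample, symbol in sorted(annotations):
        code = SYMBOL_TO_CODE.get(str(symbol))
        if code is None:
            raise ValueError(f"unknown annotation symbol {symbol!r}")
        delta = int(sample) - prev
        if delta < 0:
            raise ValueError("annotation samples must be ascending")
        if delta > 1023:
            parts += (_SKIP << 10).to_bytes(2, "little")
            parts += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            parts += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        parts += ((code << 10) | delta).to_bytes(2, "little")
        prev = int(sample)
    parts += (0).to_bytes(2, "little")
    Path(path).write_bytes(bytes(parts))
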