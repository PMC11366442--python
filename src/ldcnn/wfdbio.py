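"""Minimal codec for the PhysioNet WFDB file family.

Supports what the beat-classification pipeline needs and nothing more:

* headers (``.hea``): record line + one line per signal;
* signal files (``.dat``): formats 212 (the MIT-BIH packing: two 12-bit
  samples in 3 bytes), 16 (little-endian int16) and 32 (little-endian int32);
* annotation files (``.atr``): the MIT annotation format (16-bit words,
  6-bit type code + 10-bit time increment, with SKIP/NUM/SUB/CHN/AUX
  pseudo-annotations).

Amplitudes convert between ADC units and physical mV via the per-signal
gain/baseline from the header.  The writer emits format 32 with a gain of
1e6 ADU/mV so that a write→read round trip is exact to better than 1e-6 mV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import IOFormatError

# WFDB annotation type codes <-> symbols (the subset in common use).
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

#: Codes that denote an actual QRS complex (a beat), as opposed to rhythm
#: changes, signal-quality flags, waveform boundaries and other markers.
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41})
BEAT_SYMBOLS = frozenset(CODE_TO_SYMBOL[c] for c in BEAT_CODES)

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    """Per-signal header fields (the ones this codec interprets)."""

    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass
class RecordHeader:
    record_name: str
    n_signals: int
    sampling_rate: float
    n_samples: int
    signals: list[SignalInfo]


def read_header(path: str) -> RecordHeader:
    try:
        with open(path) as fh:
            lines = [
                ln.strip()
                for ln in fh
                if ln.strip() and not ln.startswith("#")
            ]
    except OSError as exc:
        raise IOFormatError(f"cannot read header {path!r}: {exc}") from exc
    if not lines:
        raise IOFormatError(f"empty header file {path!r}")
    rec = lines[0].split()
    if len(rec) < 2:
        raise IOFormatError(f"malformed record line in {path!r}: {lines[0]!r}")
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise IOFormatError(f"malformed signal line in {path!r}: {ln!r}")
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, 0, "mV"
        if len(tok) > 2:
            gspec = tok[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gpart, bpart = gspec.split("(", 1)
                baseline = int(bpart.rstrip(")"))
                gspec = gpart
            gain = float(gspec) if gspec else 200.0
            if gain == 0:
                gain = 200.0
        if len(tok) > 4 and baseline == 0:
            # adc zero column doubles as baseline when no explicit "(baseline)"
            try:
                baseline = int(tok[4])
            except ValueError:
                pass
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalInfo(tok[0], fmt, gain, baseline, units, desc))
    return RecordHeader(name, n_sig, fs, n_samp, signals)


def _read_dat(path: str, fmt: int, n_signals: int, n_samples: int) -> np.ndarray:
    """Return an (n_samples, n_signals) int array of ADC units."""
    try:
        raw = np.fromfile(path, dtype=np.uint8)
    except OSError as exc:
        raise IOFormatError(f"cannot read signal file {path!r}: {exc}") from exc
    total = n_samples * n_signals
    if fmt == 16:
        data = raw.view("<i2")[:total].astype(np.int64)
    elif fmt == 32:
        data = raw.view("<i4")[:total].astype(np.int64)
    elif fmt == 212:
        n_pairs = (total + 1) // 2
        raw = raw[: n_pairs * 3]
        b0 = raw[0::3].astype(np.int64)
        b1 = raw[1::3].astype(np.int64)
        b2 = raw[2::3].astype(np.int64)
        first = b0 | ((b1 & 0x0F) << 8)
        second = b2 | ((b1 & 0xF0) << 4)
        first -= (first >= 2048) * 4096  # sign-extend 12 bits
        second -= (second >= 2048) * 4096
        data = np.empty(n_pairs * 2, dtype=np.int64)
        data[0::2] = first
        data[1::2] = second
        data = data[:total]
    else:
        raise IOFormatError(f"unsupported signal format {fmt} in {path!r}")
    if data.size < total:
        raise IOFormatError(
            f"signal file {path!r} too short: {data.size} < {total} samples"
        )
    return data.reshape(n_samples, n_signals)


def read_signal(header_path: str) -> tuple[RecordHeader, np.ndarray]:
    """Read a record's signals in physical units (mV).

    Returns the parsed header and an (n_samples, n_signals) float array.
    All signals must live in a single .dat file (true of MIT-BIH and of
    everything this package writes).
    """
    hdr = read_header(header_path)
    base = os.path.dirname(header_path)
    dat_names = {s.file_name for s in hdr.signals}
    if len(dat_names) != 1:
        raise IOFormatError("multi-file records are not supported")
    fmts = {s.fmt for s in hdr.signals}
    if len(fmts) != 1:
        raise IOFormatError("mixed signal formats are not supported")
    dat_path = os.path.join(base, dat_names.pop())
    adc = _read_dat(dat_path, fmts.pop(), hdr.n_signals, hdr.n_samples)
    phys = np.empty(adc.shape, dtype=np.float64)
    for j, sig in enumerate(hdr.signals):
        phys[:, j] = (adc[:, j] - sig.baseline) / sig.gain
    return hdr, phys


def write_signal(
    directory: str,
    record_name: str,
    signals_mv: np.ndarray,
    sampling_rate: float,
    descriptions: list[str] | None = None,
    gain: float = 1_000_000.0,
) -> str:
    """Write a record (header + format-32 .dat); returns the header path."""
    sig = np.atleast_2d(np.asarray(signals_mv, dtype=np.float64))
    if sig.shape[0] < sig.shape[1]:  # accept (n_signals, n_samples) too
        sig = sig.T
    n_samples, n_signals = sig.shape
    if descriptions is None:
        descriptions = [f"lead{j}" for j in range(n_signals)]
    adc = np.rint(sig * gain).astype(np.int64)
    if np.abs(adc).max(initial=0) > 2**31 - 1:
        raise IOFormatError("signal amplitude overflows format 32 at this gain")
    os.makedirs(directory, exist_ok=True)
    dat_name = f"{record_name}.dat"
    interleaved = adc.astype("<i4").reshape(-1)
    interleaved.tofile(os.path.join(directory, dat_name))
    hea_path = os.path.join(directory, f"{record_name}.hea")
    with open(hea_path, "w") as fh:
        fh.write(f"{record_name} {n_signals} {sampling_rate:g} {n_samples}\n")
        for j in range(n_signals):
            init = int(adc[0, j]) if n_samples else 0
            fh.write(
                f"{dat_name} 32 {gain:g}(0)/mV 32 0 {init} 0 0 {descriptions[j]}\n"
            )
    return hea_path


def read_annotation_file(path: str) -> list[tuple[int, str]]:
    """Read a MIT-format annotation file → [(sample_index, symbol), ...].

    All annotation types are returned, including non-beat markers; filtering
    is the caller's concern.
    """
    try:
        words = np.fromfile(path, dtype="<u2").astype(np.int64)
    except OSError as exc:
        raise IOFormatError(f"cannot read annotation file {path!r}: {exc}") from exc
    out: list[tuple[int, str]] = []
    time = 0
    i = 0
    n = len(words)
    while i < n:
        word = int(words[i])
        code = word >> 10
        inc = word & 0x3FF
        i += 1
        if code == 0 and inc == 0:
            break
        if code == _SKIP:
            if i + 1 >= n:
                raise IOFormatError(f"truncated SKIP in {path!r}")
            # 4-byte interval, high 16 bits first (PDP-11 order)
            interval = (int(words[i]) << 16) | int(words[i + 1])
            if interval >= 2**31:
                interval -= 2**32
            time += interval
            i += 2
        elif code == _AUX:
            i += (inc + 1) // 2  # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            time += inc
            symbol = CODE_TO_SYMBOL.get(code)
            if symbol is None:
                raise IOFormatError(f"unknown annotation code {code} in {path!r}")
            out.append((time, symbol))
    return out


def write_annotation_file(path: str, annotations: list[tuple[int, str]]) -> None:
    """Write (sample_index, symbol) pairs in MIT annotation format."""
    words: list[int] = []
    prev = 0
    for sample, symbol in annotations:
        code = SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise IOFormatError(f"symbol {symbol!r} has no WFDB annotation code")
        delta = sample - prev
        if delta < 0:
            raise IOFormatError("annotations must be sorted by sample index")
        if delta > 1023:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        prev = sample
    words.append(0)  # end marker
    np.asarray(words, dtype="<u2").tofile(path)
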