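"""Reading ECG records and cutting them into fixed-length or annotation-centered fragments.

Two on-disk formats are supported:

* the two-column CSV dialect written by :mod:`shockscale.synth_ecg` / the CLI
  (``time_s,mV`` with a header line), and
* WFDB records (PhysioNet ``.hea``/``.dat`` pairs, signal formats 16 and 212,
  plus MIT-format ``.atr`` annotation files), via a self-contained reader.

All coordinates are 0-based sample indices; windows are half-open
``[start, start + W)``.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from shockscale.types import ECGFragment, SignalRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_fragment_csv(frag: ECGFragment, path: str | Path) -> None:
    """Write one fragment as a two-column ``time_s,mV`` CSV with header."""
    df = pd.DataFrame({"time_s": frag.times, "mV": frag.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def _read_csv_record(path: Path) -> SignalRecord:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unreadable CSV file {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"CSV {path} must have at least 2 columns (time, mV)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"cannot infer sampling rate from a single-row CSV {path}")
    if np.any(dt <= 0):
        raise ValueError(f"non-monotone time column in {path}")
    fs = 1.0 / float(np.median(dt))
    if not np.isfinite(fs) or fs <= 0:
        raise ValueError(f"sampling-rate inference failed for {path}")
    return SignalRecord(samples=x, fs=fs, name=path.stem)


# ---------------------------------------------------------------------------
# WFDB (.hea / .dat / .atr)
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            gfield = tok[2]
            if "(" in gfield:
                gfield, rest = gfield.split("(", 1)
                baseline = int(rest.split(")")[0])
            gfield = gfield.split("/")[0]
            g = float(gfield)
            if g != 0:
                gain = g
        sig_specs.append({"file": tok[0], "fmt": int(fmt), "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samp, sig_specs


def _read_dat(dat_path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Return raw ADC integers with shape (n_samples, n_sig)."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = len(data) // n_sig
        return data[: n * n_sig].reshape(n, n_sig).astype(np.int32)
    if fmt == 212:
        # packed 12-bit pairs: 3 bytes hold two samples
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = len(b) // 3
        b = b[: n_triplets * 3].reshape(n_triplets, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        pairs = np.column_stack([s1, s2]).ravel()
        pairs = np.where(pairs > 2047, pairs - 4096, pairs)  # 12-bit two's complement
        n = len(pairs) // n_sig
        return pairs[: n * n_sig].reshape(n, n_sig)
    raise ValueError(f"unsupported WFDB signal format {fmt} (supported: 16, 212)")


def read_annotations(atr_path: str | Path) -> list[tuple[int, str]]:
    """Parse a MIT-format annotation file into ``(sample_index, symbol)`` pairs."""
    raw = Path(atr_path).read_bytes()
    anns: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        lo, hi = raw[i], raw[i + 1]
        i += 2
        code = hi >> 2
        interval = ((hi & 0x03) << 8) | lo
        if code == 0 and interval == 0:  # EOF
            break
        if code == 59:  # SKIP: next 4 bytes are a long interval
            if i + 4 > len(raw):
                break
            (high_word,) = struct.unpack("<H", raw[i : i + 2])
            (low_word,) = struct.unpack("<H", raw[i + 2 : i + 4])
            t += (high_word << 16) | low_word
            i += 4
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers: ignored
            continue
        elif code == 63:  # AUX: interval = byte count, padded to even
            i += interval + (interval & 1)
        else:
            t += interval
            anns.append((t, _ANN_SYMBOLS.get(code, "?")))
    return anns


#: MIT annotation code -> display symbol (subset sufficient for beat labels).
_ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 38: "f", 31: "~",
    28: "+", 37: "!", 32: "|", 33: "[", 34: "]",
}
_ANN_CODES = {v: k for k, v in _ANN_SYMBOLS.items()}


def write_annotations(atr_path: str | Path, anns: list[tuple[int, str]]) -> None:
    """Write ``(sample_index, symbol)`` pairs as a MIT-format annotation file."""
    out = bytearray()
    prev = 0
    for idx, sym in anns:
        interval = idx - prev
        code = _ANN_CODES.get(sym, 13)
        while interval > 1023:
            chunk = min(interval, (1 << 31) - 1)
            out += bytes([0, 59 << 2])
            out += struct.pack("<H", chunk >> 16) + struct.pack("<H", chunk & 0xFFFF)
            interval -= chunk
        out += bytes([interval & 0xFF, (code << 2) | ((interval >> 8) & 0x03)])
        prev = idx
    out += bytes([0, 0])
    Path(atr_path).write_bytes(bytes(out))


def _read_wfdb_record(path: Path, channel: int) -> SignalRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise ValueError(f"WFDB header {hea} not found")
    name, n_sig, fs, _, specs = _parse_header(hea)
    dat = hea.parent / specs[channel]["file"]
    if not dat.exists():
        raise ValueError(f"WFDB signal file {dat} not found")
    fmt = specs[0]["fmt"]
    raw = _read_dat(dat, fmt, n_sig)
    if n_sig > 1:
        logger.info("record %s has %d channels; selecting channel %d", name, n_sig, channel)
    spec = specs[channel]
    samples = (raw[:, channel] - spec["baseline"]) / spec["gain"]
    atr = hea.with_suffix(".atr")
    annotations = read_annotations(atr) if atr.exists() else []
    annotations = [(i, s) for i, s in annotations if 0 <= i < len(samples)]
    return SignalRecord(samples=samples, fs=fs, annotations=annotations, name=name)


def read_record(path: str | Path, format: str | None = None, channel: int = 0) -> SignalRecord:
    """Read a signal record from CSV or a WFDB header/signal pair.

    ``format`` is ``"csv"`` or ``"wfdb"``; when ``None`` it is inferred from
    the file suffix.  For multi-channel WFDB records channel ``channel``
    (default 0) is selected and the choice is logged.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path, channel)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'wfdb')")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_fixed(rec: SignalRecord, window_s: float, stride_s: float) -> list[ECGFragment]:
    """Cut a record into fixed-length windows.

    Windows are contiguous slices ``[k*S, k*S + W)`` with ``W=round(window_s*fs)``
    and ``S=round(stride_s*fs)``; a trailing partial window is dropped.  Returns
    an empty list (logged) if the record is shorter than one window.
    """
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    W = int(round(window_s * rec.fs))
    S = int(round(stride_s * rec.fs))
    if W < 2:
        raise ValueError("window must span at least 2 samples")
    N = len(rec.samples)
    if N < W:
        logger.info("record %s (%d samples) shorter than window (%d): no fragments", rec.name, N, W)
        return []
    count = (N - W) // S + 1
    return [
        ECGFragment(
            samples=rec.samples[k * S : k * S + W].copy(),
            fs=rec.fs,
            id=f"{rec.name or 'rec'}-w{k:05d}",
        )
        for k in range(count)
    ]


def segment_around_annotations(rec: SignalRecord, window_s: float) -> list[ECGFragment]:
    """One window per annotation, centered on the annotated sample.

    ``W = round(window_s * fs)``; the annotated sample sits at offset
    ``floor(W/2)`` (ties toward earlier samples for even ``W``).  Annotations
    whose window would cross the record bounds are skipped and counted in the
    log.
    """
    if not rec.annotations:
        raise ValueError("record has no annotations to segment around")
    W = int(round(window_s * rec.fs))
    half = W // 2
    N = len(rec.samples)
    frags: list[ECGFragment] = []
    skipped = 0
    for idx, sym in rec.annotations:
        start = idx - half
        if start < 0 or start + W > N:
            skipped += 1
            continue
        frags.append(
            ECGFragment(
                samples=rec.samples[start : start + W].copy(),
                fs=rec.fs,
                label=None,
                id=f"{rec.name or 'rec'}-a{idx:08d}-{sym}",
            )
        )
    if skipped:
        logger.info("skipped %d annotation(s) whose window crossed record bounds", skipped)
    return frags
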