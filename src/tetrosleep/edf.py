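"""Minimal EDF I/O and 30-s epoch slicing.

Implements the classic 16-bit EDF layout (ASCII header, per-signal header
blocks, interleaved int16 data records) — enough to round-trip
single-channel polysomnography excerpts and to read user-supplied
recordings.  Stage annotations come from a plain-text sidecar with one
``onset_seconds stage`` pair per line; R&K stage-label dialects are
normalized via :data:`STAGE_ALIASES` and MT (movement) or unknown labels
are dropped with a warning.

A requested bipolar channel such as ``F4-C4`` that is not recorded is
derived as the sample-wise difference of the two referenced channels when
both exist at the same sampling rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ChannelError, FormatError, InvalidInputError

__all__ = ["EpochSet", "STAGE_ALIASES", "write_edf", "read_edf", "load_edf_epochs"]

logger = logging.getLogger(__name__)

#: normalization of stage-label dialects to the six canonical classes
STAGE_ALIASES = {
    "W": {"w", "wake", "wk", "0", "sleep stage w", "sleep stage 0"},
    "S1": {"s1", "n1", "1", "sleep stage 1", "sleep stage n1", "stage 1"},
    "S2": {"s2", "n2", "2", "sleep stage 2", "sleep stage n2", "stage 2"},
    "S3": {"s3", "n3", "3", "sleep stage 3", "sleep stage n3", "stage 3"},
    "S4": {"s4", "4", "sleep stage 4", "stage 4"},
    "REM": {"r", "rem", "5", "sleep stage r", "sleep stage rem", "stage r"},
}

_EXCLUDED = {"mt", "movement", "sleep stage ?", "?"}


def normalize_stage(label: str) -> str | None:
    """Map a stage-label dialect to its canonical class, or None to drop."""
    key = label.strip().lower()
    for canon, aliases in STAGE_ALIASES.items():
        if key == canon.lower() or key in aliases:
            return canon
    if key not in _EXCLUDED:
        logger.warning("unknown stage label %r dropped", label)
    return None


@dataclass
class EpochSet:
    """Labeled 30-s epochs cut from one recording channel."""

    epochs: list
    labels: list
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise InvalidInputError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _num(value, width: int) -> bytes:
    text = f"{value:.10g}"[:width] if isinstance(value, float) else str(value)
    return _pad(text, width)


def write_edf(path, channels: dict, sampling_rate: float, record_seconds: float = 1.0) -> None:
    """Write channels (name -> 1-D array) as a 16-bit EDF file.

    All channels share one sampling rate; the total length must be a whole
    number of ``record_seconds`` records.
    """
    names = list(channels)
    if not names:
        raise InvalidInputError("no channels to write")
    arrays = [np.asarray(channels[n], dtype=float) for n in names]
    length = arrays[0].size
    if any(a.ndim != 1 or a.size != length for a in arrays):
        raise InvalidInputError("all channels must be 1-D and equally long")
    spr = sampling_rate * record_seconds
    if abs(spr - round(spr)) > 1e-9:
        raise InvalidInputError("samples per record must be integral")
    spr = int(round(spr))
    if length % spr:
        raise InvalidInputError(
            f"signal length {length} is not a whole number of {record_seconds}-s records"
        )
    n_records = length // spr
    ns = len(names)

    phys_min, phys_max, digitized = [], [], []
    for a in arrays:
        lo, hi = float(a.min()), float(a.max())
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        dig = np.round((a - lo) / (hi - lo) * 65535.0 - 32768.0).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        digitized.append(dig)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic", 80),
            _pad("tetrosleep export", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _num(256 * (1 + ns), 8),
            _pad("", 44),
            _num(n_records, 8),
            _num(float(record_seconds), 8),
            _num(ns, 4),
        ]
    )
    fields = [
        b"".join(_pad(n[:16], 16) for n in names),
        b"".join(_pad("", 80) for _ in names),
        b"".join(_pad("uV", 8) for _ in names),
        b"".join(_num(v, 8) for v in phys_min),
        b"".join(_num(v, 8) for v in phys_max),
        b"".join(_pad("-32768", 8) for _ in names),
        b"".join(_pad("32767", 8) for _ in names),
        b"".join(_pad("", 80) for _ in names),
        b"".join(_num(spr, 8) for _ in names),
        b"".join(_pad("", 32) for _ in names),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for blob in fields:
            fh.write(blob)
        for rec in range(n_records):
            for dig in digitized:
                fh.write(dig[rec * spr : (rec + 1) * spr].tobytes())


def read_edf(path):
    """Read an EDF file; returns ``{channel: (samples, sampling_rate)}``.

    Annotation pseudo-channels are skipped.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: too short to be an EDF file")

    def ascii_at(start, width):
        return raw[start : start + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(ascii_at(236, 8))
        duration = float(ascii_at(244, 8))
        ns = int(ascii_at(252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
    base = 256
    block = {
        "label": (0, 16),
        "phys_min": (16 * ns + 80 * ns + 8 * ns, 8),
        "phys_max": (16 * ns + 80 * ns + 8 * ns + 8 * ns, 8),
        "dig_min": (16 * ns + 80 * ns + 3 * 8 * ns, 8),
        "dig_max": (16 * ns + 80 * ns + 4 * 8 * ns, 8),
        "spr": (16 * ns + 80 * ns + 5 * 8 * ns + 80 * ns, 8),
    }

    def field_values(name, cast):
        off, width = block[name]
        return [cast(ascii_at(base + off + i * width, width)) for i in range(ns)]

    try:
        labels = field_values("label", str)
        phys_min = field_values("phys_min", float)
        phys_max = field_values("phys_max", float)
        dig_min = field_values("dig_min", int)
        dig_max = field_values("dig_max", int)
        spr = field_values("spr", int)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF signal header: {exc}") from exc

    data_start = 256 * (1 + ns)
    record_words = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", offset=data_start)
    if data.size < n_records * record_words:
        raise FormatError(f"{path}: truncated EDF data section")
    data = data[: n_records * record_words].reshape(n_records, record_words)

    out = {}
    offset = 0
    for i, name in enumerate(labels):
        chunk = data[:, offset : offset + spr[i]].reshape(-1).astype(float)
        offset += spr[i]
        if "annotation" in name.lower():
            continue
        dig_rng = dig_max[i] - dig_min[i]
        if dig_rng <= 0 or phys_max[i] == phys_min[i]:
            raise FormatError(f"{path}: channel {name!r} has a degenerate scaling range")
        gain = (phys_max[i] - phys_min[i]) / dig_rng
        out[name] = (phys_min[i] + (chunk - dig_min[i]) * gain, spr[i] / duration)
    return out


def _resolve_channel(channels: dict, wanted: str):
    for name in channels:
        if name.strip().lower() == wanted.strip().lower():
            return channels[name]
    if "-" in wanted:
        left, right = (part.strip() for part in wanted.split("-", 1))
        have = {n.strip().lower(): n for n in channels}
        if left.lower() in have and right.lower() in have:
            sig_l, fs_l = channels[have[left.lower()]]
            sig_r, fs_r = channels[have[right.lower()]]
            if fs_l != fs_r:
                raise FormatError(
                    f"cannot derive {wanted!r}: sampling rates differ ({fs_l} vs {fs_r} Hz)"
                )
            n = min(sig_l.size, sig_r.size)
            return sig_l[:n] - sig_r[:n], fs_l
    raise ChannelError(
        f"channel {wanted!r} not found and not derivable; available: {sorted(channels)}"
    )


def read_annotations(path):
    """Parse the two-column ``onset_seconds stage`` sidecar."""
    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'onset_seconds stage'")
        try:
            onset = float(parts[0])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad onset {parts[0]!r}") from exc
        entries.append((onset, parts[1].strip()))
    return entries


def load_edf_epochs(edf_path, annotation_path, channel: str, epoch_seconds: float = 30.0) -> EpochSet:
    """Cut annotation-aligned labeled epochs from one EDF channel.

    One epoch per annotated 30-s window; windows with excluded (MT) or
    unknown labels, or extending past the recording end, are dropped.
    """
    channels = read_edf(edf_path)
    signal, fs = _resolve_channel(channels, channel)
    samples = int(round(fs * epoch_seconds))
    epochs, labels, provenance = [], [], []
    for onset, raw_label in read_annotations(annotation_path):
        stage = normalize_stage(raw_label)
        if stage is None:
            continue
        start = int(round(onset * fs))
        if start < 0 or not math.isclose(onset * fs, start, abs_tol=1e-6):
            logger.warning("onset %.3f s not sample-aligned; rounded", onset)
        stop = start + samples
        if stop > signal.size:
            logger.warning("epoch at %.1f s runs past the recording end; dropped", onset)
            continue
        epochs.append(signal[start:stop])
        labels.append(stage)
        provenance.append(
            {"recording": str(edf_path), "channel": channel, "onset_seconds": onset}
        )
    if not epochs:
        logger.warning("no usable labeled epochs in %s", annotation_path)
    return EpochSet(epochs=epochs, labels=labels, provenance=provenance)
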