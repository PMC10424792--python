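"""Packet framing, serialization and reassembly for belt/oximeter streams.

The acquisition gateway splits each device's sample stream into fixed-size
packets, stamps them, and ships them as JSON.  This module frames sample
arrays into such packets, writes/reads them losslessly, reassembles a
contiguous :class:`Recording` (flagging gaps left by lost packets), and
quantifies packet loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PacketBatch",
    "Recording",
    "QUALITY_OK",
    "QUALITY_MISSING",
    "QUALITY_REPAIRED",
    "frame_packets",
    "write_packets",
    "read_packets",
    "assemble",
    "packet_loss_ratio",
]

DEVICE_KINDS = ("belt", "oximeter")

# per-sample quality codes carried by Recording.quality
QUALITY_OK = 0
QUALITY_MISSING = 1
QUALITY_REPAIRED = 2

_PACKET_KEYS = {
    "device_id",
    "device_kind",
    "seq",
    "fs_hz",
    "t_start_ms",
    "t_transfer_ms",
    "samples",
}


@dataclass
class PacketBatch:
    """One fixed-size chunk of samples from a single device.

    ``t_start_ms`` is the epoch-millisecond timestamp of the first sample;
    ``t_transfer_ms`` the time the gateway shipped the packet (never earlier
    than ``t_start_ms``).
    """

    device_id: str
    device_kind: str
    seq: int
    fs_hz: float
    t_start_ms: int
    t_transfer_ms: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.device_kind not in DEVICE_KINDS:
            raise ValueError(f"unknown device_kind {self.device_kind!r}")
        if self.seq < 0:
            raise ValueError("seq must be non-negative")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.t_transfer_ms < self.t_start_ms:
            raise ValueError("t_transfer_ms must be >= t_start_ms")
        self.samples = np.asarray(self.samples, dtype=float)

    def to_dict(self) -> dict:
        return {
            "device_id": self.device_id,
            "device_kind": self.device_kind,
            "seq": int(self.seq),
            "fs_hz": float(self.fs_hz),
            "t_start_ms": int(self.t_start_ms),
            "t_transfer_ms": int(self.t_transfer_ms),
            "samples": [float(v) for v in self.samples],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PacketBatch":
        missing = _PACKET_KEYS - set(d)
        if missing:
            raise ValueError(f"packet object missing keys: {sorted(missing)}")
        return cls(
            device_id=str(d["device_id"]),
            device_kind=str(d["device_kind"]),
            seq=int(d["seq"]),
            fs_hz=float(d["fs_hz"]),
            t_start_ms=int(d["t_start_ms"]),
            t_transfer_ms=int(d["t_transfer_ms"]),
            samples=np.asarray(d["samples"], dtype=float),
        )


@dataclass
class Recording:
    """A contiguous single-device sample series with a per-sample quality mask.

    ``quality[i]`` is one of ``QUALITY_OK``, ``QUALITY_MISSING`` (gap left by
    a lost packet, filled with 0 — downstream code must consult the mask,
    never the fill value) or ``QUALITY_REPAIRED`` (interpolated during
    preprocessing).
    """

    subject_id: str
    device_kind: str
    fs_hz: float
    t0_ms: int
    samples: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.quality is None:
            self.quality = np.zeros(len(self.samples), dtype=np.uint8)
        else:
            self.quality = np.asarray(self.quality, dtype=np.uint8)
        if len(self.quality) != len(self.samples):
            raise ValueError("quality mask length must match samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def copy(self) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            device_kind=self.device_kind,
            fs_hz=self.fs_hz,
            t0_ms=self.t0_ms,
            samples=self.samples.copy(),
            quality=self.quality.copy(),
        )


def frame_packets(
    samples: Sequence[float],
    fs_hz: float,
    packet_size: int,
    t0_ms: int = 0,
    device_id: str = "dev0",
    device_kind: str = "belt",
) -> list[PacketBatch]:
    """Split a sample stream into equal-size sequenced packets.

    A trailing remainder shorter than ``packet_size`` is dropped, so the
    concatenation of the returned packets reproduces the input truncated to
    a multiple of ``packet_size``.
    """
    if packet_size < 1:
        raise ValueError("packet_size must be >= 1")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    samples = np.asarray(samples, dtype=float)
    n_packets = len(samples) // packet_size
    packets = []
    for k in range(n_packets):
        t_start = t0_ms + round(k * packet_size * 1000.0 / fs_hz)
        t_end = t0_ms + round((k + 1) * packet_size * 1000.0 / fs_hz)
        packets.append(
            PacketBatch(
                device_id=device_id,
                device_kind=device_kind,
                seq=k,
                fs_hz=fs_hz,
                t_start_ms=t_start,
                t_transfer_ms=t_end,
                samples=samples[k * packet_size : (k + 1) * packet_size],
            )
        )
    return packets


def write_packets(packets: Iterable[PacketBatch], destination: str | Path) -> None:
    """Write packets as newline-delimited JSON, one object per packet."""
    destination = Path(destination)
    with destination.open("w") as fh:
        for p in packets:
            fh.write(json.dumps(p.to_dict()) + "\n")


def read_packets(source: str | Path) -> list[PacketBatch]:
    """Read packets from NDJSON or a top-level JSON array.

    Raises ``ValueError`` naming the offending packet index on malformed
    content.
    """
    source = Path(source)
    text = source.read_text().strip()
    if not text:
        return []
    if text[0] == "[":
        objs = json.loads(text)
    else:
        objs = []
        for line in text.splitlines():
            line = line.strip()
            if line:
                objs.append(json.loads(line))
    packets = []
    for i, obj in enumerate(objs):
        try:
            packets.append(PacketBatch.from_dict(obj))
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"malformed packet at index {i} in {source}: {exc}") from exc
    return packets


def assemble(packets: Sequence[PacketBatch], subject_id: str | None = None) -> Recording:
    """Reassemble packets into a Recording, flagging lost-packet gaps.

    Packets are ordered by sequence number; duplicates keep the first
    occurrence; gaps are filled with 0 and flagged ``QUALITY_MISSING``.
    """
    if not packets:
        raise ValueError("cannot assemble an empty packet list")
    first = packets[0]
    size = len(first.samples)
    for p in packets:
        if (
            p.device_id != first.device_id
            or p.device_kind != first.device_kind
            or p.fs_hz != first.fs_hz
            or len(p.samples) != size
        ):
            raise ValueError("conflicting device metadata or packet geometry")
    by_seq: dict[int, PacketBatch] = {}
    for p in sorted(packets, key=lambda p: p.seq):
        by_seq.setdefault(p.seq, p)  # duplicates: keep first occurrence
    seqs = sorted(by_seq)
    seq0, seq_last = seqs[0], seqs[-1]
    n_slots = seq_last - seq0 + 1
    samples = np.zeros(n_slots * size, dtype=float)
    quality = np.full(n_slots * size, QUALITY_MISSING, dtype=np.uint8)
    for s in seqs:
        sl = slice((s - seq0) * size, (s - seq0 + 1) * size)
        samples[sl] = by_seq[s].samples
        quality[sl] = QUALITY_OK
    return Recording(
        subject_id=subject_id if subject_id is not None else first.device_id,
        device_kind=first.device_kind,
        fs_hz=first.fs_hz,
        t0_ms=by_seq[seq0].t_start_ms,
        samples=samples,
        quality=quality,
    )


def packet_loss_ratio(expected: int, received: int) -> float:
    """Fraction of expected packets that never arrived."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    if not 0 <= received <= expected:
        raise ValueError("received must lie in [0, expected]")
    return (expected - received) / expected
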