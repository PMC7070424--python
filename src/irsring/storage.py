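"""Emulation of the 8 MiB EEProm event store with wear-leveled addressing.

Detections are stored as fixed-width 32-byte records written strictly
sequentially through the whole address space; an address is only reused
once every address has been written in the current cycle, so flash wear
stays uniformly distributed.  With 32-byte records an 8 MiB part holds
262,144 events — comfortably more than 500 detections per day for half a
year before anything is overwritten.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detector import DetectionEvent
from .geometry import Variant

__all__ = [
    "RECORD_WIDTH",
    "EncodingError",
    "encode_record",
    "decode_record",
    "RingStore",
    "sustained_daily_capacity",
]

RECORD_WIDTH = 32
# timestamp u32 | variant u8 | pad u8 | ST u16 | mask u16 | n u16 | span u16 |
# start u32 | raw_sum u32 | normalized u32 | 6 reserved bytes
_CODEC = struct.Struct("<IBBHHHHIII6x")
assert _CODEC.size == RECORD_WIDTH

_VARIANT_CODE = {Variant.IRSR1: 1, Variant.IRSR2: 2}
_CODE_VARIANT = {v: k for k, v in _VARIANT_CODE.items()}


class EncodingError(ValueError):
    """An event field does not fit the fixed-width record layout."""


def encode_record(event: DetectionEvent, timestamp: int,
                  variant: Variant = Variant.IRSR1) -> bytes:
    """Encode one detection into the fixed 32-byte little-endian record."""
    fields = {
        "timestamp": (timestamp, 1 << 32),
        "threshold": (event.threshold_used, 1 << 16),
        "channel_mask": (event.channel_mask, 1 << 16),
        "n_samples": (event.n_samples, 1 << 16),
        "span_samples": (event.span_samples, 1 << 16),
        "start_index": (event.start_index, 1 << 32),
        "raw_sum": (event.raw_sum, 1 << 32),
        "normalized_amplitude": (event.normalized_amplitude, 1 << 32),
    }
    for name, (value, limit) in fields.items():
        if not 0 <= int(value) < limit:
            raise EncodingError(f"{name}={value} does not fit the record layout")
    return _CODEC.pack(int(timestamp), _VARIANT_CODE[Variant(variant)], 0,
                       event.threshold_used, event.channel_mask,
                       event.n_samples, event.span_samples,
                       event.start_index, event.raw_sum,
                       event.normalized_amplitude)


def decode_record(data: bytes) -> tuple[DetectionEvent, int, Variant]:
    """Inverse of :func:`encode_record`."""
    if len(data) != RECORD_WIDTH:
        raise EncodingError(f"record must be exactly {RECORD_WIDTH} bytes")
    (ts, vcode, _pad, st, mask, n, span, start, raw, norm) = _CODEC.unpack(data)
    event = DetectionEvent(channel_mask=mask, start_index=start, n_samples=n,
                           span_samples=span, raw_sum=raw,
                           normalized_amplitude=norm, threshold_used=st)
    return event, ts, _CODE_VARIANT[vcode]


@dataclass
class RingStore:
    """Cyclic wear-leveled record store.

    Writes advance one slot at a time through the whole capacity and wrap
    to the lowest address only after every slot of the cycle has been
    used, overwriting the oldest record by design.
    """

    capacity: int = 8 * 1024 * 1024  # 8 MiB
    record_width: int = RECORD_WIDTH

    def __post_init__(self) -> None:
        if self.capacity < self.record_width:
            raise ValueError("capacity smaller than one record")
        self._buf = bytearray(self.slot_count * self.record_width)
        self._write_counts = np.zeros(self.slot_count, dtype=np.uint32)
        self.total_writes = 0

    @property
    def slot_count(self) -> int:
        return self.capacity // self.record_width

    @property
    def write_pointer(self) -> int:
        """Next slot to be written."""
        return self.total_writes % self.slot_count

    @property
    def wrap_count(self) -> int:
        return self.total_writes // self.slot_count

    def store(self, record: bytes) -> "RingStore":
        if len(record) != self.record_width:
            raise EncodingError("record width does not match the store layout")
        slot = self.write_pointer
        off = slot * self.record_width
        self._buf[off:off + self.record_width] = record
        self._write_counts[slot] += 1
        self.total_writes += 1
        return self

    def store_event(self, event: DetectionEvent, timestamp: int,
                    variant: Variant = Variant.IRSR1) -> "RingStore":
        return self.store(encode_record(event, timestamp, variant))

    def slot_write_counts(self) -> np.ndarray:
        return self._write_counts.copy()

    def read_records(self) -> list[bytes]:
        """The newest ``min(total_writes, slot_count)`` records, oldest first."""
        n_valid = min(self.total_writes, self.slot_count)
        start = (self.total_writes - n_valid) % self.slot_count
        out = []
        for k in range(n_valid):
            slot = (start + k) % self.slot_count
            off = slot * self.record_width
            out.append(bytes(self._buf[off:off + self.record_width]))
        return out

    def read_events(self) -> list[tuple[DetectionEvent, int, Variant]]:
        return [decode_record(r) for r in self.read_records()]

    def dump(self, path) -> None:
        """Raw image of the store (binary scratch output)."""
        with open(path, "wb") as fh:
            fh.write(bytes(self._buf))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for event, ts, variant in self.read_events():
            rows.append({"timestamp": ts, "variant": variant.value,
                         "ST": event.threshold_used,
                         "channel_mask_hex": f"{event.channel_mask:04x}",
                         "start_index": event.start_index,
                         "n_samples": event.n_samples,
                         "duration_samples": event.span_samples,
                         "raw_sum": event.raw_sum,
                         "normalized_amplitude": event.normalized_amplitude})
        return pd.DataFrame(rows)


def sustained_daily_capacity(days: float = 183.0,
                             capacity: int = 8 * 1024 * 1024,
                             record_width: int = RECORD_WIDTH) -> float:
    """Detections per day the store can hold for ``days`` days before any
    overwrite (the half-year storage budget of the instrument)."""
    return (capacity // record_width) / days
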