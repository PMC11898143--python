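"""Binary telemetry packet codec.

Wire layout (big-endian throughout):

    magic 0xA5 (1B) | version (1B) | node_id (u16) | slot (u16)
    | window_start (u32, epoch seconds) | presence bitmap (u16,
    bit i = channel i in CHANNEL_ORDER) | per present channel:
    avg, min, max as signed 16-bit fixed point | CRC-16/CCITT (2B)

Fixed-point scales per channel: temp and RH and the electrochemical
gases x100, sound and PM x10, everything else x1. Values are saturated
to the int16 range on encode, so the codec is the identity on the
quantized, representable domain (illuminance above 32,767 lux
saturates).
"""

from __future__ import annotations

import struct

from .channels import CHANNEL_ORDER
from .node_sim import ChannelStats, PacketRecord

MAGIC = 0xA5
VERSION = 1
HEADER = struct.Struct(">BBHHIH")  # magic, version, node_id, slot, window_start, bitmap

#: fixed-point scale per channel
SCALE = {"temp": 100, "rh": 100, "sound": 10, "lux": 1, "h2s": 100,
         "nh3": 100, "co2": 1, "voc": 1, "nox": 1,
         "pm1": 10, "pm25": 10, "pm4": 10, "pm10": 10}

I16_MIN, I16_MAX = -32768, 32767


class CodecError(ValueError):
    """Base class for packet decoding failures."""


class BadMagic(CodecError):
    pass


class BadChecksum(CodecError):
    pass


class Truncated(CodecError):
    pass


def crc16_ccitt(data: bytes, init: int = 0xFFFF) -> int:
    """CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF, no reflection)."""
    crc = init
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ 0x1021) if crc & 0x8000 else (crc << 1)
            crc &= 0xFFFF
    return crc


def quantize(value: float, channel: str) -> int:
    q = round(value * SCALE[channel])
    return min(max(q, I16_MIN), I16_MAX)


def dequantize(raw: int, channel: str) -> float:
    return raw / SCALE[channel]


def encode_packet(record: PacketRecord) -> bytes:
    """Serialize a PacketRecord into the binary wire format."""
    bitmap = 0
    payload = b""
    for i, ch in enumerate(CHANNEL_ORDER):
        if ch in record.stats:
            bitmap |= 1 << i
            s = record.stats[ch]
            payload += struct.pack(">hhh", quantize(s.avg, ch),
                                   quantize(s.min, ch), quantize(s.max, ch))
    head = HEADER.pack(MAGIC, VERSION, record.node_id, record.slot,
                       record.window_start, bitmap)
    body = head + payload
    return body + struct.pack(">H", crc16_ccitt(body))


def decode_packet(buf: bytes) -> PacketRecord:
    """Parse and checksum-validate a binary packet."""
    if len(buf) < HEADER.size + 2:
        raise Truncated(f"buffer of {len(buf)} bytes is shorter than header + CRC")
    magic, version, node_id, slot, window_start, bitmap = HEADER.unpack_from(buf)
    if magic != MAGIC:
        raise BadMagic(f"bad magic 0x{magic:02X}")
    n_present = bin(bitmap).count("1")
    expected = HEADER.size + 6 * n_present + 2
    if len(buf) < expected:
        raise Truncated(f"expected {expected} bytes for {n_present} channels, got {len(buf)}")
    buf = buf[:expected]
    (crc,) = struct.unpack_from(">H", buf, expected - 2)
    if crc != crc16_ccitt(buf[:-2]):
        raise BadChecksum("CRC mismatch")
    stats: dict[str, ChannelStats] = {}
    off = HEADER.size
    for i, ch in enumerate(CHANNEL_ORDER):
        if bitmap & (1 << i):
            a, lo, hi = struct.unpack_from(">hhh", buf, off)
            off += 6
            stats[ch] = ChannelStats(dequantize(a, ch), dequantize(lo, ch),
                                     dequantize(hi, ch))
    return PacketRecord(node_id=node_id, slot=slot, window_start=window_start,
                        stats=stats)


def write_pkt(records, path) -> None:
    """Write packets to a ``.pkt`` file of length-prefixed records."""
    with open(path, "wb") as fh:
        for rec in records:
            blob = encode_packet(rec)
            fh.write(struct.pack(">H", len(blob)))
            fh.write(blob)


def read_pkt(path) -> list[PacketRecord]:
    """Read a length-prefixed ``.pkt`` file back into PacketRecords."""
    records = []
    with open(path, "rb") as fh:
        data = fh.read()
    off = 0
    while off < len(data):
        if off + 2 > len(data):
            raise Truncated("dangling length prefix")
        (length,) = struct.unpack_from(">H", data, off)
        off += 2
        if off + length > len(data):
            raise Truncated("record extends past end of file")
        records.append(decode_packet(data[off:off + length]))
        off += length
    return records
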