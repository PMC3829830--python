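"""Bit-level encoding for U3D block payloads.

ECMA-363 stores block payloads as a single bit stream that mixes plain
little-endian values with *compressed* unsigned integers.  Compression is
a 16-bit arithmetic coder driven by per-context symbol histograms:

* context 0 is reserved (plain values are written uncompressed),
* contexts 1 .. 0x3FF are **dynamic**: an adaptive histogram per context,
  with symbol 0 acting as the escape that precedes a raw literal for a
  value never seen before in this context,
* contexts 0x400+r (up to 0x400+0x3FFF) are **static**: a uniform
  distribution over the r values 0 .. r-1,
* static contexts above that range, and all floats, are written raw.

A value ``v`` is coded as symbol ``v + 1``; dynamic histograms cap their
total count (halving at 0x1FFF) and never track symbols >= 0xFFFF.  Bits
are packed least-significant-first into bytes, with the coder's bits
emitted most-significant-first, so plain byte-aligned data appears
verbatim in the payload.  Every ``BitWriter`` output is exactly
reproduced by a ``BitReader`` fed the same context sequence.

State resets per block: each payload gets a fresh writer/reader.
"""

from __future__ import annotations

import struct
from typing import Iterable, List, Sequence, Tuple

__all__ = ["Context", "BitWriter", "BitReader", "encode_values", "decode_values"]

_BITREV8 = bytes(int(f"{i:08b}"[::-1], 2) for i in range(256))

_ELEPHANT = 0x1FFF  # histogram total triggering a halving
_MAX_HISTOGRAM_SYMBOL = 0xFFFF


class Context:
    """Context identifiers for compressed values."""

    NOT_COMPRESSED = 0
    STATIC_FULL = 0x400
    MAX_RANGE = STATIC_FULL + 0x3FFF

    @staticmethod
    def static(value_range: int) -> int:
        """Static uniform context over values ``0 .. value_range - 1``.

        Ranges too large for the coder's 16-bit precision fall back to the
        uncompressed path automatically (context >= MAX_RANGE).
        """
        if value_range < 1:
            raise ValueError("static context needs a positive value range")
        return Context.STATIC_FULL + value_range

    @staticmethod
    def dynamic(index: int) -> int:
        if not (1 <= index < Context.STATIC_FULL):
            raise ValueError(f"dynamic context index must be in [1, 0x400): {index}")
        return index


class _ContextManager:
    """Per-context adaptive histograms (dynamic contexts only)."""

    def __init__(self) -> None:
        self._hist = {}  # context -> [counts]; index = symbol, 0 = escape

    def _counts(self, context: int) -> List[int]:
        c = self._hist.get(context)
        if c is None:
            c = [1]  # escape starts with frequency 1
            self._hist[context] = c
        return c

    def total(self, context: int) -> int:
        if context >= Context.STATIC_FULL:
            return context - Context.STATIC_FULL
        return sum(self._counts(context))

    def freq(self, context: int, symbol: int) -> int:
        if context >= Context.STATIC_FULL:
            return 1
        counts = self._counts(context)
        if symbol < len(counts):
            return counts[symbol]
        return 1 if symbol == 0 else 0

    def cum_freq(self, context: int, symbol: int) -> int:
        if context >= Context.STATIC_FULL:
            return symbol - 1
        counts = self._counts(context)
        return sum(counts[: min(symbol, len(counts))])

    def symbol_from_freq(self, context: int, cumulative: int) -> int:
        if context >= Context.STATIC_FULL:
            return cumulative + 1
        run = 0
        counts = self._counts(context)
        for symbol, c in enumerate(counts):
            if cumulative < run + c:
                return symbol
            run += c
        return 0  # unreachable for a well-formed stream

    def add(self, context: int, symbol: int) -> None:
        if context >= Context.STATIC_FULL or symbol >= _MAX_HISTOGRAM_SYMBOL:
            return
        counts = self._counts(context)
        if symbol >= len(counts):
            counts.extend([0] * (symbol + 1 - len(counts)))
        if sum(counts) >= _ELEPHANT:
            for i, c in enumerate(counts):
                counts[i] = c >> 1
            counts[0] = max(counts[0], 1)
        counts[symbol] += 1


class BitWriter:
    """Serializes mixed plain/compressed values into one block payload."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0
        self._low = 0
        self._high = 0xFFFF
        self._underflow = 0
        self._ctx = _ContextManager()

    # -- raw bit plumbing ---------------------------------------------------

    @property
    def _pristine(self) -> bool:
        return self._low == 0 and self._high == 0xFFFF and self._underflow == 0

    def _write_bit(self, bit: int) -> None:
        self._acc |= (bit & 1) << self._nbits
        self._nbits += 1
        if self._nbits == 8:
            self._buf.append(self._acc)
            self._acc = 0
            self._nbits = 0

    # -- arithmetic coder ---------------------------------------------------

    def _write_symbol(self, context: int, symbol: int) -> bool:
        """Code one symbol; returns True when the escape was emitted."""
        ctx = self._ctx
        escape = False
        freq = ctx.freq(context, symbol)
        if freq == 0:
            symbol = 0
            freq = ctx.freq(context, 0)
        if symbol == 0 and context < Context.STATIC_FULL:
            escape = True
        total = ctx.total(context)
        cum = ctx.cum_freq(context, symbol)
        low, high = self._low, self._high
        rng = high + 1 - low
        high = low - 1 + rng * (cum + freq) // total
        low = low + rng * cum // total
        if not escape:
            ctx.add(context, symbol)

        while True:
            if (high & 0x8000) == (low & 0x8000):
                bit = low >> 15
                self._write_bit(bit)
                while self._underflow:
                    self._underflow -= 1
                    self._write_bit(bit ^ 1)
            elif (low & 0x4000) and not (high & 0x4000):
                self._underflow += 1
                low ^= 0x4000
                high ^= 0x4000
            else:
                break
            low = (low << 1) & 0xFFFF
            high = ((high << 1) | 1) & 0xFFFF
        self._low, self._high = low, high
        return escape

    # -- plain values -------------------------------------------------------

    def write_u8(self, value: int) -> None:
        value &= 0xFF
        if self._pristine and self._nbits == 0:
            self._buf.append(value)  # identical to the coded bits, but fast
        else:
            self._write_symbol(Context.STATIC_FULL + 256, _BITREV8[value] + 1)

    def write_bytes(self, data: bytes) -> None:
        if self._pristine and self._nbits == 0:
            self._buf.extend(data)
        else:
            for b in data:
                self.write_u8(b)

    def write_u16(self, value: int) -> None:
        self.write_bytes(struct.pack("<H", value & 0xFFFF))

    def write_u32(self, value: int) -> None:
        self.write_bytes(struct.pack("<I", value & 0xFFFFFFFF))

    def write_u64(self, value: int) -> None:
        self.write_bytes(struct.pack("<Q", value))

    def write_i16(self, value: int) -> None:
        self.write_bytes(struct.pack("<h", value))

    def write_f32(self, value: float) -> None:
        self.write_bytes(struct.pack("<f", value))

    def write_f64(self, value: float) -> None:
        self.write_bytes(struct.pack("<d", value))

    def write_string(self, text: str) -> None:
        data = text.encode("utf-8")
        if len(data) > 0xFFFF:
            raise ValueError("string too long for U3D (max 65535 bytes)")
        self.write_u16(len(data))
        self.write_bytes(data)

    # -- compressed values --------------------------------------------------

    def _write_compressed(self, context: int, value: int, literal) -> None:
        if context == Context.NOT_COMPRESSED:
            raise ValueError("context 0 is reserved; use an explicit plain write")
        if context >= Context.MAX_RANGE:
            literal(value)
            return
        if context >= Context.STATIC_FULL and value + 1 > context - Context.STATIC_FULL:
            raise ValueError(
                f"value {value} outside static context range {context - Context.STATIC_FULL}"
            )
        if self._write_symbol(context, value + 1):
            literal(value)
            self._ctx.add(context, value + 1)

    def write_compressed_u32(self, context: int, value: int) -> None:
        self._write_compressed(context, value, self.write_u32)

    def write_compressed_u16(self, context: int, value: int) -> None:
        self._write_compressed(context, value, self.write_u16)

    def write_compressed_u8(self, context: int, value: int) -> None:
        self._write_compressed(context, value, self.write_u8)

    # -- finalization -------------------------------------------------------

    def getvalue(self) -> bytes:
        """Flush the coder and return the complete payload bytes."""
        if not self._pristine:
            # emit the disambiguating quarter bits (then the stream may be
            # zero-padded arbitrarily on the reader side)
            bit = (self._low >> 14) & 1
            self._underflow += 1
            self._write_bit(bit)
            while self._underflow:
                self._underflow -= 1
                self._write_bit(bit ^ 1)
            self._low, self._high = 0, 0xFFFF
        while self._nbits:
            self._write_bit(0)
        return bytes(self._buf)


class BitReader:
    """Decodes payloads produced by :class:`BitWriter`.

    The caller must request values in the same order and with the same
    contexts as the writer; the reader raises on reads past the end of
    plain data (coder refill bits beyond the end read as zero padding).
    """

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._bitpos = 0  # next raw bit for the coder window
        self._low = 0
        self._high = 0xFFFF
        self._underflow = 0  # mirrors the writer's deferred-bit counter
        self._code = 0
        self._window_valid = False
        self._ctx = _ContextManager()

    @property
    def _pristine(self) -> bool:
        return self._low == 0 and self._high == 0xFFFF and self._underflow == 0

    def _bit(self) -> int:
        byte_idx = self._bitpos >> 3
        if byte_idx >= len(self._data):
            self._bitpos += 1
            return 0  # zero padding past the end (flush slack)
        bit = (self._data[byte_idx] >> (self._bitpos & 7)) & 1
        self._bitpos += 1
        return bit

    def _fill_window(self) -> None:
        if not self._window_valid:
            code = 0
            for _ in range(16):
                code = (code << 1) | self._bit()
            self._code = code
            self._window_valid = True

    def _read_symbol(self, context: int) -> int:
        self._fill_window()
        ctx = self._ctx
        total = ctx.total(context)
        low, high, code = self._low, self._high, self._code
        rng = high + 1 - low
        cum_target = ((code - low + 1) * total - 1) // rng
        symbol = ctx.symbol_from_freq(context, cum_target)
        freq = ctx.freq(context, symbol)
        cum = ctx.cum_freq(context, symbol)
        high = low - 1 + rng * (cum + freq) // total
        low = low + rng * cum // total
        if not (symbol == 0 and context < Context.STATIC_FULL):
            ctx.add(context, symbol)

        while True:
            if (high & 0x8000) == (low & 0x8000):
                self._underflow = 0
            elif (low & 0x4000) and not (high & 0x4000):
                self._underflow += 1
                code ^= 0x4000
                low ^= 0x4000
                high ^= 0x4000
            else:
                break
            low = (low << 1) & 0xFFFF
            high = ((high << 1) | 1) & 0xFFFF
            code = ((code << 1) | self._bit()) & 0xFFFF
        self._low, self._high, self._code = low, high, code
        return symbol

    # -- plain values -------------------------------------------------------

    def _raw_aligned(self) -> bool:
        # the writer's fast path fires only when its coder is pristine AND
        # its bit cursor is on a byte boundary; mirror both conditions
        logical = self._bitpos - (16 if self._window_valid else 0)
        return self._pristine and logical % 8 == 0

    def _drop_window(self) -> int:
        if self._window_valid:
            self._bitpos -= 16
            self._window_valid = False
        return self._bitpos >> 3

    def read_u8(self) -> int:
        if self._raw_aligned():
            idx = self._drop_window()
            if idx >= len(self._data):
                raise ValueError(f"payload truncated at byte {idx}")
            self._bitpos += 8
            return self._data[idx]
        symbol = self._read_symbol(Context.STATIC_FULL + 256)
        return _BITREV8[symbol - 1]

    def read_bytes(self, n: int) -> bytes:
        if self._raw_aligned():
            idx = self._drop_window()
            if idx + n > len(self._data):
                raise ValueError(f"payload truncated at byte {len(self._data)} (need {idx + n})")
            self._bitpos += 8 * n
            return self._data[idx : idx + n]
        return bytes(self.read_u8() for _ in range(n))

    def read_u16(self) -> int:
        return struct.unpack("<H", self.read_bytes(2))[0]

    def read_u32(self) -> int:
        return struct.unpack("<I", self.read_bytes(4))[0]

    def read_u64(self) -> int:
        return struct.unpack("<Q", self.read_bytes(8))[0]

    def read_i16(self) -> int:
        return struct.unpack("<h", self.read_bytes(2))[0]

    def read_f32(self) -> float:
        return struct.unpack("<f", self.read_bytes(4))[0]

    def read_f64(self) -> float:
        return struct.unpack("<d", self.read_bytes(8))[0]

    def read_string(self) -> str:
        n = self.read_u16()
        return self.read_bytes(n).decode("utf-8")

    # -- compressed values --------------------------------------------------

    def _read_compressed(self, context: int, literal):
        if context == Context.NOT_COMPRESSED:
            raise ValueError("context 0 is reserved; use an explicit plain read")
        if context >= Context.MAX_RANGE:
            return literal()
        symbol = self._read_symbol(context)
        if symbol == 0 and context < Context.STATIC_FULL:
            value = literal()
            self._ctx.add(context, value + 1)
            return value
        return symbol - 1

    def read_compressed_u32(self, context: int) -> int:
        return self._read_compressed(context, self.read_u32)

    def read_compressed_u16(self, context: int) -> int:
        return self._read_compressed(context, self.read_u16)

    def read_compressed_u8(self, context: int) -> int:
        return self._read_compressed(context, self.read_u8)


def encode_values(writer: BitWriter, values_with_contexts: Iterable[Tuple[int, int]]) -> None:
    """Write ``(context, value)`` pairs as compressed U32 values."""
    for context, value in values_with_contexts:
        writer.write_compressed_u32(context, value)


def decode_values(reader: BitReader, contexts: Sequence[int]) -> List[int]:
    """Read one compressed U32 per context, in order."""
    return [reader.read_compressed_u32(context) for context in contexts]
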