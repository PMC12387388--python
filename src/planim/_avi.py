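"""Uncompressed AVI container support.

Reads and writes RIFF/AVI files whose video stream is raw 24-bit RGB
(``DIB `` handler, ``BI_RGB`` compression, bottom-up rows, BGR byte
order).  This is the lossless dialect the phantom generator emits, so a
write/read round trip is bit exact.  Compressed AVI streams are
rejected with :class:`~planim.errors.VideoIOError`.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import VideoIOError

_AVIH = struct.Struct("<14I")
_STRH = struct.Struct("<4s4sI2H8I4H")
_BMIH = struct.Struct("<I2i2H2I2i2I")


def _pad_width(width: int) -> int:
    """Bytes of zero padding appended to each 24-bit row."""
    return (-3 * width) % 4


def write_avi(path: str | Path, frames: np.ndarray, fps: int = 25) -> None:
    """Write ``frames`` (n, h, w, 3) uint8 RGB as an uncompressed AVI."""
    frames = np.asarray(frames, dtype=np.uint8)
    if frames.ndim != 4 or frames.shape[3] != 3 or frames.shape[0] == 0:
        raise VideoIOError("expected a non-empty (n, h, w, 3) frame stack")
    n, height, width, _ = frames.shape
    row_bytes = 3 * width + _pad_width(width)
    frame_bytes = row_bytes * height

    # raw DIB payload: bottom-up rows, BGR order, rows padded to 4 bytes
    payloads = []
    pad = b"\x00" * _pad_width(width)
    for frame in frames:
        bgr = frame[::-1, :, ::-1]
        if pad:
            rows = [row.tobytes() + pad for row in bgr]
            payloads.append(b"".join(rows))
        else:
            payloads.append(bgr.tobytes())

    avih = _AVIH.pack(
        1_000_000 // fps,  # microseconds per frame
        frame_bytes * fps,  # max bytes per second
        0,  # padding granularity
        0x10,  # AVIF_HASINDEX
        n, 0, 1, frame_bytes, width, height, 0, 0, 0, 0,
    )
    strh = _STRH.pack(
        b"vids", b"DIB ", 0, 0, 0, 0, 1, fps, 0, n,
        frame_bytes, 0xFFFFFFFF, 0, 0, 0, width, height,
    )
    strf = _BMIH.pack(40, width, height, 1, 24, 0, frame_bytes, 0, 0, 0, 0)

    strl = _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf))
    hdrl = _list(b"hdrl", _chunk(b"avih", avih) + strl)
    movi_body = b"".join(_chunk(b"00db", p) for p in payloads)
    movi = _list(b"movi", movi_body)

    # idx1: one entry per frame, offsets relative to the 'movi' fourcc
    idx_entries = []
    offset = 4
    for p in payloads:
        idx_entries.append(struct.pack("<4s3I", b"00db", 0x10, offset, len(p)))
        offset += 8 + len(p) + (len(p) & 1)
    idx1 = _chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    Path(path).write_bytes(b"RIFF" + struct.pack("<I", len(body)) + body)


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    out = fourcc + struct.pack("<I", len(payload)) + payload
    if len(payload) & 1:
        out += b"\x00"
    return out


def _list(fourcc: bytes, body: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        data_start = pos + 8
        yield fourcc, data_start, data_start + size
        pos = data_start + size + (size & 1)


def read_avi(path: str | Path) -> np.ndarray:
    """Read an uncompressed 24-bit AVI into an (n, h, w, 3) uint8 RGB stack."""
    try:
        buf = Path(path).read_bytes()
    except OSError as exc:
        raise VideoIOError(f"cannot read video file {path}: {exc}") from exc
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise VideoIOError(f"{path} is not an AVI (RIFF) file")

    width = height = None
    bit_count = compression = None
    payloads: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bit_count, compression
        for fourcc, s, e in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(s + 4, e)
            elif fourcc == b"strf" and width is None:
                fields = _BMIH.unpack_from(buf, s)
                width, height = fields[1], fields[2]
                bit_count, compression = fields[4], fields[5]
            elif fourcc in (b"00db", b"00dc") and e <= len(buf):
                payloads.append(buf[s:e])

    walk(12, 8 + struct.unpack_from("<I", buf, 4)[0])

    if width is None or height is None:
        raise VideoIOError(f"{path}: no video stream format found")
    if compression != 0 or bit_count != 24:
        raise VideoIOError(
            f"{path}: only uncompressed 24-bit AVI is supported "
            f"(biBitCount={bit_count}, biCompression={compression})"
        )
    top_down = height < 0
    height = abs(height)
    row_bytes = 3 * width + _pad_width(width)

    frames = []
    for payload in payloads:
        if len(payload) < row_bytes * height:
            continue  # truncated frame chunk
        rows = np.frombuffer(payload, dtype=np.uint8, count=row_bytes * height)
        rows = rows.reshape(height, row_bytes)[:, : 3 * width].reshape(height, width, 3)
        rgb = rows[:, :, ::-1] if top_down else rows[::-1, :, ::-1]
        frames.append(rgb.copy())
    if not frames:
        raise VideoIOError(f"{path}: no decodable frames")
    return np.stack(frames)
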