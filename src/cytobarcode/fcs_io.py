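"""Reading and writing list-mode cytometry event data in FCS format.

Supports FCS 3.0/3.1 list-mode files on read ($DATATYPE F, D, or I; integer
data is promoted to float) and writes FCS 3.1 with $DATATYPE=F (little-endian
float32) and $MODE=L. One dataset per file; $MODE=C/U (histogram) files and
FCS 2.0 are rejected.

The in-memory container is :class:`EventMatrix`: an events x channels array
of nonnegative intensities plus per-channel metadata ($PnN short name, $PnS
stain label, isotope mass when parseable).
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field

import numpy as np

HEADER_LEN = 58


class FCSFormatError(ValueError):
    """File is not a supported FCS list-mode dataset."""


@dataclass
class ChannelInfo:
    """One detector channel: short name ($PnN), stain label ($PnS), mass."""

    short_name: str
    label: str = ""
    mass: int | None = None

    def __post_init__(self) -> None:
        if not self.short_name:
            raise FCSFormatError("channel short_name must be nonempty")
        if self.mass is None:
            m = re.search(r"(\d{2,3})", self.short_name)
            if m:
                self.mass = int(m.group(1))


@dataclass
class EventMatrix:
    """List-mode event data: channels, an events x channels value matrix,
    and the TEXT-segment metadata of the source file (if any)."""

    channels: list[ChannelInfo]
    values: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float32))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.channels))
        if self.values.shape[1] != len(self.channels):
            raise FCSFormatError(
                f"{self.values.shape[1]} value columns for "
                f"{len(self.channels)} channels"
            )
        names = [c.short_name for c in self.channels]
        if len(set(names)) != len(names):
            raise FCSFormatError("duplicate channel short_name")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def short_names(self) -> list[str]:
        return [c.short_name for c in self.channels]

    def channel_index(self, ref: str) -> int:
        """Resolve a channel reference to a column index.

        Matching order: exact short_name, case-insensitive short_name,
        case-insensitive label. An ambiguous match is an error.
        """
        names = self.short_names
        if ref in names:
            return names.index(ref)
        low = ref.lower()
        hits = [i for i, n in enumerate(names) if n.lower() == low]
        if not hits:
            hits = [
                i for i, c in enumerate(self.channels) if c.label.lower() == low
            ]
        if not hits:
            # labels in real files often bundle several markers
            # ("112Cd_CD29_CD45"); accept a unique substring hit
            hits = [
                i for i, c in enumerate(self.channels) if low in c.label.lower()
            ]
        if len(hits) > 1:
            raise FCSFormatError(f"channel reference {ref!r} is ambiguous")
        if not hits:
            raise FCSFormatError(f"channel {ref!r} not found among {names}")
        return hits[0]

    def column(self, ref: str) -> np.ndarray:
        return self.values[:, self.channel_index(ref)]

    def take(self, indices) -> "EventMatrix":
        """Row subset as a new EventMatrix (channels/metadata shared)."""
        idx = np.asarray(indices, dtype=np.intp)
        return EventMatrix(self.channels, self.values[idx], dict(self.metadata))


def _validate_for_write(matrix: EventMatrix) -> None:
    if matrix.values.size:
        if not np.isfinite(matrix.values).all():
            raise FCSFormatError("non-finite intensity value")
        if (matrix.values < 0).any():
            raise FCSFormatError("negative intensity value")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    text = raw.decode("latin-1")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # a doubled delimiter escapes a literal delimiter inside a value
    merged: list[str] = []
    i = 0
    while i < len(parts):
        cur = parts[i]
        while i + 2 < len(parts) and parts[i + 1] == "":
            cur += delim + parts[i + 2]
            i += 2
        merged.append(cur)
        i += 1
    if len(merged) % 2:
        merged = merged[:-1]
    return {k.strip(): v for k, v in zip(merged[0::2], merged[1::2])}


def read_fcs(path) -> EventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventMatrix`.

    Integer data ($DATATYPE=I) is promoted to float32; float64 data is
    narrowed to float32 (the toolkit's working precision).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < HEADER_LEN:
        raise FCSFormatError(f"{path}: truncated FCS header")
    version = data[:6].decode("latin-1", "replace")
    if not version.startswith("FCS3."):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        txt = data[lo:hi].decode("latin-1").strip()
        return int(txt) if txt else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end >= len(data) or text_end < text_start:
        raise FCSFormatError(f"{path}: TEXT segment extends past end of file")
    text = _parse_text_segment(data[text_start : text_end + 1])

    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"{path}: $MODE={mode} is not list mode")
    datatype = text.get("$DATATYPE", "").upper()
    if datatype not in ("F", "D", "I"):
        raise FCSFormatError(f"{path}: unsupported $DATATYPE={datatype!r}")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    if n_tot == 0:  # empty dataset: no DATA segment to bound-check
        channels = [
            ChannelInfo(
                short_name=text.get(f"$P{p}N", f"P{p}"),
                label=text.get(f"$P{p}S", ""),
            )
            for p in range(1, n_par + 1)
        ]
        values = np.zeros((0, n_par), dtype=np.float32)
        return EventMatrix(channels=channels, values=values, metadata=text)
    if data_end + 1 > len(data):
        raise FCSFormatError(f"{path}: DATA segment extends past end of file")

    channels: list[ChannelInfo] = []
    bits: list[int] = []
    for p in range(1, n_par + 1):
        name = text.get(f"$P{p}N", f"P{p}")
        label = text.get(f"$P{p}S", "")
        channels.append(ChannelInfo(short_name=name, label=label))
        bits.append(int(text.get(f"$P{p}B", 32)))

    raw = data[data_start : data_end + 1]
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
        values = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=dtype)
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
        values = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=dtype)
    else:  # I — require a uniform 16/32/64-bit width
        widths = set(bits)
        if len(widths) != 1 or bits[0] not in (16, 32, 64):
            raise FCSFormatError(
                f"{path}: unsupported $PnB widths {sorted(widths)} for $DATATYPE=I"
            )
        nbytes = bits[0] // 8
        dtype = np.dtype(f"{endian}u{nbytes}")
        values = np.frombuffer(raw[: nbytes * n_par * n_tot], dtype=dtype)
    if values.size != n_par * n_tot:
        raise FCSFormatError(
            f"{path}: DATA segment holds {values.size} values, "
            f"expected {n_par * n_tot}"
        )
    values = values.reshape(n_tot, n_par).astype(np.float32)
    return EventMatrix(channels=channels, values=values, metadata=text)


def write_fcs(matrix: EventMatrix, path) -> None:
    """Write an :class:`EventMatrix` as FCS 3.1, $DATATYPE=F, $MODE=L.

    Values are stored as little-endian float32; channel short names go to
    $PnN and labels to $PnS. Negative or non-finite intensities are a
    validation error.
    """
    _validate_for_write(matrix)
    values = np.ascontiguousarray(matrix.values, dtype="<f4")
    n_tot, n_par = values.shape

    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for p, ch in enumerate(matrix.channels, start=1):
        pairs.append((f"$P{p}N", ch.short_name))
        if ch.label:
            pairs.append((f"$P{p}S", ch.label))
        pairs.append((f"$P{p}B", "32"))
        pairs.append((f"$P{p}E", "0,0"))
        rng = float(values[:, p - 1].max()) if n_tot else 1.0
        pairs.append((f"$P{p}R", str(int(np.ceil(rng)) + 1)))

    # BEGINDATA/ENDDATA appear inside TEXT, whose length they depend on;
    # fixed-width zero-padded offsets break the circularity.
    delim = "/"

    def render(begin_data: int, end_data: int) -> bytes:
        items = [("$BEGINDATA", f"{begin_data:010d}"), ("$ENDDATA", f"{end_data:010d}")]
        items += pairs
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in items) + delim
        return text.encode("latin-1")

    probe = render(0, 0)
    text_start = HEADER_LEN
    text_end = text_start + len(probe) - 1
    data_start = text_end + 1 if values.nbytes else 0
    data_end = data_start + values.nbytes - 1 if values.nbytes else 0
    text = render(data_start, data_end)
    assert len(text) == len(probe)

    def fld(v: int) -> bytes:
        return f"{v:>8d}".encode("ascii") if v <= 99_999_999 else b"       0"

    header = b"FCS3.1    " + b"".join(
        fld(v) for v in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())
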