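"""Combinatorial k-of-n barcode key schemes.

A barcoding scheme assigns each sample a binary *key* over the barcode
channels: exactly ``k`` of the ``B`` channels are positive for every sample
(a constant-weight code). Because all keys share the same weight, any two
distinct keys differ in at least two positions, which is what makes
cell-cell doublets detectable: the union of two different keys has weight
``>= k + 1`` and therefore matches no key.

The complete ``B``-choose-``k`` scheme enumerates all C(B, k) keys in
lexicographic order of their positive-channel index sets, e.g. the 10-plex
design over five channels (112Cd, 113In, 114Cd, 115In, 116Cd) with k = 3,
extensible to a 20-plex by adding a sixth channel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

#: Barcode channels of the reference 10-plex design, ascending mass order.
DEFAULT_CHANNELS = ["112Cd", "113In", "114Cd", "115In", "116Cd"]


class SchemeError(ValueError):
    """Invalid scheme parameters or malformed key file."""


@dataclass
class BarcodeScheme:
    """A binary key matrix: one row per sample, one column per channel.

    Attributes
    ----------
    channel_ids : list of str
        Ordered barcode-channel labels (isotope names).
    sample_names : list of str
        Ordered sample labels, one per key row.
    key_matrix : numpy.ndarray
        Binary (samples x channels) matrix; ``key_matrix[s, j] == 1`` means
        sample ``s`` is stained on channel ``j``.
    k : int
        Positives per key (constant row weight).
    """

    channel_ids: list[str]
    sample_names: list[str]
    key_matrix: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.key_matrix = np.asarray(self.key_matrix, dtype=np.int8)
        if self.key_matrix.ndim != 2:
            raise SchemeError("key_matrix must be two-dimensional")
        s, b = self.key_matrix.shape
        if len(self.sample_names) != s:
            raise SchemeError(
                f"{len(self.sample_names)} sample names for {s} key rows"
            )
        if len(self.channel_ids) != b:
            raise SchemeError(
                f"{len(self.channel_ids)} channel ids for {b} key columns"
            )

    @property
    def n_samples(self) -> int:
        return self.key_matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.key_matrix.shape[1]

    def positive_channels(self, sample_index: int) -> tuple[int, ...]:
        """Indices of the positive channels of one key."""
        return tuple(np.flatnonzero(self.key_matrix[sample_index]))

    def is_complete(self) -> bool:
        """True if the scheme holds all C(B, k) constant-weight keys."""
        return self.n_samples == comb(self.n_channels, self.k)


def generate_complete_scheme(
    channel_ids: list[str] | None = None, k: int = 3
) -> BarcodeScheme:
    """Enumerate the complete k-of-B scheme over the given channels.

    Rows are ordered lexicographically by their positive-channel index set,
    so repeated generation is deterministic. Samples are named
    ``BC01 ... BCnn``.

    Parameters
    ----------
    channel_ids : list of str, optional
        Barcode channel labels; defaults to the five-channel
        112Cd/113In/114Cd/115In/116Cd layout.
    k : int
        Positive channels per key; must satisfy ``1 <= k <= len(channel_ids)``.

    Returns
    -------
    BarcodeScheme
        Scheme with C(B, k) rows.
    """
    if channel_ids is None:
        channel_ids = list(DEFAULT_CHANNELS)
    b = len(channel_ids)
    if not 1 <= k <= b:
        raise SchemeError(f"k={k} out of range for {b} channels (need 1 <= k <= B)")
    if len(set(channel_ids)) != b:
        raise SchemeError("channel_ids must be unique")

    subsets = list(combinations(range(b), k))  # lexicographic by construction
    key = np.zeros((len(subsets), b), dtype=np.int8)
    for row, pos in enumerate(subsets):
        key[row, list(pos)] = 1
    width = max(2, len(str(len(subsets))))
    names = [f"BC{i + 1:0{width}d}" for i in range(len(subsets))]
    return BarcodeScheme(list(channel_ids), names, key, k)


def validate_scheme(scheme: BarcodeScheme) -> list[str]:
    """Check every scheme invariant; return violation descriptions.

    An empty list means the scheme is valid. Checked rules: row weight
    equals k, rows pairwise distinct, row count within C(B, k), k in range,
    pairwise Hamming distance >= 2, binary entries.
    """
    violations: list[str] = []
    key = scheme.key_matrix
    s, b = key.shape

    if not np.isin(key, (0, 1)).all():
        violations.append("non-binary entry in key matrix")
    if not 1 <= scheme.k <= b:
        violations.append(f"k={scheme.k} out of range for B={b} channels")

    weights = key.sum(axis=1)
    for row in np.flatnonzero(weights != scheme.k):
        violations.append(
            f"row weight != k: sample {scheme.sample_names[row]!r} "
            f"(row {row}) has weight {weights[row]}, expected {scheme.k}"
        )

    seen: dict[bytes, int] = {}
    for row in range(s):
        fp = key[row].tobytes()
        if fp in seen:
            violations.append(
                f"duplicate key: rows {seen[fp]} and {row} "
                f"({scheme.sample_names[seen[fp]]!r}, {scheme.sample_names[row]!r})"
            )
        else:
            seen[fp] = row

    if 1 <= scheme.k <= b and s > comb(b, scheme.k):
        violations.append(
            f"{s} rows exceeds C({b},{scheme.k}) = {comb(b, scheme.k)}"
        )

    # Hamming >= 2 is implied by distinct constant-weight rows but asserted
    # independently so corrupt matrices are caught even when other rules fail.
    for i, j in combinations(range(s), 2):
        d = int(np.sum(key[i] != key[j]))
        if 0 < d < 2:
            violations.append(
                f"Hamming distance < 2 between rows {i} and {j} (distance {d})"
            )
    return violations


def write_key_file(scheme: BarcodeScheme, path) -> None:
    """Write the scheme as a key CSV: header ``sample,<ch1>,...``, body 0/1."""
    violations = validate_scheme(scheme)
    if violations:
        raise SchemeError("refusing to write invalid scheme: " + "; ".join(violations))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", *scheme.channel_ids])
        for name, row in zip(scheme.sample_names, scheme.key_matrix):
            writer.writerow([name, *(int(v) for v in row)])


def read_key_file(path) -> BarcodeScheme:
    """Read a key CSV written by :func:`write_key_file` (or compatible).

    The first header cell is ignored (conventionally ``sample``); remaining
    header cells are channel labels. Body cells must be 0 or 1. Row weight
    (k) is inferred from the first row and all rows must agree.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise SchemeError(f"{path}: not a key CSV (need header with >= 2 columns)")
    header = rows[0]
    channel_ids = [c.strip() for c in header[1:]]
    names: list[str] = []
    body: list[list[int]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise SchemeError(
                f"{path}: line {line_no} has {len(row)} columns, expected {len(header)}"
            )
        names.append(row[0].strip())
        parsed = []
        for col, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise SchemeError(
                    f"{path}: line {line_no}, column {col}: "
                    f"expected 0 or 1, got {cell!r}"
                )
            parsed.append(int(cell))
        body.append(parsed)
    if not body:
        raise SchemeError(f"{path}: key CSV has no sample rows")
    key = np.asarray(body, dtype=np.int8)
    k = int(key[0].sum())
    return BarcodeScheme(channel_ids, names, key, k)
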