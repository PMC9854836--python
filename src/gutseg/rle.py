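"""Run-length-encoded segmentation mask codec.

Masks are exchanged as RLE strings of whitespace-separated integers,
alternating ``start length`` pairs. Starts are 1-indexed positions into the
row-major (left-to-right, top-to-bottom) flattening of the image — the
convention of the UW-Madison GI-tract competition CSVs. An empty string is
the empty mask.

Per-slice annotations are rows of ``(slice_id, class_name, rle)`` with
exactly three possible classes; :func:`records_to_mask` assembles them into
a fixed-order H×W×3 binary stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed class-channel order (alphabetical), used everywhere a 3-channel
#: mask stack appears.
CLASSES: tuple[str, str, str] = ("large_bowel", "small_bowel", "stomach")

CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}


class MalformedRleError(ValueError):
    """RLE string violates the format (odd token count, bad length, ...)."""


class RleOutOfBoundsError(ValueError):
    """A run extends outside the H·W pixel grid."""


class DuplicateRecordError(ValueError):
    """More than one record for the same (slice_id, class_name)."""


class UnknownClassError(ValueError):
    """Record class name is not one of the three organ classes."""


@dataclass(frozen=True)
class SegmentationRecord:
    """One (slice, organ class, RLE mask) annotation row."""

    slice_id: str
    class_name: str
    rle: str


def _parse_runs(rle: str) -> np.ndarray:
    """Parse an RLE string into an (n_runs, 2) int array of (start, length)."""
    tokens = rle.split()
    if not tokens:
        return np.empty((0, 2), dtype=np.int64)
    try:
        values = np.array([int(t) for t in tokens], dtype=np.int64)
    except ValueError as exc:
        raise MalformedRleError(f"non-integer token in RLE string: {exc}") from None
    if values.size % 2 != 0:
        raise MalformedRleError(
            f"RLE string has odd token count ({values.size}); expected 'start length' pairs"
        )
    runs = values.reshape(-1, 2)
    if np.any(runs[:, 1] < 1):
        raise MalformedRleError("RLE run lengths must be >= 1")
    if np.any(runs[:, 0] < 1):
        raise MalformedRleError("RLE starts are 1-indexed and must be >= 1")
    return runs


def decode_rle(rle: str, height: int, width: int) -> np.ndarray:
    """Decode an RLE string into a binary ``(height, width)`` uint8 mask.

    Tolerates non-canonical (unsorted, adjacent) but valid input.

    Raises
    ------
    MalformedRleError
        Odd token count, non-integer token, or run length < 1.
    RleOutOfBoundsError
        A run extends past ``height * width``.
    """
    runs = _parse_runs(rle)
    n = height * width
    flat = np.zeros(n, dtype=np.uint8)
    for start, length in runs:
        if start + length - 1 > n:
            raise RleOutOfBoundsError(
                f"run (start={start}, length={length}) exceeds {height}x{width}={n} pixels"
            )
        flat[start - 1 : start - 1 + length] = 1
    return flat.reshape(height, width)


def encode_rle(mask: np.ndarray) -> str:
    """Encode a binary 2-D mask as a canonical RLE string.

    Canonical means 1-indexed starts, row-major flattening, maximal runs,
    strictly ascending starts. The all-zero mask encodes to ``""``.

    Raises
    ------
    ValueError
        If the mask contains values other than 0 and 1.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")
    flat = arr.reshape(-1).astype(np.int8)
    # transitions of the padded sequence 0,m1..mn,0 mark run starts/ends
    padded = np.concatenate([[0], flat, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1  # 1-indexed
    ends = np.flatnonzero(diff == -1)  # inclusive, 1-indexed
    lengths = ends - starts + 1
    return " ".join(f"{s} {l}" for s, l in zip(starts, lengths))


def canonicalize(rle: str, height: int, width: int) -> str:
    """Return the canonical form of a valid RLE string (decode then encode)."""
    return encode_rle(decode_rle(rle, height, width))


def records_to_mask(
    records: Iterable[SegmentationRecord | Sequence],
    height: int,
    width: int,
) -> np.ndarray:
    """Assemble one slice's records into an ``(H, W, 3)`` binary stack.

    Channel order follows :data:`CLASSES`; a class without a record yields an
    all-zero channel.

    Raises
    ------
    DuplicateRecordError
        Two records for the same class.
    UnknownClassError
        ``class_name`` not among the three organ classes.
    """
    stack = np.zeros((height, width, len(CLASSES)), dtype=np.uint8)
    seen: set[str] = set()
    for rec in records:
        if isinstance(rec, SegmentationRecord):
            cls, rle = rec.class_name, rec.rle
        else:
            _, cls, rle = rec
        if cls not in CLASS_INDEX:
            raise UnknownClassError(f"unknown class {cls!r}; expected one of {CLASSES}")
        if cls in seen:
            raise DuplicateRecordError(f"duplicate record for class {cls!r}")
        seen.add(cls)
        stack[:, :, CLASS_INDEX[cls]] = decode_rle(rle, height, width)
    return stack


def mask_to_records(mask: np.ndarray, slice_id: str) -> list[SegmentationRecord]:
    """Encode an (H, W, 3) stack into one record per class (empty RLE kept)."""
    arr = np.asarray(mask)
    if arr.ndim != 3 or arr.shape[2] != len(CLASSES):
        raise ValueError(f"expected (H, W, 3) mask stack, got shape {arr.shape}")
    return [
        SegmentationRecord(slice_id, cls, encode_rle(arr[:, :, i]))
        for i, cls in enumerate(CLASSES)
    ]


def read_records_csv(path) -> pd.DataFrame:
    """Read an ``id,class,segmentation`` CSV; empty cells become empty RLE."""
    df = pd.read_csv(path, dtype={"id": str, "class": str, "segmentation": str})
    missing = {"id", "class", "segmentation"} - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    df["segmentation"] = df["segmentation"].fillna("")
    return df


def write_records_csv(records: Iterable[SegmentationRecord], path) -> pd.DataFrame:
    """Write records to an ``id,class,segmentation`` CSV and return the frame."""
    df = pd.DataFrame(
        [(r.slice_id, r.class_name, r.rle) for r in records],
        columns=["id", "class", "segmentation"],
    )
    df.to_csv(path, index=False)
    return df
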