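"""Segmentation of a raw EEG channel into segments and sub-segment matrices.

A channel of *n* samples is first partitioned into ``n_segments`` contiguous
non-overlapping segments: the first ``n_segments - 1`` have length
``floor(n / n_segments)`` and the last absorbs the remainder (a 4097-sample
channel split four ways gives 1024, 1024, 1024, 1025).  Each segment is then
rearranged into an ``m × k`` matrix of consecutive sub-segments with
``k = floor(len / m)``; trailing samples beyond ``m·k`` are dropped (and
counted).  With the defaults (1024-sample segments, m = 32) the matrix is
square, which is what the covariance-determinant reduction expects.

Indexing is 0-based with half-open intervals throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .io import RawChannel

logger = logging.getLogger("covdet")

DEFAULT_N_SEGMENTS = 4
DEFAULT_M_SUBSEGMENTS = 32


@dataclass
class Segment:
    """A contiguous block of one channel."""

    samples: np.ndarray
    index: int
    parent: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class SegmentMatrix:
    """A segment rearranged as an ``m × k`` matrix of sub-segment rows."""

    rows: np.ndarray
    m: int
    k: int
    dropped: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.shape != (self.m, self.k):
            raise InvalidArgumentError(
                f"rows shape {self.rows.shape} != ({self.m}, {self.k})")

    @property
    def is_square(self) -> bool:
        return self.m == self.k


def segment_lengths(n: int, n_segments: int) -> list[int]:
    """Lengths of the partition of *n* samples into *n_segments* pieces.

    First ``n_segments - 1`` pieces get ``floor(n / n_segments)`` samples;
    the last absorbs the remainder.
    """
    if n_segments < 1:
        raise InvalidArgumentError("n_segments must be >= 1")
    if n_segments > n:
        raise InvalidArgumentError(
            f"n_segments={n_segments} exceeds channel length {n}")
    base = n // n_segments
    return [base] * (n_segments - 1) + [n - base * (n_segments - 1)]


def segment_channel(channel: RawChannel, n_segments: int = DEFAULT_N_SEGMENTS) -> list[Segment]:
    """Partition *channel* into ordered, gapless, non-overlapping segments."""
    lengths = segment_lengths(len(channel), n_segments)
    segments = []
    start = 0
    for i, length in enumerate(lengths):
        segments.append(Segment(samples=channel.samples[start:start + length],
                                index=i, parent=channel.channel_id))
        start += length
    return segments


def to_subsegment_matrix(segment: Segment, m: int = DEFAULT_M_SUBSEGMENTS,
                         overlap: int = 0) -> SegmentMatrix:
    """Rearrange *segment* into an ``m × k`` matrix of sub-segment rows.

    With ``overlap = 0`` (the default), row *i* holds samples
    ``[i·k, (i+1)·k)`` with ``k = floor(len / m)`` and the tail beyond
    ``m·k`` is dropped.  A positive ``overlap`` (in samples) makes
    consecutive rows share that many samples, with
    ``k = floor((len + (m-1)·overlap) / m)`` and stride ``k - overlap``.
    """
    n = len(segment)
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    if m > n:
        raise InvalidArgumentError(f"m={m} exceeds segment length {n}")
    if overlap < 0:
        raise InvalidArgumentError("overlap must be >= 0")
    k = (n + (m - 1) * overlap) // m
    if overlap >= k:
        raise InvalidArgumentError(f"overlap={overlap} >= sub-segment length {k}")
    stride = k - overlap
    rows = np.stack([segment.samples[i * stride:i * stride + k] for i in range(m)])
    used = (m - 1) * stride + k
    dropped = n - used
    if dropped:
        logger.debug("segment %d: dropped %d trailing sample(s) (len %d, m=%d)",
                     segment.index, dropped, n, m)
    return SegmentMatrix(rows=rows, m=m, k=k, dropped=dropped)
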