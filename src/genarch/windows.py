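"""Assembly input and the fixed-size window grid.

Every downstream feature, embedding and cluster label is indexed by the
window grid built here: each scaffold is partitioned into contiguous,
non-overlapping windows of ``window_size`` bp (default 5000), with the
trailing partial window of each scaffold retained as a first-class window.
Coordinates are 0-based half-open throughout, matching BED/bedgraph.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 5000

_VALID_BASES = set("ACGTNacgtn")


@dataclass
class SequenceRecord:
    """A single scaffold: identifier, sequence and length.

    Lowercase bases are preserved but treated as equivalent to uppercase by
    all feature computations. Characters outside {A,C,G,T,N} (either case)
    are mapped to N at load time.
    """

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file (plain or gzip) into SequenceRecords.

    Order is preserved. Characters outside {A,C,G,T,N,a,c,g,t,n} are mapped
    to N with a logged warning. Empty files, duplicate identifiers and
    non-FASTA content raise ValueError naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        head = fh.read(1)
        if head == "":
            raise ValueError(f"{path}: empty file")
        if head != ">":
            raise ValueError(f"{path}: not FASTA (first character {head!r})")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if not set(seq) <= _VALID_BASES:
                n_bad = sum(c not in _VALID_BASES for c in seq)
                log.warning(
                    "%s: record %s has %d non-ACGTN characters; mapped to N",
                    path, rec.id, n_bad,
                )
                seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


@dataclass
class WindowGrid:
    """Ordered, non-overlapping fixed-size windows over an assembly.

    Windows are stored as parallel arrays in global order: scaffold order as
    given, then position. The last window of each scaffold may be shorter
    than ``window_size``; its actual span is end − start.
    """

    window_size: int
    scaffold_ids: list[str]
    scaffold_lengths: dict[str, int]
    scaffold: np.ndarray = field(repr=False)   # per-window scaffold index
    start: np.ndarray = field(repr=False)
    end: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        """Per-window span in bp (== window_size except trailing windows)."""
        return self.end - self.start

    @property
    def n_windows_per_scaffold(self) -> dict[str, int]:
        idx, counts = np.unique(self.scaffold, return_counts=True)
        return {self.scaffold_ids[i]: int(c) for i, c in zip(idx, counts)}

    def scaffold_names(self) -> np.ndarray:
        """Per-window scaffold id as an object array."""
        return np.asarray(self.scaffold_ids, dtype=object)[self.scaffold]

    def iter_windows(self) -> Iterator[tuple[str, int, int]]:
        names = self.scaffold_names()
        for name, s, e in zip(names, self.start, self.end):
            yield str(name), int(s), int(e)

    def window_index(self, scaffold_id: str, position: int) -> int:
        """Global index of the window containing (scaffold, position)."""
        if scaffold_id not in self.scaffold_lengths:
            raise KeyError(scaffold_id)
        if not 0 <= position < self.scaffold_lengths[scaffold_id]:
            raise IndexError(
                f"position {position} outside scaffold {scaffold_id!r}"
            )
        sidx = self.scaffold_ids.index(scaffold_id)
        offset = int(np.searchsorted(self.scaffold, sidx, side="left"))
        return offset + position // self.window_size

    def locate(self, index: int) -> tuple[str, int, int]:
        """(scaffold, start, end) of the window at global index."""
        return (
            self.scaffold_ids[int(self.scaffold[index])],
            int(self.start[index]),
            int(self.end[index]),
        )

    def overlapping_windows(self, scaffold_id: str, start: int, end: int) -> np.ndarray:
        """Global indices of windows overlapping [start, end) on a scaffold."""
        if scaffold_id not in self.scaffold_lengths:
            return np.empty(0, dtype=int)
        length = self.scaffold_lengths[scaffold_id]
        start = max(0, start)
        end = min(length, end)
        if end <= start:
            return np.empty(0, dtype=int)
        sidx = self.scaffold_ids.index(scaffold_id)
        offset = int(np.searchsorted(self.scaffold, sidx, side="left"))
        first = start // self.window_size
        last = (end - 1) // self.window_size
        return np.arange(offset + first, offset + last + 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": self.scaffold_names(),
                "start": self.start.astype(int),
                "end": self.end.astype(int),
            }
        )


def partition_windows(
    records: Sequence[SequenceRecord], window_size: int = DEFAULT_WINDOW_SIZE
) -> WindowGrid:
    """Partition every scaffold into ceil(length / window_size) windows.

    Scaffolds shorter than ``window_size`` yield a single short window;
    nothing is dropped. Raises ValueError for window_size < 1.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    scaffold_idx: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    ids = [r.id for r in records]
    lengths = {r.id: r.length for r in records}
    for i, rec in enumerate(records):
        s = np.arange(0, rec.length, window_size, dtype=np.int64)
        e = np.minimum(s + window_size, rec.length)
        scaffold_idx.append(np.full(len(s), i, dtype=np.int64))
        starts.append(s)
        ends.append(e)
    return WindowGrid(
        window_size=window_size,
        scaffold_ids=ids,
        scaffold_lengths=lengths,
        scaffold=np.concatenate(scaffold_idx) if scaffold_idx else np.empty(0, int),
        start=np.concatenate(starts) if starts else np.empty(0, int),
        end=np.concatenate(ends) if ends else np.empty(0, int),
    )
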