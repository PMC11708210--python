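"""Merging unique windows into unique regions (URs) and BED I/O.

A unique region is a maximal run of sliding windows whose match
complexity is indistinguishable from random, merged over overlaps and
book-ended joins, and at least ``min_length`` bp long (10 kb in the
headline analyses). Intervals are 0-based half-open throughout; the BED
files written here carry the run's provenance as ``#`` header comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "GenomicInterval",
    "URSet",
    "BedFormatError",
    "extract_unique_regions",
    "merge_intervals",
    "read_bed",
    "write_bed",
]

DEFAULT_MIN_LENGTH = 10_000


class BedFormatError(ValueError):
    pass


class GenomicInterval(NamedTuple):
    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class URSet:
    """Sorted, non-overlapping unique regions plus their provenance."""

    intervals: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["chromosome", "start", "end"])


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list:
    """Union of intervals; adjacent (book-ended) intervals merge too."""
    ivs = sorted(intervals, key=lambda iv: (iv.chromosome, iv.start, iv.end))
    merged: list = []
    for iv in ivs:
        if merged and merged[-1].chromosome == iv.chromosome and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chromosome, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(*iv))
    return merged


def extract_unique_regions(
    classified: pd.DataFrame,
    min_length: int = DEFAULT_MIN_LENGTH,
    provenance: dict | None = None,
) -> URSet:
    """Merge unique-flagged windows and apply the minimum-length filter.

    ``classified`` is a complexity profile with a boolean ``unique``
    column (see :func:`urscan.complexity.classify_unique`). Runs of
    overlapping or abutting unique windows become one region; merged
    regions shorter than ``min_length`` are discarded (the ``>=`` bound
    is inclusive: a region exactly ``min_length`` long is kept).
    """
    flagged = classified[classified["unique"].astype(bool)]
    windows = [
        GenomicInterval(row.chromosome, int(row.start), int(row.end))
        for row in flagged.itertuples()
    ]
    merged = [iv for iv in merge_intervals(windows) if iv.length >= min_length]
    prov = dict(provenance or {})
    prov.setdefault("min_length", min_length)
    return URSet(intervals=merged, provenance=prov)


def write_bed(urs: URSet, path) -> None:
    with open(path, "w") as fh:
        for k, v in urs.provenance.items():
            fh.write(f"# {k}={v}\n")
        for iv in urs.intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\n")


def read_bed(path, chrom_lengths: dict | None = None) -> list:
    """Read 3-column BED (0-based half-open); ``#`` lines are ignored.

    Raises :class:`BedFormatError` naming the line for malformed rows,
    ``start >= end``, or (when ``chrom_lengths`` is given) chromosomes
    absent from the genome.
    """
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval [{start},{end})"
                )
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise BedFormatError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
                if end > chrom_lengths[chrom]:
                    raise BedFormatError(
                        f"{path}: line {lineno}: interval end {end} beyond chromosome"
                    )
            out.append(GenomicInterval(chrom, start, end))
    return out
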