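"""Sequence I/O and the exact-match index over a genome.

The detection of unique genomic regions rests on *maximal matches*: for
every position of a genome, the length of the longest substring starting
there that also occurs somewhere else in the genome — on the forward
strand at a different position, or anywhere on the reverse-complement
strand. Transposons and other repeats produce long maximal matches; a
region with no close homolog elsewhere produces only the short chance
matches expected of random sequence.

This module provides:

* :func:`load_fasta` — FASTA input normalised to upper-case ``ACGTN``;
* :class:`MatchIndex` — a suffix array over the concatenation of all
  chromosomes and their reverse complements, with unique sentinels so no
  match crosses a chromosome boundary, a strand boundary, or an ``N``;
* :func:`matching_statistics` — the per-position maximal-match lengths;
* :func:`factorize` — the greedy left-to-right decomposition of a
  chromosome into maximal-match factors, whose count inside a sliding
  window is the observed factor count ``mo`` used by the complexity
  module.

The suffix array is built by numpy prefix doubling and the LCP array by
Kasai's algorithm; matching statistics then fall out as the maximum of
the two LCP values adjacent to each suffix in suffix-array order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "SequenceRecord",
    "MatchIndex",
    "MatchingStatistics",
    "Factorization",
    "InputFormatError",
    "DegenerateInputError",
    "load_fasta",
    "reverse_complement",
    "random_residues",
    "build_index",
    "matching_statistics",
    "factorize",
]


class InputFormatError(ValueError):
    """Raised when an input file is malformed; the message names the line."""


class DegenerateInputError(ValueError):
    """Raised when an input is syntactically valid but unusable (e.g. all-N)."""


# ---------------------------------------------------------------------------
# Sequence records and FASTA I/O
# ---------------------------------------------------------------------------

_VALID = set(b"ACGTN")
# translation: lowercase -> uppercase, anything outside {A,C,G,T,N} -> N
_NORMALISE = bytes(
    (b if b in _VALID else b"N"[0]) for b in (bytes([c]).upper()[0] for c in range(256))
)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named chromosome (or contig) over the alphabet ``{A,C,G,T,N}``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.encode("ascii", "replace").translate(_NORMALISE)
        object.__setattr__(self, "residues", norm.decode("ascii"))

    @property
    def length(self) -> int:
        return len(self.residues)


def reverse_complement(residues: str) -> str:
    return residues.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def load_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Lowercase residues are uppercased; characters outside ``{A,C,G,T,N}``
    become ``N``. Raises :class:`InputFormatError` naming the offending
    line for empty files, text before the first header, or empty headers.
    """
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []
    saw_content = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            saw_content = True
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise InputFormatError(f"{path}: empty FASTA header on line {lineno}")
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks)))
                name = header.split()[0]
                chunks = []
            elif name is None:
                raise InputFormatError(
                    f"{path}: line {lineno} precedes the first '>' header; not FASTA"
                )
            else:
                chunks.append(line.strip())
    if not saw_content:
        raise InputFormatError(f"{path}: empty file is not FASTA (line 1)")
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


def random_residues(length: int, composition=None, rng: np.random.Generator | None = None) -> str:
    """An i.i.d. random sequence over ``ACGT`` with the given base frequencies."""
    if rng is None:
        rng = np.random.default_rng()
    p = None if composition is None else np.asarray(composition, dtype=float)
    if p is not None:
        p = p / p.sum()
    codes = rng.choice(4, size=int(length), p=p)
    return codes.astype(np.uint8).tobytes().translate(bytes.maketrans(b"\0\1\2\3", b"ACGT")).decode()


# ---------------------------------------------------------------------------
# Suffix array, LCP, matching statistics
# ---------------------------------------------------------------------------


def _suffix_array(text: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Suffix array and ranks of an integer text by prefix doubling."""
    n = len(text)
    _, rank = np.unique(text, return_inverse=True)
    rank = rank.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while k < n:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new
        sa = order
        if new[-1] == n - 1:
            break
        k *= 2
    return sa, rank


@njit(cache=True)
def _kasai(text, sa, rank):  # pragma: no cover - exercised via matching_statistics
    n = len(text)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass
class MatchIndex:
    """Queryable index over all chromosomes and their reverse complements.

    ``A,C,G,T`` encode as ``0..3``; every ``N`` and every record/strand
    separator receives its own unique integer, so no common prefix — and
    hence no maximal match — can include an ``N`` or span a boundary.
    """

    records: list[SequenceRecord]
    total_length: int
    composition: np.ndarray  # A,C,G,T frequencies over non-N residues
    _text: np.ndarray = field(repr=False)
    _offsets: dict = field(repr=False)  # chromosome -> start of forward slice
    _sa: np.ndarray | None = field(default=None, repr=False)
    _rank: np.ndarray | None = field(default=None, repr=False)

    def _ensure_arrays(self) -> None:
        if self._sa is None:
            self._sa, self._rank = _suffix_array(self._text)

    @property
    def chromosomes(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def chromosome_lengths(self) -> dict:
        return {r.id: r.length for r in self.records}


def _encode(residues: str, next_unique: int) -> tuple[np.ndarray, int]:
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = np.empty(len(raw), dtype=np.int64)
    codes[raw == ord("A")] = 0
    codes[raw == ord("C")] = 1
    codes[raw == ord("G")] = 2
    codes[raw == ord("T")] = 3
    n_mask = raw == ord("N")
    k = int(n_mask.sum())
    codes[n_mask] = np.arange(next_unique, next_unique + k)
    return codes, next_unique + k


def build_index(records: Sequence[SequenceRecord]) -> MatchIndex:
    """Index the concatenation of all records and their reverse complements."""
    records = list(records)
    if not records:
        raise DegenerateInputError("no sequence records to index")
    total = sum(r.length for r in records)
    base_counts = np.zeros(4, dtype=np.int64)
    for r in records:
        enc = np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            base_counts[i] += int((enc == b).sum())
    if base_counts.sum() == 0:
        raise DegenerateInputError("all residues are N; nothing to index")
    composition = base_counts / base_counts.sum()

    parts: list[np.ndarray] = []
    offsets: dict = {}
    nxt = 4  # 0..3 are bases; sentinels and Ns count upward from here
    pos = 0
    for r in records:
        offsets[r.id] = pos
        codes, nxt = _encode(r.residues, nxt)
        sep = np.array([nxt], dtype=np.int64)
        nxt += 1
        parts.extend([codes, sep])
        pos += r.length + 1
    for r in records:
        codes, nxt = _encode(reverse_complement(r.residues), nxt)
        sep = np.array([nxt], dtype=np.int64)
        nxt += 1
        parts.extend([codes, sep])
    text = np.concatenate(parts)
    return MatchIndex(
        records=records,
        total_length=total,
        composition=composition,
        _text=text,
        _offsets=offsets,
    )


@dataclass
class MatchingStatistics:
    """Per-chromosome arrays of maximal-match lengths.

    ``ms[chrom][i]`` is the length of the longest prefix of the suffix at
    position ``i`` that occurs at least once elsewhere in the indexed
    genome (other forward position or anywhere on the reverse strand);
    0 when the residue is ``N`` or matches nothing.
    """

    ms: dict

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.ms[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.ms)


def matching_statistics(index: MatchIndex) -> MatchingStatistics:
    index._ensure_arrays()
    n = len(index._text)
    lcp = _kasai(index._text, index._sa, index._rank)
    # longest match of suffix i with ANY other suffix = max of the LCPs
    # with its two suffix-array neighbours
    up = np.zeros(n, dtype=np.int64)
    up[:-1] = lcp[1:]
    best = np.maximum(lcp, up)  # best[r] for rank r
    out: dict = {}
    for rec in index.records:
        off = index._offsets[rec.id]
        ranks = index._rank[off : off + rec.length]
        out[rec.id] = best[ranks].copy()
    return MatchingStatistics(ms=out)


# ---------------------------------------------------------------------------
# Greedy factorization
# ---------------------------------------------------------------------------


@dataclass
class Factorization:
    """Greedy left-to-right tiling of a region into maximal-match factors.

    The factor starting at position ``p`` has length ``max(MS[p], 1)``;
    the next factor starts immediately after it. Factors therefore tile
    the region exactly. The observed factor count of a window — the
    ``mo`` of the match-complexity statistic — is the number of factors
    whose span overlaps the window by at least 1 bp.
    """

    starts: np.ndarray
    lengths: np.ndarray
    region: tuple

    @property
    def factors(self) -> list[tuple]:
        return list(zip(self.starts.tolist(), self.lengths.tolist()))

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.lengths

    def factor_count(self, start: int, end: int) -> int:
        """Number of factors intersecting ``[start, end)`` by >= 1 bp."""
        return int(self.factor_counts(np.array([start]), np.array([end]))[0])

    def factor_counts(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`factor_count` over many windows."""
        if len(self.starts) == 0:
            return np.zeros(len(starts), dtype=np.int64)
        lo = np.clip(starts, self.region[0], self.region[1])
        hi = np.clip(ends, self.region[0], self.region[1])
        i0 = np.searchsorted(self.starts, lo, side="right") - 1
        i0 = np.maximum(i0, 0)
        # factor containing position hi-1 (the last bp of the window)
        i1 = np.searchsorted(self.starts, hi - 1, side="right") - 1
        counts = i1 - i0 + 1
        counts[hi <= lo] = 0
        return counts.astype(np.int64)


def factorize(ms: np.ndarray, start: int = 0, end: int | None = None) -> Factorization:
    """Greedily decompose ``[start, end)`` using the matching statistics.

    A position with ``MS == 0`` is its own length-1 factor, which makes
    the tiling total and the recursion terminate. The final factor is
    clipped at ``end``.
    """
    L = len(ms)
    if end is None:
        end = L
    if not (0 <= start <= end <= L):
        raise ValueError(f"region [{start},{end}) outside chromosome of length {L}")
    starts: list[int] = []
    lengths: list[int] = []
    p = start
    while p < end:
        ln = max(int(ms[p]), 1)
        ln = min(ln, end - p)
        starts.append(p)
        lengths.append(ln)
        p += ln
    return Factorization(
        starts=np.asarray(starts, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=np.int64),
        region=(start, end),
    )


# ---------------------------------------------------------------------------
# Brute-force oracle (small inputs; used by the test suite)
# ---------------------------------------------------------------------------


def brute_force_matching_statistics(records: Sequence[SequenceRecord]) -> MatchingStatistics:
    """Quadratic reference for :func:`matching_statistics`.

    Compares every suffix against every other start position on the
    forward strands and every position of the reverse-complement strands,
    by direct character comparison; ``N`` matches nothing, including
    another ``N``. Intended for genomes of a few hundred bp.
    """
    fwd = [(i, r.residues) for i, r in enumerate(records)]
    rev = [(i, reverse_complement(r.residues)) for i, r in enumerate(records)]
    out: dict = {}
    for ci, rec in enumerate(records):
        s = rec.residues
        ms = np.zeros(rec.length, dtype=np.int64)
        for i in range(rec.length):
            best = 0
            for (cj, t), same_strand in [(x, True) for x in fwd] + [(x, False) for x in rev]:
                for j in range(len(t)):
                    if same_strand and cj == ci and j == i:
                        continue  # the self-occurrence does not count
                    k = 0
                    while (
                        i + k < len(s)
                        and j + k < len(t)
                        and s[i + k] == t[j + k]
                        and s[i + k] != "N"
                    ):
                        k += 1
                    if k > best:
                        best = k
            ms[i] = best
        out[rec.id] = ms
    return MatchingStatistics(ms=out)
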