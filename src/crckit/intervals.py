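"""Genomic coordinate primitives and interval algebra.

All coordinates are 0-based half-open (BED convention). One-based formats
(GTF/refFlat-style inputs) are converted on read by the :mod:`crckit.io`
readers, so every interval inside the package follows a single convention.

"Overlap" always means at least one shared base: two intervals that merely
share a boundary (bookended) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "CoordinateError",
    "GenomicInterval",
    "RegionSet",
    "Transcript",
    "GenomeAssembly",
    "overlaps",
    "merge_union",
    "window_around",
]


class CoordinateError(ValueError):
    """An interval or position falls outside its chromosome."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates; ``0 <= start < end`` is enforced.
    strand : str
        One of ``"+"``, ``"-"`` or ``"."`` (unstranded).
    name, score : optional
        Free label and float score, carried through BED round-trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base.

    Half-open semantics: ``[0, 10)`` and ``[10, 20)`` do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class RegionSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``. A set with
    ``merged=True`` guarantees that no two intervals share a base, which is
    what downstream signal assignment assumes of a chromatin landscape.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], merged: bool = False):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if merged:
            for a, b in zip(ivs, ivs[1:]):
                if overlaps(a, b):
                    raise ValueError("merged RegionSet contains overlapping intervals")
        self.intervals: List[GenomicInterval] = ivs
        self.merged = merged
        self._index: Dict[str, tuple] = {}
        for iv in ivs:
            self._index.setdefault(iv.chrom, None)
        self._build_index()

    def _build_index(self) -> None:
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        self._chrom_offset: Dict[str, int] = {}
        for i, iv in enumerate(self.intervals):
            if iv.chrom not in by_chrom:
                self._chrom_offset[iv.chrom] = i
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._index = {}
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            # running max of ends lets a binary search bound the scan window
            maxend = np.maximum.accumulate(ends)
            self._index[chrom] = (starts, ends, maxend, ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def chroms(self) -> List[str]:
        return sorted(self._index)

    def total_bases(self) -> int:
        """Sum of interval lengths (covered bases when merged)."""
        return sum(len(iv) for iv in self.intervals)

    def overlapping(self, query: GenomicInterval) -> List[GenomicInterval]:
        """All intervals sharing >= 1 base with ``query``."""
        entry = self._index.get(query.chrom)
        if entry is None:
            return []
        ivs = entry[3]
        return [ivs[i] for i in self._overlapping_local(entry, query)]

    @staticmethod
    def _overlapping_local(entry, query: GenomicInterval) -> List[int]:
        starts, ends, maxend, _ = entry
        # candidates: start < query.end and running-max end > query.start
        hi = int(np.searchsorted(starts, query.end, side="left"))
        lo = int(np.searchsorted(maxend[:hi], query.start, side="right"))
        return [i for i in range(lo, hi) if ends[i] > query.start]

    def overlapping_indices(self, query: GenomicInterval) -> List[int]:
        """Positions (into ``self.intervals``) of intervals overlapping ``query``."""
        entry = self._index.get(query.chrom)
        if entry is None:
            return []
        # intervals are grouped by chrom in sorted order, so local index + offset
        offset = self._chrom_offset[query.chrom]
        return [offset + i for i in self._overlapping_local(entry, query)]

    def overlaps_any(self, query: GenomicInterval) -> bool:
        entry = self._index.get(query.chrom)
        if entry is None:
            return False
        starts, ends, maxend, _ = entry
        hi = int(np.searchsorted(starts, query.end, side="left"))
        if hi == 0:
            return False
        return bool(maxend[hi - 1] > query.start)

    def filter(self, keep) -> "RegionSet":
        return RegionSet([iv for iv in self.intervals if keep(iv)], merged=self.merged)

    def subtract_overlapping(self, other: "RegionSet") -> "RegionSet":
        """Intervals of self with no overlap in ``other`` (no trimming)."""
        return self.filter(lambda iv: not other.overlaps_any(iv))

    def check_bounds(self, assembly: "GenomeAssembly") -> None:
        for iv in self.intervals:
            assembly.check_interval(iv)

    def __repr__(self) -> str:
        return f"RegionSet(n={len(self)}, merged={self.merged})"


def merge_union(sets: Sequence[RegionSet | Iterable[GenomicInterval]],
                assembly: Optional["GenomeAssembly"] = None) -> RegionSet:
    """Union of region sets with overlapping intervals coalesced.

    Intervals sharing >= 1 base are merged into one; bookended intervals
    that only share a boundary are kept separate. The result is sorted and
    flagged ``merged=True``. Idempotent.
    """
    ivs: List[GenomicInterval] = []
    for s in sets:
        ivs.extend(s)
    if assembly is not None:
        for iv in ivs:
            assembly.check_interval(iv)
    ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: List[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return RegionSet(out, merged=True)


@dataclass(frozen=True)
class Transcript:
    """A transcript model reduced to what the pipeline needs: a TSS.

    The TSS is the strand-appropriate end of the span: ``span.start`` on the
    plus strand, ``span.end - 1`` on the minus strand.
    """

    transcript_id: str
    gene_name: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id} needs a strand")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand == "+" else self.span.end - 1


class GenomeAssembly:
    """Chromosome sizes plus (optionally) nucleotide sequence.

    Chromosome-name dialects ("chr1" vs "1") are normalized to the
    assembly's spelling via :meth:`normalize_chrom`.
    """

    def __init__(self, chrom_sizes: Dict[str, int],
                 sequence: Optional[Dict[str, str]] = None):
        self.chrom_sizes = dict(chrom_sizes)
        self.sequence = sequence
        if sequence is not None:
            for chrom, seq in sequence.items():
                if chrom in self.chrom_sizes and len(seq) != self.chrom_sizes[chrom]:
                    raise ValueError(
                        f"sequence length for {chrom} ({len(seq)}) != chrom size "
                        f"({self.chrom_sizes[chrom]})"
                    )
        self._alias = {}
        for chrom in self.chrom_sizes:
            self._alias[chrom] = chrom
            if chrom.startswith("chr"):
                self._alias[chrom[3:]] = chrom
            else:
                self._alias["chr" + chrom] = chrom

    @classmethod
    def from_sequences(cls, sequence: Dict[str, str]) -> "GenomeAssembly":
        return cls({c: len(s) for c, s in sequence.items()}, sequence=sequence)

    def normalize_chrom(self, chrom: str) -> str:
        try:
            return self._alias[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def check_interval(self, iv: GenomicInterval) -> None:
        size = self.chrom_sizes.get(iv.chrom)
        if size is None:
            raise CoordinateError(f"interval on unknown chromosome: {iv}")
        if iv.end > size:
            raise CoordinateError(
                f"interval beyond chromosome bounds: {iv.chrom}:{iv.start}-{iv.end} "
                f"(size {size})"
            )

    def check_position(self, chrom: str, pos: int) -> None:
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos >= size:
            raise CoordinateError(f"position {chrom}:{pos} outside chromosome (size {size})")

    def fetch(self, iv: GenomicInterval) -> str:
        if self.sequence is None or iv.chrom not in self.sequence:
            raise CoordinateError(f"no sequence available for chromosome {iv.chrom!r}")
        return self.sequence[iv.chrom][iv.start:iv.end]


def window_around(tss: int, half_width: int, chrom: str,
                  assembly: Optional[GenomeAssembly] = None,
                  name: Optional[str] = None) -> GenomicInterval:
    """Strand-independent window ``[tss - hw, tss + hw)`` clamped to the chromosome."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    end = tss + half_width
    if assembly is not None:
        assembly.check_position(chrom, tss)
        end = min(end, assembly.chrom_sizes[chrom])
    return GenomicInterval(chrom, max(0, tss - half_width), end, name=name)
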