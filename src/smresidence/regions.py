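"""Genomic-interval arithmetic: overlap counts/shares between interval
sets (e.g. differentially accessible regions from two depletion
experiments), A/T base composition of interval sets, and spike-in
normalization factors for sequencing coverage.

Intervals follow BED conventions: 0-based, half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "OverlapSummary",
    "read_bed",
    "read_fasta",
    "intersect_counts",
    "overlap_share",
    "at_content",
    "spike_in_factors",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    name: Optional[str] = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class OverlapSummary:
    """Two-way overlap counts and percentage shares between interval sets."""

    n_a: int
    n_b: int
    n_a_overlapping_b: int
    n_b_overlapping_a: int

    @property
    def share_a_percent(self) -> float:
        return overlap_share(self.n_a_overlapping_b, self.n_a)

    @property
    def share_b_percent(self) -> float:
        return overlap_share(self.n_b_overlapping_a, self.n_b)


def read_bed(path) -> List[GenomicInterval]:
    """Read a BED3+ file into a sorted interval list.

    Lines are 0-based half-open; ``track``/``browser``/comment lines are
    skipped.  Malformed lines (fewer than 3 columns, non-integer or
    inverted coordinates) raise with the offending line number.
    """
    path = Path(path)
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
            name = fields[3] if len(fields) > 3 else None
            intervals.append(GenomicInterval(chrom, start, end, name))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA sequences into a name → sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _merged_by_chrom(intervals: Sequence[GenomicInterval]) -> Dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns chrom → (m, 2) array of merged [start, end) sorted by start."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        out = []
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append((cur_s, cur_e))
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def _count_overlapping(
    queries: Sequence[GenomicInterval],
    merged: Dict[str, np.ndarray],
    min_overlap: int,
) -> int:
    count = 0
    for iv in queries:
        arr = merged.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        # merged intervals possibly overlapping [start, end)
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            continue
        shared = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        if int(shared.max()) >= min_overlap:
            count += 1
    return count


def intersect_counts(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bases: int = 1,
) -> OverlapSummary:
    """Count intervals of each set overlapping the other.

    An interval of ``a`` counts as overlapping if it shares at least
    ``min_overlap_bases`` bases (default 1) with any interval of ``b``,
    under half-open semantics — abutting intervals do not overlap.
    Counts and percentage shares are computed in both directions.
    """
    if min_overlap_bases < 1:
        raise ValueError("min_overlap_bases must be >= 1")
    merged_b = _merged_by_chrom(b)
    merged_a = _merged_by_chrom(a)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_a_overlapping_b=_count_overlapping(a, merged_b, min_overlap_bases),
        n_b_overlapping_a=_count_overlapping(b, merged_a, min_overlap_bases),
    )


def overlap_share(n_overlap: int, n_total: int) -> float:
    """Percentage of a set that overlaps another, to one decimal.

    e.g. 4559 of 26510 sites → 17.2.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_overlap <= n_total:
        raise ValueError("n_overlap must lie in [0, n_total]")
    return round(100.0 * n_overlap / n_total, 1)


def at_content(
    intervals: Sequence[GenomicInterval],
    sequences: Union[Mapping[str, str], str, Path],
) -> float:
    """Percent A/T base composition across an interval set.

    Case-insensitive; ambiguity codes (N etc.) count in the denominator
    only.  ``sequences`` is a chrom → sequence mapping or a FASTA path.
    """
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    n_at = 0
    n_total = 0
    for iv in intervals:
        if iv.chrom not in sequences:
            raise KeyError(f"chromosome {iv.chrom!r} not present in sequences")
        seq = sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds sequence length {len(seq)}"
            )
        sub = seq[iv.start : iv.end].upper()
        n_at += sub.count("A") + sub.count("T")
        n_total += len(sub)
    if n_total == 0:
        raise ValueError("no bases covered")
    return 100.0 * n_at / n_total


def spike_in_factors(counts):
    """Per-sample spike-in scale factors: count divided by the minimum count.

    The sample with the fewest uniquely mapped spike-in reads gets factor
    1.0; factors are equivariant under permutation of samples.  Accepts a
    mapping (name → count) or a sequence; returns the matching type.
    """
    if isinstance(counts, Mapping):
        names = list(counts.keys())
        values = np.asarray([counts[k] for k in names], dtype=float)
    else:
        names = None
        values = np.asarray(list(counts), dtype=float)
    if len(values) == 0:
        raise ValueError("no counts given")
    if np.any(values <= 0):
        raise ValueError("all spike-in counts must be positive")
    factors = values / values.min()
    if names is not None:
        return {k: float(f) for k, f in zip(names, factors)}
    return [float(f) for f in factors]
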