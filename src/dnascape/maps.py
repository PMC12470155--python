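"""Binned genomic maps: dinucleotide counts, tandem repeats, interval coverage,
and annotation readers.

All tracks use a fixed resolution (default 1000 bp).  Dinucleotides are
counted on the forward strand, overlapping; the dinucleotide spanning
positions ``(i, i+1)`` is assigned to the bin containing ``i``, so the pair
bridging two bins belongs to the left bin and every genomic dinucleotide is
counted exactly once (an interior N-free bin then holds exactly
``resolution`` dinucleotides).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._seq import BASES, DINUCLEOTIDES, N_CODE, dinuc_code, encode, revcomp_str
from .tracks import (BinnedTrack, VALID_FRACTION_THRESHOLD, bin_lengths, n_bins)


class Interval(NamedTuple):
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."


# ---------------------------------------------------------------------------
# dinucleotide counting
# ---------------------------------------------------------------------------

@dataclass
class DinucleotideTrackSet:
    """Per-bin dinucleotide and nucleotide counts for one chromosome.

    ``dinuc_counts`` has shape (n_bins, 16) in AA..TT order; ``nuc_counts``
    has shape (n_bins, 4) in ACGT order.  ``valid_length`` is the number of
    non-N bases per bin and plays the role of the modelled sequence length
    L_seq in the null-model formulas.
    """

    chrom: str
    resolution: int
    dinuc_counts: np.ndarray
    nuc_counts: np.ndarray
    valid_length: np.ndarray
    length: int

    @property
    def n_bins(self) -> int:
        return int(self.dinuc_counts.shape[0])

    @property
    def valid_fraction(self) -> np.ndarray:
        return self.valid_length / bin_lengths(self.length, self.resolution)

    @property
    def valid(self) -> np.ndarray:
        return self.valid_fraction >= VALID_FRACTION_THRESHOLD

    @property
    def total_dinucs(self) -> np.ndarray:
        return self.dinuc_counts.sum(axis=1)

    def track(self, xy: str) -> BinnedTrack:
        """Count track for one dinucleotide; invalid bins carry NaN."""
        vals = self.dinuc_counts[:, dinuc_code(xy)].astype(float)
        vals[~self.valid] = np.nan
        return BinnedTrack(self.chrom, self.resolution, vals, self.valid_fraction)

    def nucleotide_track(self, x: str) -> BinnedTrack:
        vals = self.nuc_counts[:, BASES.index(x.upper())].astype(float)
        vals[~self.valid] = np.nan
        return BinnedTrack(self.chrom, self.resolution, vals, self.valid_fraction)


def count_dinucleotides(sequence: str | np.ndarray, resolution: int = 1000,
                        chrom: str = "chr") -> DinucleotideTrackSet:
    """Count overlapping dinucleotides and nucleotides per bin.

    Pairs containing an N are skipped and N bases reduce the per-bin valid
    fraction.  Non-IUPAC characters raise ``ValueError`` with the position.
    """
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    L = codes.size
    nb = n_bins(L, resolution)
    bins = np.arange(L) // resolution

    valid_base = codes != N_CODE
    flat = bins[valid_base] * 4 + codes[valid_base].astype(np.int64)
    nuc = np.bincount(flat, minlength=nb * 4).reshape(nb, 4)

    dinuc = np.zeros((nb, 16), dtype=np.int64)
    if L >= 2:
        a, b = codes[:-1], codes[1:]
        ok = (a != N_CODE) & (b != N_CODE)
        pair = (a[ok].astype(np.int64) * 4 + b[ok])
        pbin = bins[:-1][ok]
        dinuc = np.bincount(pbin * 16 + pair, minlength=nb * 16).reshape(nb, 16)

    valid_length = np.bincount(bins[valid_base], minlength=nb)
    return DinucleotideTrackSet(chrom, resolution, dinuc, nuc, valid_length, L)


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def repeat_class(unit: str, merge_complements: bool = False) -> str:
    """Class label of a repeat unit, e.g. ``(AC)n``.

    Rotational phases form one class; with ``merge_complements`` the
    reverse-complement unit is folded in as well (a reporting option).
    """
    canon = canonical_rotation(unit.upper())
    if merge_complements:
        canon = min(canon, canonical_rotation(revcomp_str(canon)))
    return f"({canon})n"


@dataclass(frozen=True)
class TandemRepeat:
    chrom: str
    start: int
    end: int
    unit: str
    period: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cls(self) -> str:
        return repeat_class(self.unit)


def _minimal_period(region: np.ndarray, upto: int) -> int:
    """Smallest period p' <= upto under which the region self-matches."""
    for p in range(1, upto + 1):
        if np.all(region[:-p] == region[p:]):
            return p
    return upto + 1


def _qualifies(length: int, period: int, min_total: int) -> bool:
    return length >= max(min_total, 2 * period)


def find_tandem_repeats(sequence: str | np.ndarray, max_unit: int = 6,
                        min_total: int = 4, chrom: str = "chr") -> list[TandemRepeat]:
    """Detect maximal perfect tandem-repeat runs with unit length 1..max_unit.

    A run qualifies iff its total length is at least ``max(min_total,
    2 * unit length)`` — at least two complete units and at least 4 bp by
    default.  Runs are reported at their smallest period, so a homopolymer is
    never additionally reported as a dimer repeat.  Overlaps between runs of
    different periods are resolved greedily, longest run first (leftmost, then
    smallest period on ties); trailing fragments of later runs are trimmed to
    the uncovered bases and re-checked, so no base is counted twice.
    """
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    L = codes.size
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(1, max_unit + 1):
        if L < 2 * p:
            break
        match = (codes[:-p] == codes[p:]) & (codes[:-p] != N_CODE) & (codes[p:] != N_CODE)
        # maximal runs of consecutive matches
        padded = np.concatenate([[False], match, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]  # exclusive in match-space
        for s, e in zip(starts, ends):
            region_start, region_end = int(s), int(e) + p
            length = region_end - region_start
            if not _qualifies(length, p, min_total):
                continue
            region = codes[region_start:region_end]
            if _minimal_period(region, p) != p:
                continue  # smallest-period rule
            candidates.append((region_start, region_end, p))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    covered = np.zeros(L, dtype=bool)
    accepted: list[TandemRepeat] = []
    for s, e, p in candidates:
        free = ~covered[s:e]
        if not free.any():
            continue
        # contiguous uncovered sub-segments
        padded = np.concatenate([[False], free, [False]])
        diff = np.diff(padded.astype(np.int8))
        for fs, fe in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
            a, b = s + int(fs), s + int(fe)
            length = b - a
            if not _qualifies(length, p, min_total):
                continue
            region = codes[a:b]
            if _minimal_period(region, p) != p:
                continue
            unit = "".join(BASES[c] for c in region[:p])
            accepted.append(TandemRepeat(chrom, a, b, unit, p))
            covered[a:b] = True
    accepted.sort(key=lambda r: r.start)
    return accepted


def tandem_repeat_intervals(repeats: Iterable[TandemRepeat],
                            merge_complements: bool = False) -> dict[str, list[Interval]]:
    """Group repeat intervals by class label."""
    out: dict[str, list[Interval]] = {}
    for r in repeats:
        cls = repeat_class(r.unit, merge_complements)
        out.setdefault(cls, []).append(Interval(r.chrom, r.start, r.end))
    return out


# ---------------------------------------------------------------------------
# interval coverage
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted, disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"negative-length interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage_track(intervals: Sequence[tuple[int, int] | Interval], length: int,
                   resolution: int = 1000, chrom: str = "chr") -> BinnedTrack:
    """Bases covered by the union of intervals, per bin (union semantics)."""
    nb = n_bins(length, resolution)
    cov = np.zeros(nb, dtype=np.float64)
    pairs = [(iv[1], iv[2]) if isinstance(iv, Interval) else (iv[0], iv[1])
             for iv in intervals]
    for s, e in merge_intervals(pairs):
        s, e = max(0, s), min(length, e)
        if e <= s:
            continue
        b0, b1 = s // resolution, (e - 1) // resolution
        if b0 == b1:
            cov[b0] += e - s
        else:
            cov[b0] += (b0 + 1) * resolution - s
            cov[b1] += e - b1 * resolution
            cov[b0 + 1:b1] += resolution
    return BinnedTrack(chrom, resolution, cov)


def coverage_fraction(intervals: Sequence[tuple[int, int] | Interval], length: int,
                      resolution: int = 1000) -> np.ndarray:
    """Fraction of each bin covered by the union of intervals."""
    cov = coverage_track(intervals, length, resolution).values
    return cov / bin_lengths(length, resolution)


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Named interval lists per annotation category, 0-based half-open."""

    categories: dict[str, list[Interval]] = field(default_factory=dict)

    def add(self, category: str, interval: Interval) -> None:
        self.categories.setdefault(category, []).append(interval)

    def __getitem__(self, category: str) -> list[Interval]:
        return self.categories[category]

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    @property
    def names(self) -> list[str]:
        return list(self.categories)

    def all_intervals(self) -> list[Interval]:
        return [iv for ivs in self.categories.values() for iv in ivs]

    def on(self, chrom: str, category: str | None = None) -> list[Interval]:
        ivs = self.all_intervals() if category is None else self.categories.get(category, [])
        return [iv for iv in ivs if iv.chrom == chrom]

    def merged(self, *others: "AnnotationSet") -> "AnnotationSet":
        out = AnnotationSet({k: list(v) for k, v in self.categories.items()})
        for other in others:
            for k, v in other.categories.items():
                out.categories.setdefault(k, []).extend(v)
        return out

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cat, ivs in self.categories.items():
                for iv in ivs:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cat}\t0\t{iv.strand}\n")


_DIALECTS = ("bed", "gtf", "genbank", "repeatmasker_out")


def read_annotations(path: str | Path, dialect: str,
                     default_category: str | None = None) -> AnnotationSet:
    """Read annotation intervals, normalizing coordinates to 0-based half-open.

    Dialects: ``bed`` (native 0-based; category = name column), ``gtf``
    (1-based inclusive; category = feature column), ``genbank`` (feature
    table; category = feature type, with ``gene`` features defining the gene
    category), ``repeatmasker_out`` (1-based inclusive; category = repeat
    family, the part of the class/family column after the slash).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    out = AnnotationSet()
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
                cat = parts[3] if len(parts) > 3 else (default_category or "bed")
                strand = parts[5] if len(parts) > 5 else "."
                out.add(cat, Interval(parts[0], start, end, strand))
    elif dialect == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 8:
                    raise ValueError(f"{path}:{lineno}: GTF line needs >= 8 fields")
                try:
                    start, end = int(parts[3]), int(parts[4])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer GTF coordinates") from None
                out.add(parts[2], Interval(parts[0], start - 1, end, parts[6]))
    elif dialect == "genbank":
        from Bio import SeqIO
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type == "source":
                    continue
                category = "gene" if feat.type == "gene" else feat.type
                strand = {1: "+", -1: "-"}.get(feat.location.strand, ".")
                out.add(category, Interval(rec.id, int(feat.location.start),
                                           int(feat.location.end), strand))
    else:  # repeatmasker_out
        with open(path) as fh:
            lines = fh.readlines()
        for lineno, line in enumerate(lines[3:], 4):  # 3 header lines
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: RepeatMasker row needs >= 11 fields")
            try:
                start, end = int(parts[5]), int(parts[6])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer RepeatMasker coordinates") from None
            classfam = parts[10]
            family = classfam.split("/", 1)[1] if "/" in classfam else classfam
            strand = "-" if parts[8] in ("C", "-") else "+"
            out.add(family, Interval(parts[4], start - 1, end, strand))
    return out
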