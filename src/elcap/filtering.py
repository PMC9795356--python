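"""Post-alignment record filters: unmapped, multimapper, duplicate, improper pair.

Filters operate on a minimal :class:`AlignmentRecord` abstraction so they can
be driven from SAM/BAM via pysam or constructed directly in tests. Input must
be coordinate-sorted (the native duplicate pass relies on it). Drop reasons
are exhaustive and mutually exclusive; the first matching reason wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam


@dataclass
class AlignmentRecord:
    """Minimal alignment facts needed for filtering and end extraction."""

    query_name: str
    chrom: Optional[str]
    start: int
    end: int
    strand: str
    is_paired: bool = False
    is_first_in_pair: bool = False
    is_second_in_pair: bool = False
    is_proper_pair: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    is_duplicate_marked: bool = False
    alignment_count: Optional[int] = None
    mapping_quality: int = 255
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignmentRecord":
        nh = seg.get_tag("NH") if seg.has_tag("NH") else None
        return cls(
            query_name=seg.query_name,
            chrom=seg.reference_name,
            start=seg.reference_start,
            end=seg.reference_end if not seg.is_unmapped else seg.reference_start + 1,
            strand="-" if seg.is_reverse else "+",
            is_paired=seg.is_paired,
            is_first_in_pair=seg.is_read1,
            is_second_in_pair=seg.is_read2,
            is_proper_pair=seg.is_proper_pair,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
            is_unmapped=seg.is_unmapped,
            is_duplicate_marked=seg.is_duplicate,
            alignment_count=int(nh) if nh is not None else None,
            mapping_quality=seg.mapping_quality,
            mate_chrom=seg.next_reference_name if seg.is_paired else None,
            mate_start=seg.next_reference_start if seg.is_paired else None,
        )

    @property
    def aligned_length(self) -> int:
        return self.end - self.start

    def is_multimapper(self) -> bool:
        """NH-style alignment count preferred; MAPQ-0 fallback when absent."""
        if self.alignment_count is not None:
            return self.alignment_count > 1
        return self.mapping_quality == 0


def read_sam(path: str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file."""
    with pysam.AlignmentFile(path, "r") as handle:
        for seg in handle:
            yield AlignmentRecord.from_pysam(seg)


@dataclass
class FilterStats:
    """Exhaustive, mutually exclusive drop counts; retained + drops == input."""

    input: int = 0
    retained: int = 0
    unmapped: int = 0
    secondary_supplementary: int = 0
    multimapper: int = 0
    duplicate: int = 0
    improper_pair: int = 0
    missing_mate: int = 0
    short: int = 0

    def dropped(self) -> int:
        return (
            self.unmapped + self.secondary_supplementary + self.multimapper
            + self.duplicate + self.improper_pair + self.missing_mate + self.short
        )

    def check(self) -> None:
        if self.retained + self.dropped() != self.input:
            raise AssertionError(
                f"filter accounting broken: {self.retained} retained + "
                f"{self.dropped()} dropped != {self.input} input"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            k: getattr(self, k)
            for k in (
                "input", "retained", "unmapped", "secondary_supplementary",
                "multimapper", "duplicate", "improper_pair", "missing_mate", "short",
            )
        }


class UnsortedInputError(ValueError):
    pass


def _check_sorted(records: Iterable[AlignmentRecord]) -> Iterator[AlignmentRecord]:
    seen_chroms: dict[str, int] = {}
    last_chrom: Optional[str] = None
    last_start = -1
    for rec in records:
        if rec.is_unmapped or rec.chrom is None:
            yield rec
            continue
        if rec.chrom != last_chrom:
            if rec.chrom in seen_chroms:
                raise UnsortedInputError(
                    f"record {rec.query_name}: chromosome {rec.chrom} re-appears; "
                    "input is not coordinate-sorted"
                )
            seen_chroms[rec.chrom] = 1
            last_chrom, last_start = rec.chrom, rec.start
        elif rec.start < last_start:
            raise UnsortedInputError(
                f"record {rec.query_name} at {rec.chrom}:{rec.start} is out of "
                f"order (previous start {last_start})"
            )
        else:
            last_start = rec.start
        yield rec


def deduplicate(
    records: Iterable[AlignmentRecord], mode: str = "single"
) -> tuple[list[AlignmentRecord], int, int]:
    """Drop exact coordinate duplicates, keeping the first record per key.

    Single-end key: (chrom, start, end, strand). Paired: mates are paired by
    query name; key = (chrom, fragment start, fragment end, first-in-pair
    strand) on the union span of the two mates. Idempotent.

    Returns (retained records, n duplicate records dropped, n records dropped
    for a missing mate).
    """
    retained: list[AlignmentRecord] = []
    n_dup = 0
    n_missing = 0
    if mode == "single":
        seen: set[tuple] = set()
        for rec in records:
            key = (rec.chrom, rec.start, rec.end, rec.strand)
            if key in seen:
                n_dup += 1
            else:
                seen.add(key)
                retained.append(rec)
        return retained, n_dup, n_missing

    by_name: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.query_name not in by_name:
            order.append(rec.query_name)
        by_name.setdefault(rec.query_name, []).append(rec)
    seen_pairs: set[tuple] = set()
    for name in order:
        mates = by_name[name]
        r1 = next((m for m in mates if m.is_first_in_pair), None)
        r2 = next((m for m in mates if m.is_second_in_pair), None)
        if r1 is None or r2 is None:
            n_missing += len(mates)
            continue
        frag_start = min(r1.start, r2.start)
        frag_end = max(r1.end, r2.end)
        key = (r1.chrom, frag_start, frag_end, r1.strand)
        if key in seen_pairs:
            n_dup += len(mates)
        else:
            seen_pairs.add(key)
            retained.extend(mates)
    return retained, n_dup, n_missing


def filter_alignments(
    records: Iterable[AlignmentRecord],
    mode: str = "single",
    min_length: int = 0,
    keep_duplicates: bool = False,
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Apply the post-alignment filters in order and account for every record.

    Drop order: unmapped; secondary/supplementary; multimapper (alignment
    count > 1, or MAPQ 0 when no count field); improper pair (paired mode);
    optional minimum aligned length; native duplicate removal last.
    ``keep_duplicates`` skips the duplicate pass (diagnostic mode: distinct
    fragments sharing exact coordinates are indistinguishable from PCR
    duplicates, so dedup necessarily collapses them too).
    """
    if mode not in {"single", "paired"}:
        raise ValueError(f"unknown mode {mode!r}")
    stats = FilterStats()
    survivors: list[AlignmentRecord] = []
    for rec in _check_sorted(records):
        stats.input += 1
        if rec.is_unmapped:
            stats.unmapped += 1
        elif rec.is_secondary or rec.is_supplementary:
            stats.secondary_supplementary += 1
        elif rec.is_multimapper():
            stats.multimapper += 1
        elif mode == "paired" and not rec.is_proper_pair:
            stats.improper_pair += 1
        elif min_length and rec.aligned_length < min_length:
            stats.short += 1
        else:
            survivors.append(rec)
    if keep_duplicates:
        retained = survivors
    else:
        retained, n_dup, n_missing = deduplicate(survivors, mode)
        stats.duplicate = n_dup
        stats.missing_mate = n_missing
    stats.retained = len(retained)
    stats.check()
    return retained, stats
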