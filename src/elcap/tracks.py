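"""Single-bp coverage tracks: accumulation, replicate merging, bedGraph/bigWig IO.

Tracks hold per-chromosome integer count arrays allocated lazily, so only
chromosomes carrying signal cost memory. Zero positions are never serialized;
consumers treat absent as zero. Replicates are merged by summing raw counts
before any normalization — density scaling happens at the profile level.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pyBigWig

from .filtering import AlignmentRecord
from .snr import SnrEvent


class CoverageTrack:
    """Per-bp non-negative counts over a genome, one strand (or both)."""

    def __init__(
        self,
        genome: Mapping[str, int],
        strand_label: str = ".",
        level: str = "snr",
    ) -> None:
        if strand_label not in {"+", "-", ".", "both"}:
            raise ValueError(f"invalid strand label {strand_label!r}")
        self.genome = dict(genome)
        self.strand_label = strand_label
        self.level = level
        self._data: dict[str, np.ndarray] = {}

    def _array(self, chrom: str) -> np.ndarray:
        if chrom not in self.genome:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if chrom not in self._data:
            self._data[chrom] = np.zeros(self.genome[chrom], dtype=np.int64)
        return self._data[chrom]

    def add(self, chrom: str, position: int, weight: int = 1) -> None:
        arr = self._array(chrom)
        if not (0 <= position < arr.size):
            raise ValueError(
                f"position {chrom}:{position} outside chromosome of "
                f"length {arr.size}"
            )
        arr[position] += weight

    def add_span(self, chrom: str, start: int, end: int, weight: int = 1) -> None:
        arr = self._array(chrom)
        if start < 0 or end > arr.size or start >= end:
            raise ValueError(f"span {chrom}:{start}-{end} outside chromosome")
        arr[start:end] += weight

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Counts over [start, end); positions off-chromosome read as zero."""
        if chrom not in self.genome:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        out = np.zeros(end - start, dtype=np.int64)
        clen = self.genome[chrom]
        lo, hi = max(start, 0), min(end, clen)
        if lo < hi and chrom in self._data:
            out[lo - start : hi - start] = self._data[chrom][lo:hi]
        return out

    def mass(self) -> int:
        return int(sum(int(a.sum()) for a in self._data.values()))

    def nonzero(self) -> dict[str, np.ndarray]:
        return {c: np.flatnonzero(a) for c, a in self._data.items() if a.any()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.genome != other.genome:
            return False
        chroms = set(self._data) | set(other._data)
        for c in chroms:
            a = self._data.get(c)
            b = other._data.get(c)
            if a is None:
                a = np.zeros(self.genome[c], dtype=np.int64)
            if b is None:
                b = np.zeros(self.genome[c], dtype=np.int64)
            if not np.array_equal(a, b):
                return False
        return True


def accumulate_snr_track(
    events: Iterable[SnrEvent], genome: Mapping[str, int]
) -> tuple[CoverageTrack, CoverageTrack]:
    """One (+, −) track pair; each event adds its weight at exactly one base."""
    plus = CoverageTrack(genome, "+", "snr")
    minus = CoverageTrack(genome, "-", "snr")
    for ev in events:
        track = plus if ev.strand == "+" else minus
        try:
            track.add(ev.chrom, ev.position, ev.weight)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"event off genome: {ev}") from exc
    return plus, minus


def accumulate_read_track(
    records: Iterable[AlignmentRecord],
    genome: Mapping[str, int],
    mode: str = "single",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Read-level coverage: +1 over each aligned span on the nascent-RNA strand.

    Single-end: the record's own span and strand. Paired: one span per
    fragment (union of the two mates, paired by query name) on the
    first-in-pair alignment strand (FR assumption).
    """
    plus = CoverageTrack(genome, "+", "read")
    minus = CoverageTrack(genome, "-", "read")
    if mode == "single":
        for rec in records:
            track = plus if rec.strand == "+" else minus
            track.add_span(rec.chrom, rec.start, rec.end)
        return plus, minus
    pairs: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        pairs.setdefault(rec.query_name, []).append(rec)
    for name, mates in pairs.items():
        r1 = next((m for m in mates if m.is_first_in_pair), None)
        if r1 is None:
            raise ValueError(f"pair {name} lacks a first-in-pair record")
        start = min(m.start for m in mates)
        end = max(m.end for m in mates)
        track = plus if r1.strand == "+" else minus
        track.add_span(r1.chrom, start, end)
    return plus, minus


def merge_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Positionwise sum of replicate tracks; genomes and strands must match."""
    if not tracks:
        raise ValueError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if t.genome != first.genome:
            raise ValueError("cannot merge tracks over different genomes")
        if t.strand_label != first.strand_label:
            raise ValueError("cannot merge tracks with different strand labels")
    merged = CoverageTrack(first.genome, first.strand_label, first.level)
    for t in tracks:
        for chrom, arr in t._data.items():
            merged._array(chrom)[:] += arr
    return merged


def unstranded(plus: CoverageTrack, minus: CoverageTrack) -> CoverageTrack:
    """Positionwise sum of the two strand tracks."""
    if plus.genome != minus.genome:
        raise ValueError("strand tracks disagree on genome")
    out = CoverageTrack(plus.genome, "both", plus.level)
    for t in (plus, minus):
        for chrom, arr in t._data.items():
            out._array(chrom)[:] += arr
    return out


# ---------------------------------------------------------------------------
# serialization


def _runs(arr: np.ndarray):
    """Yield (start, end, value) runs of equal nonzero values."""
    if not arr.any():
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate(([0], change, [arr.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        v = arr[lo]
        if v != 0:
            yield int(lo), int(hi), int(v)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """4-column bedGraph, 0-based half-open, sorted, equal-value runs merged."""
    with open(path, "w") as out:
        for chrom in track.genome:
            arr = track._data.get(chrom)
            if arr is None:
                continue
            for lo, hi, v in _runs(arr):
                out.write(f"{chrom}\t{lo}\t{hi}\t{v}\n")


def read_bedgraph(
    path: str, genome: Mapping[str, int], strand_label: str = ".", level: str = "snr"
) -> CoverageTrack:
    track = CoverageTrack(genome, strand_label, level)
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, lo, hi, v = line.split()[:4]
            if chrom not in genome:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            track.add_span(chrom, int(lo), int(hi), int(float(v)))
    return track


def write_bigwig(track: CoverageTrack, path: str) -> None:
    """Single-bp-resolution bigWig (one interval per equal-value run)."""
    bw = pyBigWig.open(path, "w")
    try:
        bw.addHeader([(c, int(l)) for c, l in track.genome.items()])
        for chrom in track.genome:
            arr = track._data.get(chrom)
            if arr is None:
                continue
            starts, ends, values = [], [], []
            for lo, hi, v in _runs(arr):
                starts.append(lo)
                ends.append(hi)
                values.append(float(v))
            if starts:
                bw.addEntries(
                    [chrom] * len(starts), starts, ends=ends, values=values
                )
    finally:
        bw.close()


def read_bigwig(
    path: str, genome: Optional[Mapping[str, int]] = None,
    strand_label: str = ".", level: str = "snr",
) -> CoverageTrack:
    bw = pyBigWig.open(path)
    try:
        sizes = dict(bw.chroms()) if genome is None else dict(genome)
        track = CoverageTrack(sizes, strand_label, level)
        for chrom in bw.chroms():
            for lo, hi, v in bw.intervals(chrom) or []:
                track.add_span(chrom, int(lo), int(hi), int(round(v)))
    finally:
        bw.close()
    return track
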