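"""Single-nucleotide-resolution events: the last base incorporated by RNAPII.

Each retained read (single-end) or fragment (paired-end) yields exactly one
event at the nascent RNA's 3' end. For unpaired reads this is the alignment's
3' end on its own strand. For FR pairs the second mate's 5' end marks the
fragment 3' end, and because the second mate aligns antisense to the RNA the
event strand is the OPPOSITE of its alignment strand. 5'/3' are defined on
the alignment's orientation: the 5' end of a − alignment is its rightmost
aligned base. Ends come from the aligned span, so soft-clipped bases never
shift an event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .filtering import AlignmentRecord


@dataclass(frozen=True)
class SnrEvent:
    """One genomic base + nascent-RNA strand, with a count weight."""

    chrom: str
    position: int
    strand: str
    weight: int = 1

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative event position {self.position}")
        if self.weight < 1:
            raise ValueError(f"event weight must be >= 1, got {self.weight}")


def snr_single_end(record: AlignmentRecord) -> SnrEvent:
    """3' end of an unpaired read: end − 1 on +, start on −; strand unchanged."""
    if record.is_paired:
        raise ValueError(
            f"record {record.query_name} is paired; use snr_paired_end"
        )
    if record.is_unmapped:
        raise ValueError(f"record {record.query_name} is unmapped")
    position = record.end - 1 if record.strand == "+" else record.start
    return SnrEvent(record.chrom, position, record.strand)


def snr_paired_end(record: AlignmentRecord) -> Optional[SnrEvent]:
    """5' end of the second-in-pair, strand flipped; first-in-pair yields nothing."""
    if not record.is_paired:
        raise ValueError(
            f"record {record.query_name} is unpaired; use snr_single_end"
        )
    if record.is_first_in_pair:
        return None
    if not record.is_second_in_pair:
        raise ValueError(
            f"record {record.query_name} is neither first nor second in pair"
        )
    if record.strand == "+":
        position, strand = record.start, "-"
    else:
        position, strand = record.end - 1, "+"
    return SnrEvent(record.chrom, position, strand)


def extract_snr(
    records: Iterable[AlignmentRecord], mode: str = "single"
) -> tuple[list[SnrEvent], int]:
    """One event per retained read (single) or pair (paired); returns (events, n)."""
    if mode not in {"single", "paired"}:
        raise ValueError(f"unknown mode {mode!r}")
    events: list[SnrEvent] = []
    for rec in records:
        if mode == "single":
            events.append(snr_single_end(rec))
        else:
            ev = snr_paired_end(rec)
            if ev is not None:
                events.append(ev)
    return events, len(events)


def write_bed6(events: Iterable[SnrEvent], path: str) -> None:
    """Dump events as BED6 (score = weight) for inspection."""
    with open(path, "w") as out:
        for i, ev in enumerate(events):
            out.write(
                f"{ev.chrom}\t{ev.position}\t{ev.position + 1}\tsnr{i}\t"
                f"{ev.weight}\t{ev.strand}\n"
            )
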