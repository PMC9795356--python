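"""Gene-model geometry: GTF parsing, representative transcripts, analysis regions.

All internal coordinates are 0-based half-open (BED convention); GTF input is
converted from its 1-based inclusive convention on the way in. The transcript
end site (TES) of a gene on the + strand is the base ``end - 1``; "downstream"
is strand-aware and extends toward lower coordinates for − strand genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence, Union

STRANDS = frozenset({"+", "-", "."})

#: support-level rank used for transcripts lacking an annotated level.
#: Worse than the worst documented Ensembl level (5), so unevidenced models
#: are never preferred over evidenced ones.
UNSUPPORTED_LEVEL = 6


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a strand.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Region(NamedTuple):
    """A derived analysis region plus whether chromosome-bound clamping occurred."""

    interval: GenomicInterval
    clamped: bool


@dataclass
class TranscriptModel:
    """One transcript: ordered exons on a single chromosome and strand."""

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    support_level: Optional[int] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        self.exons = exons

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        """Genomic (left) start of the transcript span."""
        return self.exons[0].start

    @property
    def end(self) -> int:
        """Genomic (right) end of the transcript span, exclusive."""
        return self.exons[-1].end

    @property
    def width(self) -> int:
        """Genomic span TSS-to-TES, introns included."""
        return self.end - self.start

    @property
    def tss(self) -> int:
        """5'-most transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """3'-most transcribed base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def support_rank(self) -> int:
        return UNSUPPORTED_LEVEL if self.support_level is None else self.support_level

    def last_exon(self) -> GenomicInterval:
        """The 3'-most exon in transcription order."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;?')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs and attr_field.strip():
        raise GtfParseError(f"line {lineno}: malformed attribute string: {attr_field!r}")
    return attrs


def _parse_support_level(raw: Optional[str]) -> Optional[int]:
    # Ensembl writes e.g. "1", "NA", or "5 (assigned to previous version 3)".
    if raw is None:
        return None
    token = raw.split()[0] if raw.split() else ""
    return int(token) if token.isdigit() else None


def parse_gene_models(
    source: Union[str, IO[str], Iterable[str]],
    biotypes: Optional[set[str]] = frozenset({"protein_coding"}),
    chromosomes: Optional[Sequence[str]] = None,
) -> dict[str, list[TranscriptModel]]:
    """Parse exon features from GTF text into transcripts grouped by gene.

    Parameters
    ----------
    source
        Path to a GTF file, an open text handle, or an iterable of lines.
    biotypes
        Biotypes to retain (``gene_biotype`` attribute); ``None`` keeps all.
    chromosomes
        Optional chromosome whitelist; transcripts elsewhere are dropped.

    Returns
    -------
    dict mapping gene_id to its transcripts (each sorted by exon coordinate).
    """
    close = False
    if isinstance(source, str):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
    chrom_whitelist = set(chromosomes) if chromosomes is not None else None

    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, Optional[int], str]] = {}  # tid -> (gene, tsl, biotype)
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start1, end1, _, strand, _, attr_field = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_field, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without gene_id")
            biotype = attrs.get("gene_biotype", "protein_coding")
            if biotypes is not None and biotype not in biotypes:
                continue
            if chrom_whitelist is not None and chrom not in chrom_whitelist:
                continue
            tid = attrs["transcript_id"]
            try:
                start = int(start1) - 1  # GTF 1-based inclusive -> 0-based half-open
                end = int(end1)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            exons.setdefault(tid, []).append(GenomicInterval(chrom, start, end, strand))
            if tid not in meta:
                meta[tid] = (
                    attrs["gene_id"],
                    _parse_support_level(attrs.get("transcript_support_level")),
                    biotype,
                )
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, exon_list in exons.items():
        gene_id, tsl, biotype = meta[tid]
        genes.setdefault(gene_id, []).append(
            TranscriptModel(gene_id, tid, exon_list, tsl, biotype)
        )
    for models in genes.values():
        models.sort(key=lambda m: m.transcript_id)
    return genes


def select_representative(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick one transcript per gene: strongest (lowest) support level, ties broken
    by widest genomic span, then lexicographically smallest transcript_id."""
    if not transcripts:
        raise ValueError("cannot select a representative from an empty transcript set")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    return min(transcripts, key=lambda t: (t.support_rank, -t.width, t.transcript_id))


def write_gtf(genes: Mapping[str, list[TranscriptModel]], path: str) -> None:
    """Write exon-only GTF (1-based inclusive) for the given gene models."""
    with open(path, "w") as out:
        for gene_id in sorted(genes):
            for model in sorted(genes[gene_id], key=lambda m: m.transcript_id):
                tsl = "NA" if model.support_level is None else str(model.support_level)
                for exon in model.exons:
                    attrs = (
                        f'gene_id "{model.gene_id}"; '
                        f'transcript_id "{model.transcript_id}"; '
                        f'gene_biotype "{model.biotype}"; '
                        f'transcript_support_level "{tsl}";'
                    )
                    out.write(
                        f"{exon.chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{exon.strand}\t.\t{attrs}\n"
                    )


def read_chrom_sizes(source: Union[str, IO[str], Iterable[str]]) -> dict[str, int]:
    """Read a two-column chromosome-sizes file (name<TAB>length)."""
    close = False
    if isinstance(source, str):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
    sizes: dict[str, int] = {}
    try:
        for line in handle:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    return sizes


def write_bed6(regions: Iterable[tuple[str, GenomicInterval]], path: str) -> None:
    """Write named regions as BED6 (score column 0)."""
    with open(path, "w") as out:
        for name, iv in regions:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def _clamp(chrom: str, start: int, end: int, strand: str,
           genome: Optional[Mapping[str, int]]) -> Region:
    lo, hi = start, end
    clamped = False
    if lo < 0:
        lo, clamped = 0, True
    if genome is not None and chrom in genome and hi > genome[chrom]:
        hi, clamped = genome[chrom], True
    if lo >= hi:
        raise ValueError(
            f"region {chrom}:{start}-{end} lies fully off-chromosome after clamping"
        )
    return Region(GenomicInterval(chrom, lo, hi, strand), clamped)


def derive_regions(
    model: TranscriptModel,
    scheme: str,
    genome: Optional[Mapping[str, int]] = None,
    *,
    flank: int = 5000,
    length: int = 50000,
    anchor: Optional[int] = None,
) -> Region:
    """Derive an analysis region from a transcript model, strand-aware.

    Schemes
    -------
    ``body``
        Full TSS-to-TES genomic span.
    ``last_exon``
        3'-most exon in transcription order.
    ``downstream(length)``
        ``length`` bp immediately 3' of the TES (toward lower coordinates for −).
    ``tes_window(flank)``
        ± ``flank`` bp around the TES boundary.
    ``point_window(anchor, flank)``
        ± ``flank`` bp around an arbitrary anchor base.

    Windows running off the chromosome are clamped and the clamping is reported
    in the returned :class:`Region`; a fully off-chromosome window is an error.
    """
    chrom, strand = model.chrom, model.strand
    if scheme == "body":
        return _clamp(chrom, model.start, model.end, strand, genome)
    if scheme == "last_exon":
        exon = model.last_exon()
        return Region(exon, False)
    if scheme == "downstream":
        if strand == "+":
            return _clamp(chrom, model.end, model.end + length, strand, genome)
        return _clamp(chrom, model.start - length, model.start, strand, genome)
    if scheme == "tes_window":
        edge = model.end if strand == "+" else model.start
        return _clamp(chrom, edge - flank, edge + flank, strand, genome)
    if scheme == "point_window":
        if anchor is None:
            raise ValueError("point_window scheme requires an anchor position")
        return _clamp(chrom, anchor - flank, anchor + flank, strand, genome)
    raise ValueError(f"unknown region scheme {scheme!r}")
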