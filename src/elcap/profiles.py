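"""Anchored-window and scale-regions binning, aggregation, density scaling.

Two binning schemes mirror the standard metagene toolbox: ``point_window``
tiles a fixed ±flank around an anchor base, and ``scale_regions`` maps each
gene body linearly onto a fixed virtual length between two real flanks. All
bins are half-open and ordered in the direction of transcription (reversed
for − strand anchors); the anchor base falls in the first downstream bin.

Density scaling divides an aggregated profile by its sum so the area under
each sample's curve is 1, making binding *shapes* comparable across samples
that cannot be depth-normalized against each other (no spike-ins survive a
double-IP workflow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import TranscriptModel
from .tracks import CoverageTrack

TrackPair = tuple[CoverageTrack, CoverageTrack]


@dataclass(frozen=True)
class BinScheme:
    """Binning geometry. ``body_target_bp`` applies to scale_regions only."""

    kind: str
    flank_bp: int
    bin_bp: int
    body_target_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in {"point_window", "scale_regions"}:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.flank_bp % self.bin_bp:
            raise ValueError(
                f"flank {self.flank_bp} not divisible by bin {self.bin_bp}"
            )
        if self.kind == "scale_regions":
            if self.body_target_bp is None:
                raise ValueError("scale_regions requires body_target_bp")
            if self.body_target_bp % self.bin_bp:
                raise ValueError(
                    f"body target {self.body_target_bp} not divisible by "
                    f"bin {self.bin_bp}"
                )

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.bin_bp

    @property
    def body_bins(self) -> int:
        return 0 if self.body_target_bp is None else self.body_target_bp // self.bin_bp

    @property
    def n_bins(self) -> int:
        if self.kind == "point_window":
            return 2 * self.flank_bins
        return 2 * self.flank_bins + self.body_bins


#: binning geometries used throughout: metagene (±5 kb flanks, body scaled to
#: 15 kb, 100 bp bins), TES window (±5 kb, 100 bp), polyA window (±2 kb, 40 bp)
METAGENE_SCHEME = BinScheme("scale_regions", 5_000, 100, 15_000)
TES_SCHEME = BinScheme("point_window", 5_000, 100)
POLYA_SCHEME = BinScheme("point_window", 2_000, 40)


def _sense_values(
    tracks: TrackPair, chrom: str, start: int, end: int, strand: str
) -> np.ndarray:
    plus, minus = tracks
    if strand == "+":
        return plus.values(chrom, start, end).astype(float)
    if strand == "-":
        return minus.values(chrom, start, end).astype(float)
    return (plus.values(chrom, start, end) + minus.values(chrom, start, end)).astype(float)


def bin_point_window(
    tracks: TrackPair,
    chrom: str,
    anchor: int,
    strand: str,
    flank_bp: int,
    bin_bp: int,
) -> np.ndarray:
    """Mean per-bp sense-strand signal in 2·flank/bin bins around an anchor.

    Bins run 5'→3' in transcription direction; the anchor base sits in the
    first downstream bin. Window portions off the chromosome contribute zeros.
    """
    if flank_bp % bin_bp:
        raise ValueError(f"flank {flank_bp} not divisible by bin {bin_bp}")
    if strand == "-":
        start, end = anchor + 1 - flank_bp, anchor + 1 + flank_bp
    else:
        start, end = anchor - flank_bp, anchor + flank_bp
    vals = _sense_values(tracks, chrom, start, end, strand)
    if strand == "-":
        vals = vals[::-1]
    return vals.reshape(-1, bin_bp).mean(axis=1)


def bin_scaled_gene(
    tracks: TrackPair, model: TranscriptModel, scheme: BinScheme
) -> np.ndarray:
    """Flank + scaled-body + flank bin vector for one gene, sense strand only.

    The body (TSS..TES genomic span) is mapped linearly onto
    ``body_target_bp`` with proportional-overlap weighting: each genomic base
    contributes to every virtual bin its image spans, so a delta stays a
    delta and total body mass is conserved (Σ body bins × L/n_bins == mass,
    with L the genomic body length). Uniform coverage v yields every body
    bin = v, whatever the gene length.
    """
    if scheme.kind != "scale_regions":
        raise ValueError("bin_scaled_gene requires a scale_regions scheme")
    chrom, strand = model.chrom, model.strand
    if chrom not in tracks[0].genome:
        raise ValueError(f"gene chromosome {chrom!r} absent from track genome")
    L = model.width
    f = scheme.flank_bp

    body = _sense_values(tracks, chrom, model.start, model.end, strand)
    if strand == "+":
        up = _sense_values(tracks, chrom, model.start - f, model.start, strand)
        down = _sense_values(tracks, chrom, model.end, model.end + f, strand)
    else:
        up = _sense_values(tracks, chrom, model.end, model.end + f, strand)[::-1]
        down = _sense_values(tracks, chrom, model.start - f, model.start, strand)[::-1]
        body = body[::-1]

    nb = scheme.body_bins
    g = L / nb  # genomic bp per virtual bin (may be fractional)
    cum = np.concatenate(([0.0], np.cumsum(body)))
    edges = np.interp(np.arange(nb + 1) * g, np.arange(L + 1), cum)
    body_bins = np.diff(edges) / g

    up_bins = up.reshape(-1, scheme.bin_bp).mean(axis=1)
    down_bins = down.reshape(-1, scheme.bin_bp).mean(axis=1)
    return np.concatenate([up_bins, body_bins, down_bins])


@dataclass
class ProfileMatrix:
    """Regions × bins raw mean-per-bp signal under one scheme."""

    region_ids: list[str]
    bins: np.ndarray  # shape (n_regions, scheme.n_bins)
    scheme: BinScheme
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.ndim != 2 or self.bins.shape != (len(self.region_ids), self.scheme.n_bins):
            raise ValueError(
                f"matrix shape {self.bins.shape} does not match "
                f"{len(self.region_ids)} regions x {self.scheme.n_bins} bins"
            )
        if (self.bins < 0).any():
            raise ValueError("profile matrix values must be non-negative")


@dataclass
class DensityProfile:
    """Area-normalized aggregate profile; bins sum to 1."""

    bins: np.ndarray
    scheme: BinScheme
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if abs(self.bins.sum() - 1.0) > 1e-9:
            raise ValueError(f"density profile sums to {self.bins.sum()}, not 1")


def compute_point_matrix(
    tracks: TrackPair,
    anchors: Sequence[tuple[str, str, int, str]],
    scheme: BinScheme,
    sample_label: str = "",
) -> ProfileMatrix:
    """Bin a point_window scheme over (id, chrom, anchor, strand) tuples."""
    rows = [
        bin_point_window(tracks, chrom, pos, strand, scheme.flank_bp, scheme.bin_bp)
        for _, chrom, pos, strand in anchors
    ]
    ids = [a[0] for a in anchors]
    return ProfileMatrix(ids, np.vstack(rows) if rows else np.empty((0, scheme.n_bins)),
                         scheme, sample_label)


def compute_scaled_matrix(
    tracks: TrackPair,
    models: Sequence[TranscriptModel],
    scheme: BinScheme = METAGENE_SCHEME,
    sample_label: str = "",
) -> ProfileMatrix:
    """Bin a scale_regions scheme over representative transcript models."""
    rows = [bin_scaled_gene(tracks, m, scheme) for m in models]
    ids = [m.gene_id for m in models]
    return ProfileMatrix(ids, np.vstack(rows) if rows else np.empty((0, scheme.n_bins)),
                         scheme, sample_label)


def aggregate_matrix(matrix: ProfileMatrix, stat: str = "mean") -> np.ndarray:
    """Columnwise aggregate over regions: mean (default), sum, or median."""
    if matrix.bins.shape[0] == 0:
        raise ValueError("cannot aggregate an empty profile matrix")
    if stat == "mean":
        return matrix.bins.mean(axis=0)
    if stat == "sum":
        return matrix.bins.sum(axis=0)
    if stat == "median":
        return np.median(matrix.bins, axis=0)
    raise ValueError(f"unknown aggregation statistic {stat!r}")


def density_scale(
    profile: np.ndarray, scheme: Optional[BinScheme] = None, sample_label: str = ""
) -> DensityProfile:
    """Divide a raw profile by its sum (area under the curve becomes 1)."""
    profile = np.asarray(profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        raise ValueError("cannot density-scale an all-zero profile")
    if scheme is None:
        scheme = BinScheme("point_window", profile.size // 2, 1)
    return DensityProfile(profile / total, scheme, sample_label)


def write_matrix_tsv(matrix: ProfileMatrix, path: str) -> None:
    """Regions as rows, bins as columns."""
    with open(path, "w") as out:
        header = "\t".join(f"bin{i}" for i in range(matrix.scheme.n_bins))
        out.write(f"region_id\t{header}\n")
        for rid, row in zip(matrix.region_ids, matrix.bins):
            out.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
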