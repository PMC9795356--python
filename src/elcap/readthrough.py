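"""Per-gene readthrough ratios and rank-based group comparisons.

Readthrough is quantified as RPK (single-nucleotide events per kilobase) in
the 50 kb downstream of the most distal TES divided by RPK in the last exon.
The ratio is invariant to global scaling of the track, so samples can be
compared without between-sample depth normalization. Genes whose last exon
carries no signal produce an infinite or undefined ratio and are dropped
from statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import GenomicInterval, TranscriptModel, derive_regions
from .profiles import TrackPair, _sense_values


@dataclass
class ReadthroughResult:
    gene_id: str
    rpk_downstream: float
    rpk_last_exon: float
    ratio: Optional[float]
    status: str  # ok | infinite_dropped | empty_dropped
    neighbor_overlap: bool = False


def region_rpk(tracks: TrackPair, region: GenomicInterval) -> float:
    """Sense-strand event count per kilobase of (clamped) region length."""
    if len(region) <= 0:
        raise ValueError("zero-length region")
    total = _sense_values(tracks, region.chrom, region.start, region.end, region.strand).sum()
    return float(total) / (len(region) / 1_000.0)


def readthrough_ratio(
    tracks: TrackPair,
    model: TranscriptModel,
    downstream_bp: int = 50_000,
    genome: Optional[Mapping[str, int]] = None,
    all_transcripts: Optional[Sequence[TranscriptModel]] = None,
    other_gene_bodies: Optional[Sequence[GenomicInterval]] = None,
) -> ReadthroughResult:
    """RPK(downstream window) / RPK(last exon) for one gene.

    The downstream window starts at the most distal TES over
    ``all_transcripts`` when given (else the representative model's TES); the
    last exon comes from the representative model. When
    ``other_gene_bodies`` is supplied, overlap of the downstream window with
    any neighboring gene body is flagged (kept, not excluded).
    """
    genome = genome if genome is not None else tracks[0].genome
    distal = model
    if all_transcripts:
        if model.strand == "+":
            distal = max(all_transcripts, key=lambda t: t.end)
        else:
            distal = min(all_transcripts, key=lambda t: t.start)
    down = derive_regions(distal, "downstream", genome, length=downstream_bp).interval
    last = model.last_exon()
    rpk_down = region_rpk(tracks, down)
    rpk_last = region_rpk(tracks, last)
    flagged = bool(other_gene_bodies) and any(down.overlaps(b) for b in other_gene_bodies)
    if rpk_last > 0:
        return ReadthroughResult(
            model.gene_id, rpk_down, rpk_last, rpk_down / rpk_last, "ok", flagged
        )
    status = "infinite_dropped" if rpk_down > 0 else "empty_dropped"
    return ReadthroughResult(model.gene_id, rpk_down, rpk_last, None, status, flagged)


def usable_ratios(results: Sequence[ReadthroughResult]) -> np.ndarray:
    """Ratios with ok status only — infinite/empty results never enter statistics."""
    return np.array([r.ratio for r in results if r.status == "ok"], dtype=float)


def compare_groups(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided Wilcoxon comparison of two ratio sets.

    Unpaired: rank-sum (Mann-Whitney U), exact null below 25 per group when
    tie-free, normal approximation with continuity correction otherwise.
    Paired: signed-rank on gene-matched vectors. Returns (statistic, p).
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 usable ratios per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length vectors")
        stat, p = sps.wilcoxon(a, b, alternative="two-sided")
        return float(stat), float(p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Brute-force two-sided rank-sum p by enumerating group assignments.

    Intended as an independent small-n check (n + m choose n enumerations);
    assumes no cross-group ties. Uses the symmetry of the U null about nm/2:
    p = P(|U' − nm/2| ≥ |U − nm/2|).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)
    pooled = a + b

    def u_stat(group_a: Sequence[float], group_b: Sequence[float]) -> float:
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x in group_a for y in group_b
        )

    mu = n * m / 2.0
    observed = abs(u_stat(a, b) - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        sel = set(idx)
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n + m) if i not in sel]
        if abs(u_stat(ga, gb) - mu) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def results_table(results: Sequence[ReadthroughResult]) -> "object":
    """Per-gene results as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "rpk_downstream": [r.rpk_downstream for r in results],
            "rpk_last_exon": [r.rpk_last_exon for r in results],
            "ratio": [math.nan if r.ratio is None else r.ratio for r in results],
            "status": [r.status for r in results],
            "neighbor_overlap": [r.neighbor_overlap for r in results],
        }
    )
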