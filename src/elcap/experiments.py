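"""Self-contained simulation experiments that exercise the whole pipeline.

Each experiment generates its own synthetic inputs at the study's stated
conditions, runs the full processing route (SAM in, statistics out), and
returns the measured quantities. They back both the acceptance checks and
the reproduction script, so the numbers they report are always recomputed
from scratch.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import parse_gene_models, read_chrom_sizes, select_representative
from .filtering import filter_alignments, read_sam
from .proteomics import (
    classify_enriched,
    enrichment_test,
    filter_min_peptides,
    impute_log_intensities,
    load_protein_groups,
)
from .readthrough import compare_groups, readthrough_ratio, usable_ratios
from .simulate import (
    LfqSimParams,
    OccupancyParams,
    occupancy_density,
    simulate_annotation,
    simulate_lfq_table,
    simulate_reads,
    write_sam,
)
from .snr import extract_snr
from .tracks import accumulate_snr_track


@dataclass
class SnrOracleResult:
    n_fragments: int
    single_agreement_pct: float
    paired_agreement_pct: float
    paired_vs_single_pct: float
    conservation_residual: int


def _one_gene_density(strand: str = "+"):
    from .annotation import GenomicInterval, TranscriptModel

    gene = TranscriptModel(
        "G_oracle", "T1", [GenomicInterval("chr1", 50_000, 70_000, strand)], 1
    )
    return occupancy_density(gene, OccupancyParams(), horizon=25_000)


def snr_oracle_experiment(seed: int, n_reads: int = 10_000) -> SnrOracleResult:
    """Score SNR extraction against the simulator's truth table.

    Simulates one gene's occupancy, draws ``n_reads`` fragments in single-end
    and paired-end dialects (no duplicates/multimappers), pushes both through
    a SAM round trip, filtering, and end extraction, and reports the
    percentage of events matching the truth 3' ends exactly, the
    cross-dialect event agreement, and the retained-reads == events ==
    track-mass conservation residual.
    """
    genome = {"chr1": 200_000}
    density = _one_gene_density()
    agreement: dict[str, float] = {}
    events_by_mode: dict[str, list] = {}
    residual = 0
    with tempfile.TemporaryDirectory() as tmp:
        for mode in ("single", "paired"):
            records, truth = simulate_reads(
                density, n_reads, mode, seed, chrom_sizes=genome
            )
            path = os.path.join(tmp, f"{mode}.sam")
            write_sam(records, genome, path)
            retained, stats = filter_alignments(
                read_sam(path), mode, keep_duplicates=True
            )
            events, n_events = extract_snr(retained, mode)
            got = sorted((e.chrom, e.position, e.strand) for e in events)
            expected = sorted(zip(truth["chrom"], truth["pos3"], truth["strand"]))
            agreement[mode] = 100.0 * sum(
                g == e for g, e in zip(got, expected)
            ) / n_reads
            events_by_mode[mode] = got
            plus, minus = accumulate_snr_track(events, genome)
            n_units = stats.retained if mode == "single" else stats.retained // 2
            residual += abs(n_units - n_events)
            residual += abs(n_events - (plus.mass() + minus.mass()))
    cross = sum(
        a == b for a, b in zip(events_by_mode["single"], events_by_mode["paired"])
    )
    return SnrOracleResult(
        n_fragments=n_reads,
        single_agreement_pct=agreement["single"],
        paired_agreement_pct=agreement["paired"],
        paired_vs_single_pct=100.0 * cross / n_reads,
        conservation_residual=residual,
    )


@dataclass
class ReadthroughRecovery:
    n_genes_per_group: int
    reads_per_gene: int
    median_high: float
    median_low: float
    wilcoxon_p: float
    n_usable_high: int
    n_usable_low: int


def _group_ratios(
    readthrough_weight: float,
    n_genes: int,
    reads_per_gene: int,
    seed: int,
) -> np.ndarray:
    """Simulate one gene set end-to-end and return its usable readthrough ratios."""
    gtf, sizes = simulate_annotation(
        n_genes, [9_000_000, 9_000_000], seed=seed, isolation_bp=55_000,
        gene_length_range=(2_000, 8_000),
    )
    genes = parse_gene_models(gtf.splitlines())
    genome = read_chrom_sizes(io.StringIO(sizes))
    body_weight = 0.8 - readthrough_weight
    params = OccupancyParams(
        tss_peak_weight=0.1,
        body_weight=body_weight,
        tes_peak_weight=0.1,
        readthrough_weight=readthrough_weight,
        readthrough_decay=5_000.0,
    )
    records = []
    for i, gid in enumerate(sorted(genes)):
        rep = select_representative(genes[gid])
        density = occupancy_density(rep, params, horizon=25_000)
        recs, _ = simulate_reads(
            density, reads_per_gene, "single", seed + 17 * (i + 1),
            chrom_sizes=genome, name_prefix=f"{gid}.",
        )
        records.extend(recs)
    with tempfile.TemporaryDirectory() as tmp:
        path = os.path.join(tmp, "reads.sam")
        write_sam(records, genome, path)
        retained, _ = filter_alignments(read_sam(path), "single")
    events, _ = extract_snr(retained, "single")
    tracks = accumulate_snr_track(events, genome)
    results = [
        readthrough_ratio(tracks, select_representative(genes[gid]),
                          genome=genome, all_transcripts=genes[gid])
        for gid in sorted(genes)
    ]
    return usable_ratios(results)


def readthrough_recovery_experiment(
    seed: int,
    n_genes: int = 200,
    reads_per_gene: int = 250,
    high_weight: float = 0.4,
    low_weight: float = 0.05,
) -> ReadthroughRecovery:
    """Recover a simulated readthrough difference between two gene sets.

    One set is simulated with a heavy readthrough tail, the other with a
    light one; every ratio is computed through the full pipeline and the two
    sets are compared with the two-sided rank-sum test.
    """
    high = _group_ratios(high_weight, n_genes, reads_per_gene, seed)
    low = _group_ratios(low_weight, n_genes, reads_per_gene, seed + 100_003)
    _, p = compare_groups(high, low)
    return ReadthroughRecovery(
        n_genes_per_group=n_genes,
        reads_per_gene=reads_per_gene,
        median_high=float(np.median(high)),
        median_low=float(np.median(low)),
        wilcoxon_p=float(p),
        n_usable_high=int(high.size),
        n_usable_low=int(low.size),
    )


@dataclass
class SpikeRecovery:
    n_background: int
    n_spiked: int
    spiked_enriched_pct: float
    background_enriched_pct: float


def spike_recovery_experiment(
    seed: int,
    n_background: int = 1_000,
    n_spiked: int = 50,
    log2_effect: float = 4.0,
    missing_rate: float = 0.3,
) -> SpikeRecovery:
    """Run the full volcano workflow on a spiked synthetic LFQ table.

    Two biological replicates with triplicate injections per side (n = 6
    observations), the default combined-peptide filter, down-shifted-Gaussian
    imputation, Student t-test, and the strict log2 diff > 2 / −log2 p > 2
    enrichment call. Reports recovery among spiked proteins and the false
    call rate among background proteins.
    """
    params = LfqSimParams(
        n_background=n_background, n_spiked=n_spiked, log2_effect=log2_effect,
        missing_rate=missing_rate, seed=seed,
    )
    df = simulate_lfq_table(params)
    truth = dict(zip(df["Protein IDs"], df["is_spiked"]))
    table = load_protein_groups(df)
    table = filter_min_peptides(table, 3)
    table = impute_log_intensities(table, seed=seed + 1)
    results = classify_enriched(enrichment_test(table))
    is_spiked = results["protein_id"].map(truth).to_numpy(dtype=bool)
    enriched = results["enriched"].to_numpy(dtype=bool)
    n_sp = int(is_spiked.sum())
    n_bg = int((~is_spiked).sum())
    return SpikeRecovery(
        n_background=n_bg,
        n_spiked=n_sp,
        spiked_enriched_pct=100.0 * enriched[is_spiked].mean() if n_sp else 0.0,
        background_enriched_pct=100.0 * enriched[~is_spiked].mean() if n_bg else 0.0,
    )


def worked_example_ttest() -> tuple[float, float]:
    """The 3-vs-3 volcano worked example: log2 (10,12,11) vs (5,6,7).

    Returns (log2_diff, p) computed by the pipeline's enrichment test.
    """
    cols = {}
    for j, (t_val, c_val) in enumerate(zip((10.0, 12.0, 11.0), (5.0, 6.0, 7.0)), 1):
        cols[f"LFQ intensity IP_r1_i{j}"] = [2.0 ** t_val]
        cols[f"LFQ intensity control_r1_i{j}"] = [2.0 ** c_val]
    df = pd.DataFrame({
        "Protein IDs": ["P1"], "Gene names": ["G1"],
        "Peptides r1": [5], "Peptides r2": [5], **cols,
    })
    table = impute_log_intensities(load_protein_groups(df), seed=0)
    res = enrichment_test(table)
    return float(res.loc[0, "log2_diff"]), float(res.loc[0, "p_value"])
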