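"""Synthetic data with the statistical structure the pipeline assumes.

Three generators: gene annotation (GTF + chromosome sizes), strand-specific
nascent reads whose fragment 3' ends follow a per-gene RNAPII occupancy
density (SAM, single- or paired-end FR), and label-free-quantitation protein
tables with spiked enrichment and missing values. Every generator is
seed-deterministic and emits a plain-TSV truth table sufficient to score the
downstream stage it feeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .annotation import GenomicInterval, TranscriptModel


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    n_genes: int,
    chrom_lengths: Union[Mapping[str, int], Sequence[int]],
    seed: int,
    *,
    gene_length_range: tuple[int, int] = (2_000, 20_000),
    gap_range: tuple[int, int] = (8_000, 25_000),
    isolation_bp: Optional[int] = None,
    margin: int = 10_000,
    max_transcripts: int = 3,
) -> tuple[str, str]:
    """Generate a synthetic exon-level GTF and matching chromosome-sizes text.

    Genes are laid out left-to-right per chromosome with random intergenic
    gaps; with ``isolation_bp`` set, consecutive gene bodies are separated by
    at least that many bases so a downstream window of that length never
    reaches a neighbouring gene body. Each gene gets 1..``max_transcripts``
    transcripts with varying support levels (the first spans the full gene).
    """
    if isinstance(chrom_lengths, Mapping):
        layout = dict(chrom_lengths)
    else:
        layout = {f"chr{i + 1}": int(l) for i, l in enumerate(chrom_lengths)}
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    placed = 0
    gene_idx = 0
    for chrom in layout:
        cursor = margin
        while placed < n_genes:
            if isolation_bp is not None:
                gap = int(rng.integers(isolation_bp + 1_000, isolation_bp + 6_000))
            else:
                gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            start = cursor + gap
            end = start + glen
            if end + margin > layout[chrom]:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gene_idx:05d}"
            n_tx = int(rng.integers(1, max_transcripts + 1))
            for t in range(n_tx):
                if t == 0:
                    t_start, t_end = start, end
                else:
                    shrink_l = int(rng.integers(0, max(1, glen // 4)))
                    shrink_r = int(rng.integers(0, max(1, glen // 4)))
                    t_start, t_end = start + shrink_l, end - shrink_r
                    if t_end - t_start < 200:
                        t_start, t_end = start, end
                tsl = int(rng.integers(1, 6)) if rng.random() > 0.15 else None
                if t == 0:
                    tsl = 1  # full-length model always well supported
                exons = _random_exons(chrom, t_start, t_end, strand, rng)
                tid = f"{gene_id}.T{t + 1}"
                tsl_str = "NA" if tsl is None else str(tsl)
                for ex in exons:
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                        f'gene_biotype "protein_coding"; '
                        f'transcript_support_level "{tsl_str}";'
                    )
                    lines.append(
                        f"{ex.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\t{attrs}"
                    )
            cursor = end
            placed += 1
            gene_idx += 1
        if placed >= n_genes:
            break
    if placed < n_genes:
        raise ValueError(
            f"chromosome layout too small: placed {placed} of {n_genes} genes"
        )
    sizes = "".join(f"{c}\t{l}\n" for c, l in layout.items())
    return "\n".join(lines) + "\n", sizes


def _random_exons(chrom, start, end, strand, rng) -> list[GenomicInterval]:
    length = end - start
    max_exons = 4 if length >= 1_000 else 1
    k = int(rng.integers(1, max_exons + 1))
    if k == 1:
        return [GenomicInterval(chrom, start, end, strand)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * (k - 1), replace=False))
    bounds = [0, *cuts.tolist(), length]
    return [
        GenomicInterval(chrom, start + bounds[2 * i], start + bounds[2 * i + 1], strand)
        for i in range(k)
    ]


# ---------------------------------------------------------------------------
# occupancy density


@dataclass
class OccupancyParams:
    """Mixture weights and shapes of the per-gene RNAPII occupancy density.

    The density is a mixture over [TSS − upstream flank, TES + horizon]:
    a Gaussian promoter-proximal pause peak, a uniform gene body, a Gaussian
    TES peak, an exponential readthrough tail beyond the TES (mean
    ``readthrough_decay`` bp), and an optional Gaussian bump at an intronic
    polyA position. Weights must be non-negative and sum to 1.
    """

    tss_peak_weight: float = 0.15
    tss_peak_sd: float = 100.0
    tss_peak_offset: float = 50.0
    body_weight: float = 0.55
    tes_peak_weight: float = 0.15
    tes_peak_sd: float = 200.0
    readthrough_weight: float = 0.15
    readthrough_decay: float = 5_000.0
    intronic_pa_position: Optional[float] = None
    intronic_pa_weight: float = 0.0
    intronic_pa_sd: float = 150.0

    def __post_init__(self) -> None:
        weights = [
            self.tss_peak_weight,
            self.body_weight,
            self.tes_peak_weight,
            self.readthrough_weight,
            self.intronic_pa_weight,
        ]
        if any(w < 0 for w in weights):
            raise ValueError("occupancy weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"occupancy weights must sum to 1, got {sum(weights)}")
        if self.readthrough_decay <= 0:
            raise ValueError("readthrough_decay must be > 0")
        if self.tss_peak_sd <= 0 or self.tes_peak_sd <= 0 or self.intronic_pa_sd <= 0:
            raise ValueError("peak standard deviations must be > 0")
        if self.intronic_pa_weight > 0 and self.intronic_pa_position is None:
            raise ValueError("intronic_pa_weight > 0 requires intronic_pa_position")


@dataclass
class OccupancyDensity:
    """Per-bp 3'-end probability over a genomic window; sums to 1.

    ``probs[i]`` is the probability of genomic base ``origin + i`` on
    ``strand``.
    """

    chrom: str
    strand: str
    origin: int
    probs: np.ndarray
    tss: int
    tes: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample n genomic 3'-end positions."""
        idx = rng.choice(self.probs.size, size=n, p=self.probs)
        return self.origin + idx

    def mass_beyond_tes(self) -> float:
        """Fraction of density strictly 3' of the TES base (strand-aware)."""
        tes_idx = self.tes - self.origin
        if self.strand == "+":
            return float(self.probs[tes_idx + 1 :].sum())
        return float(self.probs[:tes_idx].sum())


def occupancy_density(
    model: TranscriptModel,
    params: OccupancyParams,
    *,
    upstream_flank: int = 5_000,
    horizon: Optional[int] = None,
) -> OccupancyDensity:
    """Build the per-bp 3'-end density for one gene, strand-aware.

    ``horizon`` is how far beyond the TES the readthrough tail is supported;
    it must cover at least three decay lengths (default: five).
    """
    if horizon is None:
        horizon = int(5 * params.readthrough_decay)
    if horizon < 3 * params.readthrough_decay:
        raise ValueError(
            f"horizon {horizon} bp shorter than tail support "
            f"(3 x decay = {3 * params.readthrough_decay:.0f} bp)"
        )
    L = model.width
    # transcription coordinates: t = 0 at the TSS base, increasing 3'-ward
    t = np.arange(-upstream_flank, L + horizon, dtype=float)
    dens = np.zeros_like(t)

    def add_gauss(weight: float, center: float, sd: float) -> None:
        if weight <= 0:
            return
        comp = np.exp(-0.5 * ((t - center) / sd) ** 2)
        total = comp.sum()
        if total > 0:
            dens[:] += weight * comp / total

    add_gauss(params.tss_peak_weight, params.tss_peak_offset, params.tss_peak_sd)
    if params.body_weight > 0:
        body = (t >= 0) & (t < L)
        dens[body] += params.body_weight / body.sum()
    add_gauss(params.tes_peak_weight, L - 1, params.tes_peak_sd)
    if params.readthrough_weight > 0:
        tail = t >= L
        comp = np.exp(-(t[tail] - L) / params.readthrough_decay)
        dens[tail] += params.readthrough_weight * comp / comp.sum()
    if params.intronic_pa_weight > 0:
        add_gauss(
            params.intronic_pa_weight, params.intronic_pa_position, params.intronic_pa_sd
        )
    dens /= dens.sum()

    if model.strand == "+":
        origin = model.start - upstream_flank
        probs = dens
    else:
        # genomic position = TSS - t; reverse so probs is genomic left-to-right
        origin = model.start - horizon
        probs = dens[::-1].copy()
    # clip any window portion falling before base 0
    if origin < 0:
        probs = probs[-origin:].copy()
        probs /= probs.sum()
        origin = 0
    return OccupancyDensity(model.chrom, model.strand, origin, probs, model.tss, model.tes)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    density: OccupancyDensity,
    n_reads: int,
    mode: str,
    seed: int,
    *,
    duplicate_rate: float = 0.0,
    multimapper_rate: float = 0.0,
    fragment_length_range: tuple[int, int] = (20, 90),
    chrom_sizes: Optional[Mapping[str, int]] = None,
    name_prefix: str = "frag",
) -> tuple[list, pd.DataFrame]:
    """Sample fragments from an occupancy density and emit aligned records.

    Each fragment's 3' end is drawn from ``density``; its length is uniform on
    ``fragment_length_range`` (insert sizes of short nascent-RNA libraries).
    Single-end mode emits one record per fragment on the nascent-RNA strand;
    paired mode emits an FR pair where the second mate's 5' end sits at the
    fragment 3' end and its alignment strand is opposite to the RNA strand.
    Duplicates are exact coordinate copies under fresh names; multimappers
    carry an NH tag > 1 (primary record only).

    Returns ``(records, truth)`` where records are unsorted pysam-compatible
    dicts (see :func:`write_sam`) and truth is one row per fragment.
    """
    if density.probs.size == 0:
        raise ValueError("empty occupancy density")
    if mode not in {"single", "paired"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pos3 = density.sample(n_reads, rng)
    lo, hi = fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=n_reads)
    is_mm = rng.random(n_reads) < multimapper_rate
    nh = np.where(is_mm, rng.integers(2, 6, size=n_reads), 1)
    is_dup = rng.random(n_reads) < duplicate_rate

    chrom = density.chrom
    strand = density.strand
    clen = None if chrom_sizes is None else chrom_sizes.get(chrom)

    rows = []
    records = []
    for i in range(n_reads):
        p3 = int(pos3[i])
        flen = int(lengths[i])
        if strand == "+":
            start, end = max(0, p3 - flen + 1), p3 + 1
        else:
            start, end = p3, p3 + flen
            if clen is not None:
                end = min(end, clen)
        name = f"{name_prefix}{i:06d}"
        copies = 2 if is_dup[i] else 1
        rows.append(
            {
                "fragment_id": name,
                "chrom": chrom,
                "pos3": p3,
                "strand": strand,
                "start": start,
                "end": end,
                "multimapper": bool(is_mm[i]),
                "n_records": copies,
            }
        )
        for c in range(copies):
            qname = name if c == 0 else f"{name}.dup{c}"
            records.extend(
                _make_records(qname, chrom, start, end, strand, int(nh[i]), mode)
            )
    truth = pd.DataFrame(rows)
    return records, truth


def _make_records(qname, chrom, start, end, strand, nh, mode):
    length = end - start
    if mode == "single":
        flag = 16 if strand == "-" else 0
        return [
            {
                "qname": qname, "flag": flag, "chrom": chrom, "start": start,
                "cigar": f"{length}M", "nh": nh, "mate_start": -1, "tlen": 0,
            }
        ]
    # FR pair: R1 on the fragment strand, R2 opposite, both spanning the fragment
    r1_rev = strand == "-"
    r1_flag = 0x1 | 0x2 | 0x40 | (0x10 if r1_rev else 0) | (0x20 if not r1_rev else 0)
    r2_flag = 0x1 | 0x2 | 0x80 | (0x10 if not r1_rev else 0) | (0x20 if r1_rev else 0)
    tlen = length if strand == "+" else -length
    return [
        {
            "qname": qname, "flag": r1_flag, "chrom": chrom, "start": start,
            "cigar": f"{length}M", "nh": nh, "mate_start": start, "tlen": tlen,
        },
        {
            "qname": qname, "flag": r2_flag, "chrom": chrom, "start": start,
            "cigar": f"{length}M", "nh": nh, "mate_start": start, "tlen": -tlen,
        },
    ]


def write_sam(records: list, chrom_sizes: Mapping[str, int], path: str) -> None:
    """Write records coordinate-sorted as SAM text with an @SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    order = {c: i for i, c in enumerate(chrom_sizes)}
    records = sorted(records, key=lambda r: (order[r["chrom"]], r["start"], r["qname"], r["flag"]))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r["qname"]
            seg.flag = r["flag"]
            seg.reference_name = r["chrom"]
            seg.reference_start = r["start"]
            seg.mapping_quality = 255
            seg.cigarstring = r["cigar"]
            if r["flag"] & 0x1:
                seg.next_reference_name = r["chrom"]
                seg.next_reference_start = r["mate_start"]
                seg.template_length = r["tlen"]
            seg.set_tag("NH", r["nh"])
            out.write(seg)


# ---------------------------------------------------------------------------
# LFQ tables


@dataclass
class LfqSimParams:
    """Parameters of the synthetic label-free quantitation table.

    Intensities are simulated on the log2 scale (protein means spread with sd
    ``intensity_sd`` across proteins; per-injection measurement noise
    ``noise_sd``) and written on the linear scale. Spiked proteins are shifted
    up by ``log2_effect`` in the first (test) group. Missingness is
    left-censored, as in real label-free data: within each injection column a
    cell's missing probability falls linearly with its intensity rank
    (2·rate·(1 − percentile)), so low-abundance measurements drop out
    preferentially while the marginal missing fraction stays ``missing_rate``.
    Missing cells are written as 0, the MaxQuant convention.
    """

    n_background: int = 1_000
    n_spiked: int = 50
    log2_effect: float = 4.0
    intensity_mean: float = 25.0
    intensity_sd: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.3
    peptide_count_range: tuple[int, int] = (1, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_background <= 0 or self.n_spiked < 0:
            raise ValueError("protein counts must be positive")


def simulate_lfq_table(
    params: LfqSimParams,
    groups: Sequence[str] = ("IP", "control"),
    n_replicates: int = 2,
    n_injections: int = 3,
) -> pd.DataFrame:
    """Simulate a protein-group quantitation table.

    Columns: ``Protein IDs``, ``Gene names``, per-replicate ``Peptides r<k>``,
    per-injection ``LFQ intensity <group>_r<rep>_i<inj>``, empty ``Reverse``
    and ``Potential contaminant`` flags, and a truth flag ``is_spiked``.
    Spiked proteins are shifted in the FIRST group of ``groups``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if n_replicates * n_injections < 2:
        raise ValueError("need at least 2 injections per group")
    rng = np.random.default_rng(params.seed)
    n = params.n_background + params.n_spiked
    spiked = np.zeros(n, dtype=bool)
    spiked[params.n_background :] = True
    mu = rng.normal(params.intensity_mean, params.intensity_sd, size=n)

    data: dict[str, object] = {
        "Protein IDs": [f"P{i:05d}" for i in range(n)],
        "Gene names": [f"GENE{i}" for i in range(n)],
    }
    plo, phi = params.peptide_count_range
    for r in range(1, n_replicates + 1):
        data[f"Peptides r{r}"] = rng.integers(plo, phi + 1, size=n)
    for g_idx, g in enumerate(groups):
        shift = params.log2_effect if g_idx == 0 else 0.0
        for r in range(1, n_replicates + 1):
            for j in range(1, n_injections + 1):
                log2_vals = mu + shift * spiked + rng.normal(0, params.noise_sd, size=n)
                linear = np.exp2(log2_vals)
                # left-censored missingness: rank percentile within the column
                pct = (log2_vals.argsort().argsort() + 0.5) / n
                p_missing = np.clip(2 * params.missing_rate * (1 - pct), 0, 1)
                missing = rng.random(n) < p_missing
                linear[missing] = 0.0
                data[f"LFQ intensity {g}_r{r}_i{j}"] = linear
    data["Reverse"] = [""] * n
    data["Potential contaminant"] = [""] * n
    data["is_spiked"] = spiked
    return pd.DataFrame(data)
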