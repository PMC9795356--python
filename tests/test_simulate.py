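"""Synthetic-data generators: determinism, density shape, truth-table contracts."""

import io

import numpy as np
import pandas as pd
import pytest

from elcap.annotation import derive_regions, parse_gene_models, read_chrom_sizes, select_representative
from elcap.simulate import (
    LfqSimParams,
    OccupancyParams,
    occupancy_density,
    simulate_annotation,
    simulate_lfq_table,
    simulate_reads,
    write_sam,
)

from conftest import make_transcript


class TestAnnotationGenerator:
    def test_seed_determinism(self):
        a = simulate_annotation(20, [2_000_000], seed=7)
        b = simulate_annotation(20, [2_000_000], seed=7)
        assert a == b

    def test_layout_too_small_errors(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation(500, [100_000], seed=0)

    def test_gene_count_recovered_by_parser(self, synthetic_annotation):
        _, _, genes, _ = synthetic_annotation
        assert len(genes) == 50

    def test_isolation_keeps_downstream_windows_off_neighbours(self, synthetic_annotation):
        _, _, genes, genome = synthetic_annotation
        reps = {g: select_representative(ts) for g, ts in genes.items()}
        bodies = {
            g: (m.chrom, m.start, m.end) for g, m in reps.items()
        }
        for g, m in reps.items():
            down = derive_regions(m, "downstream", genome, length=50_000).interval
            for og, (chrom, s, e) in bodies.items():
                if og == g or chrom != down.chrom:
                    continue
                assert not (down.start < e and s < down.end), (g, og)


class TestOccupancyDensity:
    def test_pure_body_is_uniform(self):
        gene = make_transcript(exons=((10_000, 20_000),))
        params = OccupancyParams(
            tss_peak_weight=0, body_weight=1, tes_peak_weight=0, readthrough_weight=0
        )
        d = occupancy_density(gene, params)
        body = d.probs[d.probs > 0]
        assert body.size == gene.width
        assert np.allclose(body, 1.0 / gene.width)
        # window positions outside the body carry nothing
        assert d.origin + np.flatnonzero(d.probs)[0] == gene.start

    def test_density_sums_to_one_and_tail_mass_matches_weight(self):
        gene = make_transcript(exons=((50_000, 80_000),))
        params = OccupancyParams(
            tss_peak_weight=0, body_weight=0.5, tes_peak_weight=0,
            readthrough_weight=0.5, readthrough_decay=5_000,
        )
        d = occupancy_density(gene, params, horizon=30_000)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.mass_beyond_tes() == pytest.approx(0.5, abs=0.01)

    def test_minus_strand_density_is_mirror_of_plus(self):
        span = 200_000
        plus = make_transcript(exons=((50_000, 80_000),), strand="+")
        minus = make_transcript(exons=((span - 80_000, span - 50_000),), strand="-")
        params = OccupancyParams()
        dp = occupancy_density(plus, params, horizon=25_000)
        dm = occupancy_density(minus, params, horizon=25_000)
        assert np.allclose(dp.probs, dm.probs[::-1])

    def test_short_horizon_is_an_error(self):
        gene = make_transcript(exons=((50_000, 60_000),))
        with pytest.raises(ValueError, match="horizon"):
            occupancy_density(gene, OccupancyParams(), horizon=1_000)

    def test_intronic_pa_bump_adds_mass_at_position(self):
        gene = make_transcript(exons=((50_000, 80_000),))
        params = OccupancyParams(
            tss_peak_weight=0, body_weight=0.7, tes_peak_weight=0,
            readthrough_weight=0.1, intronic_pa_weight=0.2,
            intronic_pa_position=5_000, intronic_pa_sd=100,
        )
        d = occupancy_density(gene, params)
        window = d.probs[(5_000 + 5_000 - 500):(5_000 + 5_000 + 500)]  # flank + offset
        assert window.sum() > 0.19  # the bump's mass sits where it was placed


class TestReadSimulator:
    @pytest.fixture(scope="class")
    def density(self):
        gene = make_transcript(exons=((50_000, 70_000),))
        return occupancy_density(gene, OccupancyParams(), horizon=25_000)

    def test_truth_rows_and_record_counts(self, density):
        genome = {"chr1": 200_000}
        recs, truth = simulate_reads(density, 1_000, "single", seed=3, chrom_sizes=genome)
        assert len(truth) == 1_000 and len(recs) == 1_000
        recs_p, truth_p = simulate_reads(density, 1_000, "paired", seed=3, chrom_sizes=genome)
        assert len(truth_p) == 1_000 and len(recs_p) == 2_000

    def test_same_seed_gives_identical_sam_bytes(self, density, tmp_path):
        genome = {"chr1": 200_000}
        paths = []
        for i in (1, 2):
            recs, _ = simulate_reads(density, 500, "single", seed=9, chrom_sizes=genome)
            p = tmp_path / f"run{i}.sam"
            write_sam(recs, genome, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_paired_truth_three_prime_ends_match_single_mode(self, density):
        genome = {"chr1": 200_000}
        _, t_single = simulate_reads(density, 800, "single", seed=5, chrom_sizes=genome)
        _, t_paired = simulate_reads(density, 800, "paired", seed=5, chrom_sizes=genome)
        assert (t_single["pos3"] == t_paired["pos3"]).all()
        assert (t_single["strand"] == t_paired["strand"]).all()

    def test_fragment_lengths_respect_insert_range(self, density):
        _, truth = simulate_reads(density, 2_000, "single", seed=6)
        lengths = truth["end"] - truth["start"]
        assert lengths.min() >= 1 and lengths.max() <= 90
        interior = truth[truth["start"] > 0]
        assert ((interior["end"] - interior["start"]) >= 20).all()

    def test_empirical_3prime_histogram_converges_to_density(self, density):
        # total-variation distance on 100-bp bins: per-bp TV at this depth is
        # dominated by multinomial sampling noise, binned TV is not
        _, truth = simulate_reads(density, 100_000, "single", seed=8)
        counts = np.bincount(truth["pos3"] - density.origin, minlength=density.probs.size)
        n = density.probs.size // 100 * 100
        empirical = counts[:n].reshape(-1, 100).sum(axis=1) / counts.sum()
        expected = density.probs[:n].reshape(-1, 100).sum(axis=1)
        tv = 0.5 * np.abs(empirical - expected).sum()
        assert tv < 0.05

    def test_empty_density_is_an_error(self, density):
        bad = type(density)(density.chrom, density.strand, 0, np.array([]), 0, 0)
        with pytest.raises(ValueError, match="empty"):
            simulate_reads(bad, 10, "single", seed=0)


class TestLfqGenerator:
    def test_seed_determinism_and_tsv_stability(self):
        params = LfqSimParams(n_background=100, n_spiked=10, seed=42)
        a = simulate_lfq_table(params).to_csv(sep="\t", index=False)
        b = simulate_lfq_table(params).to_csv(sep="\t", index=False)
        assert a == b

    def test_missing_fraction_matches_rate(self):
        params = LfqSimParams(n_background=900, n_spiked=0, missing_rate=0.3, seed=1)
        table = simulate_lfq_table(params)
        cells = table.filter(like="LFQ intensity").to_numpy()
        assert cells.size >= 10_000
        zero_frac = (cells == 0).mean()
        assert zero_frac == pytest.approx(0.3, abs=0.02)

    def test_zero_effect_leaves_groups_identical_in_expectation(self):
        params = LfqSimParams(
            n_background=400, n_spiked=100, log2_effect=0.0, missing_rate=0.0, seed=2
        )
        table = simulate_lfq_table(params)
        ip = np.log2(table.filter(like="LFQ intensity IP").to_numpy())
        ctrl = np.log2(table.filter(like="LFQ intensity control").to_numpy())
        assert ip.mean() == pytest.approx(ctrl.mean(), abs=0.05)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            simulate_lfq_table(LfqSimParams(), groups=("only",))

    def test_truth_flags_spiked_rows(self):
        params = LfqSimParams(n_background=50, n_spiked=5, seed=3)
        table = simulate_lfq_table(params)
        assert table["is_spiked"].sum() == 5
        assert (table["is_spiked"].to_numpy()[-5:]).all()
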