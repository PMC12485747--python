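import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import cohort_with_tracts
from invstruct import (
    GenotypeMatrix,
    SimConfig,
    draw_cohort,
    genotype_inversion,
    simulate_inversion_snps,
    simulate_tag_genotypes,
)
from invstruct.core import Interval
from invstruct.recomb import (
    GroupStats,
    ScanConfig,
    flag_ambiguous_windows,
    group_stats,
    scan,
    windowed_pc1,
)
from invstruct.simulate import SIM_CONTIG

REGION = Interval(SIM_CONTIG, 140_000, 500_000)
SCAN = ScanConfig(region=REGION)


def _pipeline(cfg):
    truth = draw_cohort(cfg)
    snps = simulate_inversion_snps(truth, cfg)
    tags, _ = simulate_tag_genotypes(truth, cfg)
    calls = genotype_inversion(tags)
    return truth, snps, calls


@pytest.fixture(scope="module")
def clean_cohort(two_hap_config):
    return _pipeline(two_hap_config)


class TestWindowedPC1:
    def test_three_groups_separate_everywhere(self, clean_cohort):
        """At divergence 0.8 every window's 5-95% envelopes are disjoint."""
        truth, snps, calls = clean_cohort
        result = windowed_pc1(snps, calls, SCAN)
        stats = group_stats(result, SCAN)
        ambiguous = flag_ambiguous_windows(result, stats, SCAN)
        assert not ambiguous.any()

    def test_orientation_puts_h2_above_h1(self, clean_cohort):
        truth, snps, calls = clean_cohort
        result = windowed_pc1(snps, calls, SCAN)
        geno = np.array(result.genotypes)
        for w in range(result.n_windows):
            h11 = result.pc1[geno == "H1/H1", w].mean()
            h22 = result.pc1[geno == "H2/H2", w].mean()
            het = result.pc1[geno == "H1/H2", w].mean()
            assert h11 < het < h22

    def test_allele_coding_flip_leaves_scores_unchanged(self, clean_cohort):
        """Flipping 0<->2 at every site is absorbed by the orientation rule."""
        truth, snps, calls = clean_cohort
        flipped = GenotypeMatrix(
            snps.samples, snps.positions, (2 - snps.data).astype(np.int8),
            contig=snps.contig,
        )
        r1 = windowed_pc1(snps, calls, SCAN)
        r2 = windowed_pc1(flipped, calls, SCAN)
        assert np.allclose(r1.pc1, r2.pc1, equal_nan=True)

    def test_variant_poor_window_is_ambiguous(self, clean_cohort):
        truth, snps, calls = clean_cohort
        # drop all sites from one window
        keep = ~(
            (snps.positions >= 200_000) & (snps.positions < 210_000)
        )
        result = windowed_pc1(snps.subset_sites(keep), calls, SCAN)
        w = int((200_000 - REGION.start) // SCAN.window)
        assert result.ambiguous[w]
        assert np.isnan(result.pc1[:, w]).all()

    def test_constant_window_is_ambiguous(self):
        """A window whose genotypes are identical for everyone is degenerate."""
        data = np.ones((20, 5), dtype=np.int8)
        positions = np.linspace(140_500, 149_500, 5).astype(int)
        gm = GenotypeMatrix([f"s{i}" for i in range(20)], positions, data)
        calls = genotype_inversion(
            GenotypeMatrix(
                gm.samples, np.arange(4),
                np.array([[0] * 4] * 10 + [[2] * 4] * 10, dtype=np.int8),
            )
        )
        cfg = ScanConfig(region=Interval("chr17", 140_000, 150_000))
        result = windowed_pc1(gm, calls, cfg)
        assert result.ambiguous.all()

    def test_determinism(self, clean_cohort):
        truth, snps, calls = clean_cohort
        r1 = windowed_pc1(snps, calls, SCAN)
        r2 = windowed_pc1(snps, calls, SCAN)
        assert np.array_equal(r1.pc1, r2.pc1, equal_nan=True)


class TestAmbiguity:
    def _stats(self, envelopes):
        rows = []
        for g, (lo, hi) in envelopes.items():
            rows.append(dict(window=0, genotype=g, n=10, mean=(lo + hi) / 2,
                             median=(lo + hi) / 2, q_low=lo, q_high=hi))
        return GroupStats(pd.DataFrame(rows))

    def _result(self):
        return dataclasses.replace  # unused helper placeholder

    def test_disjoint_envelopes_not_ambiguous(self):
        stats = self._stats({"H1/H1": (-3, -1), "H1/H2": (-0.5, 0.5), "H2/H2": (1, 3)})
        from invstruct.recomb import WindowPCAResult

        result = WindowPCAResult(
            samples=["a", "b"], genotypes=["H1/H1", "H2/H2"],
            starts=np.array([0]), ends=np.array([10_000]),
            pc1=np.zeros((2, 1)), variant_counts=np.array([10]),
            ambiguous=np.array([False]),
        )
        assert not flag_ambiguous_windows(result, stats, SCAN)[0]

    def test_overlapping_envelopes_ambiguous(self):
        stats = self._stats({"H1/H1": (-1, 0.2), "H1/H2": (0.1, 0.9), "H2/H2": (1, 3)})
        from invstruct.recomb import WindowPCAResult

        result = WindowPCAResult(
            samples=["a", "b"], genotypes=["H1/H1", "H2/H2"],
            starts=np.array([0]), ends=np.array([10_000]),
            pc1=np.zeros((2, 1)), variant_counts=np.array([10]),
            ambiguous=np.array([False]),
        )
        assert flag_ambiguous_windows(result, stats, SCAN)[0]

    def test_zero_divergence_makes_everything_ambiguous(self):
        cfg = SimConfig(
            n_individuals=80, haplotype_freqs={"H1.β1": 0.5, "H2.α1": 0.5},
            haplotype_divergence=0.0, snp_density=2.0, seed=8,
        )
        truth = draw_cohort(cfg)
        snps = simulate_inversion_snps(truth, cfg)
        # genotype labels must come from tag SNPs, which stay informative
        tags, _ = simulate_tag_genotypes(truth, cfg)
        calls = genotype_inversion(tags)
        result = windowed_pc1(snps, calls, SCAN)
        stats = group_stats(result, SCAN)
        ambiguous = flag_ambiguous_windows(result, stats, SCAN)
        assert ambiguous.mean() > 0.9


class TestEvents:
    def test_inliers_everywhere_no_reassignment(self, clean_cohort):
        truth, snps, calls = clean_cohort
        events, *_ = scan(snps, calls, SCAN)
        assert events == []

    def test_single_isolated_outlier_window_not_reassigned(self, two_hap_config):
        """A 10 kb tract covers one window: below the min-run threshold."""
        truth, cfg, tracts = cohort_with_tracts(
            two_hap_config, [(250_000, 260_000)], donor="H1"
        )
        snps = simulate_inversion_snps(truth, cfg)
        tags, _ = simulate_tag_genotypes(truth, cfg)
        events, *_ = scan(snps, genotype_inversion(tags), SCAN)
        carrier = truth.sample_ids[tracts[0].individual]
        assert not any(e.sample == carrier for e in events)

    def test_interior_tract_detected_as_double(self, two_hap_config):
        truth, cfg, tracts = cohort_with_tracts(
            two_hap_config, [(250_000, 400_000)], donor="H1"
        )
        snps = simulate_inversion_snps(truth, cfg)
        tags, _ = simulate_tag_genotypes(truth, cfg)
        events, *_ = scan(snps, genotype_inversion(tags), SCAN)
        carrier = truth.sample_ids[tracts[0].individual]
        mine = [e for e in events if e.sample == carrier]
        assert len(mine) == 1
        e = mine[0]
        assert e.event_class == "double"
        assert e.original == "H1/H2" and e.reassigned == "H1/H1"
        assert abs(e.start - 250_000) <= 10_000 and abs(e.end - 400_000) <= 10_000

    def test_tract_reaching_boundary_is_single(self, two_hap_config):
        """A switch running to the region edge has no distal flank."""
        truth, cfg, tracts = cohort_with_tracts(
            two_hap_config, [(400_000, 500_000)], donor="H2", carrier_genotype="H1/H2"
        )
        snps = simulate_inversion_snps(truth, cfg)
        tags, _ = simulate_tag_genotypes(truth, cfg)
        events, *_ = scan(snps, genotype_inversion(tags), SCAN)
        carrier = truth.sample_ids[tracts[0].individual]
        mine = [e for e in events if e.sample == carrier]
        assert len(mine) == 1 and mine[0].event_class == "single"
        assert mine[0].reassigned == "H2/H2"

    def test_homozygote_tract_reassigned_to_het(self, two_hap_config):
        """An H1/H1 individual with one converted haplotype becomes locally
        heterozygous."""
        truth, cfg, tracts = cohort_with_tracts(
            two_hap_config, [(250_000, 350_000)], donor="H2",
            carrier_genotype="H1/H1",
        )
        snps = simulate_inversion_snps(truth, cfg)
        tags, _ = simulate_tag_genotypes(truth, cfg)
        events, *_ = scan(snps, genotype_inversion(tags), SCAN)
        carrier = truth.sample_ids[tracts[0].individual]
        mine = [e for e in events if e.sample == carrier]
        assert len(mine) == 1
        assert mine[0].reassigned == "H1/H2" and mine[0].event_class == "double"

    def test_sample_order_invariance(self, two_hap_config):
        truth, cfg, tracts = cohort_with_tracts(
            two_hap_config, [(250_000, 400_000)], donor="H1"
        )
        snps = simulate_inversion_snps(truth, cfg)
        tags, _ = simulate_tag_genotypes(truth, cfg)
        calls = genotype_inversion(tags)
        events_a, *_ = scan(snps, calls, SCAN)
        order = np.arange(truth.n)[::-1]
        shuffled = GenotypeMatrix(
            [snps.samples[i] for i in order], snps.positions, snps.data[order],
            contig=snps.contig,
        )
        events_b, *_ = scan(shuffled, [calls[i] for i in order], SCAN)
        key = lambda e: (e.sample, e.start, e.end, e.event_class)
        assert sorted(map(key, events_a)) == sorted(map(key, events_b))

    def test_population_annotation(self, two_hap_config):
        truth, cfg, tracts = cohort_with_tracts(
            two_hap_config, [(250_000, 400_000)], donor="H1"
        )
        snps = simulate_inversion_snps(truth, cfg)
        tags, _ = simulate_tag_genotypes(truth, cfg)
        pops = {s: "AFR" for s in truth.sample_ids}
        events, *_ = scan(snps, genotype_inversion(tags), SCAN, populations=pops)
        assert all(e.population == "AFR" for e in events)
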