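"""Tests for variant filtering, window counting, hotspot calling,
gene intersection and term enrichment."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from wgtkit import (
    FilterPolicy,
    GenomeWindow,
    HetGenomeSpec,
    call_hotspots,
    enrichment,
    filter_variants,
    gen_het_vcf,
    genes_in_hotspots,
    window_counts,
)
from wgtkit.errors import InputError
from wgtkit.io import GeneFeature, VariantSite


def _site(pos, chrom="chr1", het=True, dp=10, qual=50):
    return VariantSite(chrom, pos, het, dp, qual)


class TestFilter:
    LENGTHS = {"chr1": 1_000_000}

    def test_low_depth_removed(self):
        kept, _ = filter_variants([_site(10, dp=1)], FilterPolicy(), self.LENGTHS)
        assert kept == []

    def test_in_band_het_retained(self):
        kept, _ = filter_variants([_site(10, dp=10, qual=50)], FilterPolicy(), self.LENGTHS)
        assert len(kept) == 1

    def test_band_edges_inclusive_depth_exclusive_quality_floor(self):
        policy = FilterPolicy()
        keep2, _ = filter_variants([_site(1, dp=2)], policy, self.LENGTHS)
        keep20, _ = filter_variants([_site(1, dp=20)], policy, self.LENGTHS)
        keep21, _ = filter_variants([_site(1, dp=21)], policy, self.LENGTHS)
        q19, _ = filter_variants([_site(1, qual=19.9)], policy, self.LENGTHS)
        assert len(keep2) == len(keep20) == 1
        assert keep21 == [] and q19 == []

    def test_homozygous_excluded(self):
        kept, _ = filter_variants([_site(10, het=False)], FilterPolicy(), self.LENGTHS)
        assert kept == []

    def test_vcf_roundtrip_from_generator(self, tmp_path):
        spec = HetGenomeSpec({"chr1": 100_000}, 0.001, (), seed=4)
        path = tmp_path / "sim.vcf"
        text, _ = gen_het_vcf(spec, path)
        n_records = sum(1 for l in text.splitlines() if not l.startswith("#"))
        kept, lengths = filter_variants(path)
        assert len(kept) == n_records  # generator sits inside the filter band
        assert lengths == {"chr1": 100_000}

    def test_raising_quality_floor_never_retains_more(self, rng):
        sites = [
            _site(int(p), dp=float(d), qual=float(q))
            for p, d, q in zip(
                rng.integers(1, 10**6, 200),
                rng.integers(0, 30, 200),
                rng.uniform(0, 60, 200),
            )
        ]
        previous = math.inf
        for qual_min in (0, 10, 20, 30, 60):
            kept, _ = filter_variants(sites, FilterPolicy(qual_min=qual_min), self.LENGTHS)
            assert len(kept) <= previous
            previous = len(kept)


class TestWindows:
    def test_tiling_with_trailing_partial_window(self):
        sites = [_site(101), _site(250_001)]
        windows = window_counts(sites, {"chr1": 500_000})
        assert [(w.start, w.end, w.het_count) for w in windows] == [
            (0, 200_000, 1),
            (200_000, 400_000, 1),
            (400_000, 500_000, 0),
        ]

    def test_no_sites_all_zero(self):
        windows = window_counts([], {"chr1": 450_000})
        assert [w.het_count for w in windows] == [0, 0, 0]
        assert windows[-1].width == 50_000

    def test_counts_partition_sites_when_tumbling(self, rng):
        for _ in range(5):
            positions = rng.integers(1, 10**6 + 1, size=500)
            sites = [_site(int(p)) for p in positions]
            windows = window_counts(sites, {"chr1": 10**6})
            assert sum(w.het_count for w in windows) == len(sites)

    def test_boundary_site_goes_to_right_window(self):
        # 1-based position 200001 is 0-based 200000, first bp of window 2
        windows = window_counts([_site(200_001)], {"chr1": 400_000})
        assert [w.het_count for w in windows] == [0, 1]

    def test_site_beyond_chromosome_named_in_error(self):
        with pytest.raises(InputError, match="chr1:600000"):
            window_counts([_site(600_000)], {"chr1": 500_000})

    def test_overlapping_step_supported(self):
        windows = window_counts([_site(150_000)], {"chr1": 400_000}, step=100_000)
        covering = [w for w in windows if w.start <= 149_999 < w.end]
        assert all(w.het_count >= 1 for w in covering)
        assert len(covering) == 2


class TestCallHotspots:
    @staticmethod
    def _window(count, start=0, width=200_000, chrom="chr1"):
        return GenomeWindow(chrom, start, start + width, count)

    def test_cutoff_is_strict(self):
        result = call_hotspots([self._window(1001), self._window(1000, start=200_000)])
        flags = [w.is_hotspot for w in result.windows]
        assert flags == [True, False]
        assert result.n_hotspots == 1

    def test_partial_window_judged_by_rate(self):
        # 100-kb trailing window: 501 sites is >0.5% even though <=1000
        windows = [self._window(1200), self._window(501, start=200_000, width=100_000)]
        result = call_hotspots(windows)
        assert [w.is_hotspot for w in result.windows] == [True, True]
        windows = [self._window(1200), self._window(500, start=200_000, width=100_000)]
        assert [w.is_hotspot for w in call_hotspots(windows).windows] == [True, False]

    def test_fraction_of_het_sites_in_hotspots(self):
        result = call_hotspots([self._window(1500), self._window(500, start=200_000)])
        assert result.fraction_het_in_hotspots == pytest.approx(0.75)
        assert 0 <= result.fraction_het_in_hotspots <= 1

    def test_quantile_mode_flags_right_tail(self):
        windows = [self._window(c, start=i * 200_000) for i, c in enumerate([10] * 19 + [999])]
        result = call_hotspots(windows, mode="quantile", quantile=0.95)
        assert result.n_hotspots == 1
        assert result.windows[-1].is_hotspot

    def test_planted_hotspots_recovered_exactly_across_seeds(self):
        """Sensitivity and specificity are both 1.0 when the planted rate is
        10x background and both sit far from the cutoff."""
        planted = ("chr1", 400_000, 600_000, 0.01)  # 2000 sites expected per window
        for seed in range(20):
            spec = HetGenomeSpec({"chr1": 1_000_000}, 0.001, (planted,), seed=seed)
            text, truth = gen_het_vcf(spec)
            positions = [
                int(l.split("\t")[1]) for l in text.splitlines() if not l.startswith("#")
            ]
            sites = [_site(p) for p in positions]
            windows = window_counts(sites, {"chr1": 1_000_000})
            result = call_hotspots(windows)
            for w in result.windows:
                overlaps_truth = w.start < truth[0][2] and w.end > truth[0][1]
                assert w.is_hotspot == overlaps_truth, (seed, w.start)


class TestGenesInHotspots:
    HOT = [GenomeWindow("chr1", 0, 200_000, 1500, is_hotspot=True)]

    def _genes(self):
        return [
            GeneFeature("inside", "chr1", 149_999, 160_000),
            GeneFeature("outside", "chr1", 300_000, 310_000),
            GeneFeature("straddle", "chr1", 190_000, 210_000),
            GeneFeature("other_chrom", "chr2", 100, 200),
        ]

    def test_overlap_rules(self):
        hits = genes_in_hotspots(self.HOT, self._genes())
        assert hits == {"inside", "straddle"}

    def test_one_bp_overlap_counts(self):
        genes = [GeneFeature("g", "chr1", 199_999, 250_000)]
        assert genes_in_hotspots(self.HOT, genes) == {"g"}
        genes = [GeneFeature("g", "chr1", 200_000, 250_000)]
        assert genes_in_hotspots(self.HOT, genes) == set()


class TestEnrichment:
    def test_term_absent_from_gene_set_balanced_p_one(self):
        background = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(10)}
        term_map = {f"g{i}": {"T"} for i in range(10, 15)}
        table = enrichment(gene_set, background, term_map)
        row = table.iloc[0]
        assert row["a"] == 0
        assert row["p"] <= 1.0

    def test_p_equals_two_sided_hypergeometric_sum(self):
        # 2x2 table (5, 5, 10, 80): sum the probabilities of all tables
        # with the same margins that are no more likely than the observed
        background = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        with_term = list(range(5)) + list(range(20, 30))
        term_map = {f"g{i}": {"T"} for i in with_term}
        table = enrichment(gene_set, background, term_map)
        p = table.iloc[0]["p"]
        m, n_draw, k_total = 100, 10, 15
        probs = [hypergeom.pmf(k, m, k_total, n_draw) for k in range(0, 11)]
        observed = hypergeom.pmf(5, m, k_total, n_draw)
        expected = sum(pr for pr in probs if pr <= observed * (1 + 1e-9))
        assert p == pytest.approx(expected)
        assert table.iloc[0]["a"] == 5

    def test_adjusted_p_at_least_raw(self, rng):
        background = {f"g{i}" for i in range(200)}
        gene_set = set(f"g{i}" for i in rng.choice(200, 40, replace=False))
        term_map = {}
        for i in range(200):
            for t in range(5):
                if rng.random() < 0.2:
                    term_map.setdefault(f"g{i}", set()).add(f"T{t}")
        table = enrichment(gene_set, background, term_map)
        assert (table["p_adj"] >= table["p"] - 1e-12).all()

    def test_empty_background_rejected(self):
        with pytest.raises(InputError):
            enrichment(set(), set(), {})

    def test_gene_set_must_be_subset(self):
        with pytest.raises(InputError):
            enrichment({"a"}, {"b"}, {})
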