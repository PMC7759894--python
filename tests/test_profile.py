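"""Weighted population statistics, abundance, binning, counting helpers."""

import math

import numpy as np
import pytest

from conftest import random_sample

from hydropep.io_tables import PeptideRecord, ProteomeStats
from hydropep.profile import (
    bin_pcl,
    bin_pmw,
    bin_pz,
    combinatorial_space,
    fold_change,
    format_fold_change,
    histogram,
    relative_intensity,
    substring_count,
    summarize_sample,
    top_n,
    weighted_mean,
    weighted_sd,
)
from hydropep.properties import compute_properties


class TestWeightedMoments:
    def test_weighted_mean_hand_values(self):
        assert weighted_mean([4, 10], [1, 1]) == 7.0
        assert weighted_mean([4, 10], [3, 1]) == 5.5
        assert weighted_mean([5], [2e6]) == 5.0

    def test_weighted_mean_errors(self):
        with pytest.raises(ValueError):
            weighted_mean([1, 2], [0, 0])
        with pytest.raises(ValueError):
            weighted_mean([1, 2], [1])

    def test_weighted_sd_hand_values(self):
        assert weighted_sd([4, 10], [1, 1]) == pytest.approx(math.sqrt(18))
        assert weighted_sd([3, 3, 3], [1, 2, 3]) == 0.0
        assert weighted_sd([0, 0, 6], [1, 1, 1]) == pytest.approx(math.sqrt(12))

    def test_weighted_sd_needs_two_nonzero_weights(self):
        with pytest.raises(ValueError):
            weighted_sd([1, 2], [1, 0])

    def test_bounded_by_extremes(self, rng):
        for _ in range(20):
            vals = rng.normal(size=10)
            wts = rng.uniform(0.1, 5, size=10)
            mean = weighted_mean(vals, wts)
            assert vals.min() <= mean <= vals.max()
            assert weighted_sd(vals, wts) >= 0


class TestSummarize:
    def test_equal_weights_match_unweighted(self):
        records = [PeptideRecord("GGGG", "S", 5.0),
                   PeptideRecord("AAAAAAAAAA", "S", 5.0)]
        summary = summarize_sample(records)
        assert summary.pcl_avg == summary.pcl_avg_u == 7.0

    def test_brute_force_oracle(self, rng):
        """Naive per-peptide loop agrees to 1e-12 relative."""
        for _ in range(50):
            records = random_sample(rng, int(rng.integers(5, 200)))
            summary = summarize_sample(records)
            props = {r.sequence: compute_properties(r.sequence) for r in records}
            for attr, field in (("pcl_avg", "pcl"), ("pmw_avg", "pmw"),
                                ("pz_avg", "pz")):
                num = den = 0.0
                for rec in records:
                    num += getattr(props[rec.sequence], field) * rec.intensity
                    den += rec.intensity
                assert getattr(summary, attr) == pytest.approx(
                    num / den, rel=1e-12
                )
            # SD oracle for PCL
            mean = summary.pcl_avg
            m = sum(1 for r in records if r.intensity > 0)
            num = sum(r.intensity * (props[r.sequence].pcl - mean) ** 2
                      for r in records)
            den = (m - 1) / m * sum(r.intensity for r in records)
            assert summary.sd_pcl == pytest.approx(math.sqrt(num / den),
                                                   rel=1e-12)

    def test_intensity_scale_invariance(self, rng):
        records = random_sample(rng, 50)
        scaled = [PeptideRecord(r.sequence, r.sample, r.intensity * 1000)
                  for r in records]
        a, b = summarize_sample(records), summarize_sample(scaled)
        for attr in ("pcl_avg", "pmw_avg", "pz_avg", "sd_pcl", "sd_pmw", "sd_pz"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), rel=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            summarize_sample([])


class TestAbundance:
    def test_relative_intensity_percentages(self):
        records = [PeptideRecord("AAA", "S", 2e6),
                   PeptideRecord("CCC", "S", 98e6)]
        entries = relative_intensity(records)
        assert entries[0].sequence == "CCC" and entries[0].ri == 98.0
        assert entries[1].ri == 2.0

    def test_ties_break_lexicographically(self):
        records = [PeptideRecord(s, "S", 1e6) for s in ("CCC", "AAA", "BBB")]
        entries = relative_intensity(records)
        assert [e.sequence for e in entries] == ["AAA", "BBB", "CCC"]
        assert [e.rank for e in entries] == [1, 2, 3]
        assert all(e.ri == pytest.approx(100 / 3) for e in entries)

    def test_normalization(self, rng):
        records = random_sample(rng, 100)
        assert sum(e.ri for e in relative_intensity(records)) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_fold_change_reported_pairs(self):
        assert format_fold_change(3.49, 1.11) == 3.1
        assert format_fold_change(1.43, 0.95) == 1.5
        assert fold_change(2.2, 2.2) == 1.0

    def test_fold_change_reciprocal(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 5, size=2)
            assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_fold_change_zero_reference(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_top_n_and_length_filters(self):
        records = [
            PeptideRecord("AAAA", "S", 5e6),        # PCL 4
            PeptideRecord("CCCCCCC", "S", 4e6),     # PCL 7
            PeptideRecord("DDDDDDDD", "S", 3e6),    # PCL 8
            PeptideRecord("E" * 31, "S", 2e6),      # PCL 31
            PeptideRecord("FFF", "S", 1e6),
        ]
        entries = relative_intensity(records)
        assert [e.sequence for e in top_n(entries, 3)] == [
            "AAAA", "CCCCCCC", "DDDDDDDD"
        ]
        longer = top_n(entries, 10, min_len=6)
        assert {len(e.sequence) for e in longer} == {7, 8, 31}
        short = top_n(entries, 10, max_len=30)
        assert all(len(e.sequence) <= 30 for e in short)
        assert "E" * 31 not in {e.sequence for e in short}


class TestBinning:
    @pytest.mark.parametrize("pcl, label", [(3, 5), (7, 5), (8, 10), (12, 10),
                                            (13, 15), (65, 65)])
    def test_pcl_bins(self, pcl, label):
        assert bin_pcl(pcl) == label

    @pytest.mark.parametrize(
        "pmw, label",
        [(200, 500), (749.99, 500), (750, 1000), (800, 1000), (1249.9, 1000),
         (1250, 1500), (4200, 4000), (4251, 4500), (6000, 4500)],
    )
    def test_pmw_bins(self, pmw, label):
        assert bin_pmw(pmw) == label

    @pytest.mark.parametrize(
        "pz, label",
        [(0.2, 0), (0.49, 0), (-0.4, 0), (1.2, 1), (-7.2, -7), (-6.51, -7),
         (-6.5, -6), (2.8, 3), (2.5, 3)],
    )
    def test_pz_bins(self, pz, label):
        assert bin_pz(pz) == label

    def test_histogram_hand_fractions(self):
        records = [PeptideRecord("GGGG", "S", 3e6),           # PCL 4 -> bin 5
                   PeptideRecord("A" * 12, "S", 1e6)]          # PCL 12 -> bin 10
        hist = histogram(records, "PCL")
        assert hist.bins == (5, 10)
        assert hist.weighted_fraction == pytest.approx((0.75, 0.25))
        assert hist.unweighted_fraction == pytest.approx((0.5, 0.5))

    def test_histogram_conservation(self, rng):
        records = random_sample(rng, 200)
        for variable in ("PCL", "PMW", "Pz"):
            hist = histogram(records, variable)
            assert sum(hist.weighted_fraction) == pytest.approx(1.0, abs=1e-9)
            assert sum(hist.unweighted_fraction) == pytest.approx(1.0, abs=1e-9)

    def test_single_bin(self):
        records = [PeptideRecord("GGG", "S", 1.0),
                   PeptideRecord("AAAA", "S", 2.0)]
        hist = histogram(records, "PCL")
        assert hist.bins == (5,)
        assert hist.weighted_fraction == (1.0,)


class TestProteomeCounting:
    def test_reference_scale_substring_count(self):
        stats = ProteomeStats(74913, 325.7)
        assert substring_count(stats, 4) > 2e7

    def test_small_cases(self):
        assert substring_count(ProteomeStats(10, 10), 1) == 100
        assert substring_count(ProteomeStats(10, 10), 11) == 0

    def test_combinatorial_space(self):
        assert combinatorial_space(4) == 160_000
        assert combinatorial_space(2, n_mods_per_residue=2) == 22**2
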