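"""CAGE filters, power-law normalization, clustering and peak acceptance."""

import numpy as np
import pandas as pd
import pytest

from paracis import cage


def make_records(**overrides):
    base = {
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 300, 400],
        "umi": ["u1", "u2", "u3", "u4"],
        "tlen": [300, 300, 300, 300],
        "soft_clip": [0, 0, 0, 0],
        "mismatches": [0, 0, 0, 0],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestArchitectureFilter:
    def test_clean_records_kept(self):
        kept, removed = cage.architecture_filter(make_records())
        assert len(kept) == 4
        assert removed == {"template_length": 0, "soft_clip": 0, "mismatch": 0}

    def test_long_template_removed(self):
        kept, removed = cage.architecture_filter(make_records(tlen=[12000, 300, 300, 300]))
        assert len(kept) == 3
        assert removed["template_length"] == 1

    def test_soft_clip_boundary_is_strict(self):
        kept, removed = cage.architecture_filter(make_records(soft_clip=[4, 3, 0, 0]))
        assert removed["soft_clip"] == 1  # 4 bp removed, 3 bp kept
        assert len(kept) == 3

    def test_any_mismatch_removed(self):
        kept, removed = cage.architecture_filter(make_records(mismatches=[1, 0, 0, 2]))
        assert removed["mismatch"] == 2
        assert len(kept) == 2

    def test_rule_order_does_not_matter(self):
        recs = make_records(tlen=[20000, 300, 300, 300], soft_clip=[0, 5, 0, 0],
                            mismatches=[0, 0, 1, 0])
        kept, _ = cage.architecture_filter(recs)
        # each rule is per-record; the one clean record survives regardless
        assert kept["pos"].tolist() == [400]

    def test_missing_mismatch_info_rejected(self):
        with pytest.raises(ValueError):
            cage.architecture_filter(make_records(mismatches=[0, np.nan, 0, 0]))


class TestUmiDedup:
    def test_adjacent_same_umi_collapses(self):
        recs = make_records(umi=["u1", "u1", "u2", "u3"])
        out = cage.umi_proximity_dedup(recs)
        assert out["pos"].tolist() == [100, 300, 400]

    def test_far_apart_same_umi_kept(self):
        recs = make_records(umi=["u1", "u2", "u3", "u1"])
        out = cage.umi_proximity_dedup(recs, window_records=2)
        assert len(out) == 4

    def test_distinct_umis_unchanged(self):
        recs = make_records()
        assert len(cage.umi_proximity_dedup(recs)) == 4

    def test_unsorted_input_rejected(self):
        recs = make_records(pos=[400, 100, 200, 300])
        with pytest.raises(ValueError):
            cage.umi_proximity_dedup(recs)


class TestPowerLaw:
    def test_rank_order_preserved(self, rng):
        counts = rng.poisson(20, size=500).astype(float)
        norm = cage.powerlaw_normalize(counts)
        order = np.argsort(counts, kind="stable")
        assert np.all(np.diff(norm[order]) >= -1e-9)

    def test_reference_law_counts_map_to_themselves(self):
        cfg = cage.PowerLawConfig()
        C = cage._reference_intercept(cfg)
        ranks = np.arange(1, 3001)
        counts = np.round((ranks / C) ** (1 / (1 - cfg.alpha)))
        counts = counts[counts >= 1]
        norm = cage.powerlaw_normalize(counts, cfg)
        sel = (counts >= 5) & (counts <= 1000)
        assert np.median(norm[sel] / counts[sel]) == pytest.approx(1.0, rel=0.05)

    def test_identical_multisets_normalize_identically(self, rng):
        counts = rng.poisson(30, size=300).astype(float)
        shuffled = rng.permutation(counts)
        n1 = np.sort(cage.powerlaw_normalize(counts))
        n2 = np.sort(cage.powerlaw_normalize(shuffled))
        assert np.allclose(n1, n2)

    def test_degenerate_fit_falls_back_to_scaling(self):
        counts = np.array([7.0] * 50)
        with pytest.warns(UserWarning):
            norm = cage.powerlaw_normalize(counts)
        assert norm.sum() == pytest.approx(1e6)


def ctss_frame(positions, signal, strand="+", n_samples=2):
    data = {
        "chrom": ["chr1"] * len(positions),
        "pos": positions,
        "strand": [strand] * len(positions),
    }
    for i in range(n_samples):
        data[f"s{i}"] = signal
    return pd.DataFrame(data)


class TestDistclu:
    def test_gap_rule_merges_and_splits(self):
        ctss = ctss_frame([100, 130, 200], [5.0, 5.0, 5.0])
        clusters = cage.distclu(ctss)
        spans = [(c.start, c.end) for c in clusters]
        assert spans == [(100, 131), (200, 201)]

    def test_singleton_threshold_is_strict(self):
        low = cage.distclu(ctss_frame([200], [3.0]))
        high = cage.distclu(ctss_frame([200], [5.0]))
        at = cage.distclu(ctss_frame([200], [4.0]))
        assert low == [] and at == []
        assert len(high) == 1

    def test_opposite_strands_never_merge(self):
        plus = ctss_frame([100, 105], [5.0, 5.0], strand="+")
        minus = ctss_frame([110, 115], [5.0, 5.0], strand="-")
        ctss = pd.concat([plus, minus], ignore_index=True)
        clusters = cage.distclu(ctss)
        assert len(clusters) == 2
        assert {c.strand for c in clusters} == {"+", "-"}

    def test_min_samples_controls_seeding(self):
        ctss = ctss_frame([100, 150], [5.0, 5.0], n_samples=2)
        ctss.loc[1, "s1"] = 0.0  # second position passes in one sample only
        loose = cage.distclu(ctss, min_samples=1)
        strict = cage.distclu(ctss, min_samples=2)
        assert {p for c in loose for p in c.positions} == {100, 150}
        assert {p for c in strict for p in c.positions} == {100}

    def test_same_strand_clusters_respect_max_dist(self, rng):
        pos = np.sort(rng.choice(5000, size=150, replace=False))
        ctss = ctss_frame(pos.tolist(), [5.0] * 150)
        clusters = cage.distclu(ctss)
        starts = sorted(c.start for c in clusters)
        ends = sorted(c.end for c in clusters)
        for nxt, prev_end in zip(starts[1:], ends[:-1]):
            assert nxt - (prev_end - 1) > 50


class TestTwoStepPeaks:
    def test_signal_in_all_samples_accepted_with_loose_bounds(self):
        ctss = ctss_frame([100, 140], [5.0, 5.0], n_samples=4)
        ctss.loc[1, "s3"] = 0.0  # loose cluster extends further than strict
        peaks = cage.two_step_peaks(ctss)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (100, 141)

    def test_single_sample_signal_rejected_without_allowlist(self):
        ctss = ctss_frame([100], [5.0], n_samples=4)
        for s in ("s1", "s2", "s3"):
            ctss[s] = 0.0
        assert cage.two_step_peaks(ctss) == []

    def test_allowlisted_region_bypasses_strict_step(self):
        ctss = ctss_frame([100], [5.0], n_samples=4)
        for s in ("s1", "s2", "s3"):
            ctss[s] = 0.0
        peaks = cage.two_step_peaks(ctss, allowlist=[("chr1", 90, 110, "+")])
        assert len(peaks) == 1

    def test_acceptance_is_exactly_loose_overlapping_strict(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(3000, size=80, replace=False)).tolist()
        data = ctss_frame(pos, [5.0] * 80, n_samples=3)
        drop = rng.random(80) < 0.4
        data.loc[drop, "s2"] = 0.0
        cfg = cage.PeakCallConfig()
        loose = cage.distclu(data, cfg, min_samples=1)
        strict = cage.distclu(data, cfg, min_samples=3)
        expected = [c for c in loose if any(c.overlaps(s) for s in strict)]
        assert cage.two_step_peaks(data, cfg) == expected


class TestCapFilter:
    def make_cluster(self, n_reads, n_capped):
        return cage.TagCluster(
            chrom="chr1", strand="+", start=0, end=10, positions=(0,),
            n_reads=n_reads, n_capped=n_capped,
        )

    def test_above_threshold_retained(self):
        assert len(cage.cap_filter([self.make_cluster(10, 8)])) == 1

    def test_exactly_seventy_percent_removed(self):
        assert cage.cap_filter([self.make_cluster(10, 7)]) == []

    def test_no_capped_reads_removed(self):
        assert cage.cap_filter([self.make_cluster(10, 0)]) == []

    def test_zero_read_cluster_removed_with_warning(self):
        with pytest.warns(UserWarning):
            assert cage.cap_filter([self.make_cluster(0, 0)]) == []


class TestCorrelation:
    def test_proportional_vectors_correlate_perfectly(self):
        cagev = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        _, r, p = cage.promoter_signal_correlation(cagev, 3.0 * cagev)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_atac_scaling_does_not_change_r(self, rng):
        cagev = rng.lognormal(2, 1, size=15)
        atacv = rng.lognormal(2, 1, size=15)
        _, r1, _ = cage.promoter_signal_correlation(cagev, atacv)
        _, r2, _ = cage.promoter_signal_correlation(cagev, atacv * 17.0)
        assert r1 == pytest.approx(r2)

    def test_p_value_matches_t_statistic_oracle(self, rng):
        from scipy import stats

        cagev = rng.lognormal(2, 1, size=15)
        atacv = cagev * rng.lognormal(0, 0.4, size=15)
        table, r, p = cage.promoter_signal_correlation(cagev, atacv)
        n = 15
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert p == pytest.approx(p_oracle, rel=1e-6)
        assert table["atac_normalized"].sum() == pytest.approx(100_000.0)

    def test_nonpositive_values_need_pseudocount(self):
        with pytest.raises(ValueError):
            cage.promoter_signal_correlation(
                np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0])
            )
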