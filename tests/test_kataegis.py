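"""Kataegis detection: ADL, window scan, Fisher test, merging, decomposition."""

import numpy as np
import pandas as pd
import pytest

from flgenomics import kataegis as kat
from flgenomics import simulate as sim

from _oracles import brute_force_kataegis, hypergeom_upper_tail
from conftest import make_mutations


class TestAdl:
    def test_pooled_mean_over_one_chromosome(self):
        muts = make_mutations({"chr1": [0, 100, 300, 600]})
        adl = kat.compute_adl(muts)
        assert adl.mean_distance == 200
        assert adl.adl == 20
        assert adl.n_below + adl.n_above == 3

    def test_distances_never_cross_chromosomes(self):
        muts = make_mutations({"chr1": [0, 1000], "chr2": [0, 1000]})
        adl = kat.compute_adl(muts)
        assert adl.mean_distance == 1000
        assert adl.adl == 100
        assert adl.n_below + adl.n_above == 2

    def test_insufficient_mutations_raise(self):
        muts = make_mutations({"chr1": [5]})
        with pytest.raises(ValueError, match="insufficient mutations"):
            kat.compute_adl(muts)

    def test_uniform_positions_give_adl_near_tenth_of_spacing(self, rng):
        pos = np.sort(rng.integers(1, 100_000_000, size=10_000))
        muts = make_mutations({"chr1": pos.tolist()})
        adl = kat.compute_adl(muts)
        assert adl.adl == pytest.approx(1000, rel=0.05)

    def test_distance_equal_to_adl_counts_as_above(self):
        # distances 10, 10, 280: mean 100, ADL 10; ties are not "below"
        muts = make_mutations({"chr1": [0, 10, 20, 300]})
        adl = kat.compute_adl(muts)
        assert adl.n_below == 0
        assert adl.n_above == 3


class TestFisherOneTailed:
    @pytest.mark.parametrize(
        "table",
        [(9, 0, 10, 9000), (3, 6, 500, 700), (0, 9, 100, 900), (5, 4, 5, 4)],
    )
    def test_matches_exact_summation_oracle(self, table):
        assert kat.fisher_one_tailed(*table) == pytest.approx(
            hypergeom_upper_tail(*table), abs=1e-12
        )

    def test_no_below_distances_gives_p_one(self):
        assert kat.fisher_one_tailed(0, 9, 123, 4567) == pytest.approx(1.0)

    def test_table_at_marginal_expectation_is_not_significant(self):
        # window ratio equals the background ratio exactly -> no enrichment
        assert kat.fisher_one_tailed(3, 6, 300, 600) >= 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kat.fisher_one_tailed(-1, 2, 3, 4)


class TestScanWindows:
    def _sample_with_cluster(self, spacing=1, n_background=2000, rng=None):
        rng = rng or np.random.default_rng(5)
        bg = np.sort(rng.integers(1, 20_000_000, size=n_background))
        cluster = 10_000_001 + spacing * np.arange(10)
        return make_mutations({"chr1": np.concatenate([bg, cluster]).tolist()})

    def test_tight_cluster_is_a_strong_candidate(self):
        muts = self._sample_with_cluster(spacing=1)
        adl = kat.compute_adl(muts)
        cands = kat.scan_windows(muts, adl)
        best = min(cands, key=lambda c: c.p)
        assert best.p < 1e-8
        assert best.start >= 10_000_001

    def test_window_spanning_more_than_limit_not_formed(self):
        # 10 mutations spanning 10,001 bp: no window
        pos = np.round(np.linspace(0, 10_001, 10)).astype(int).tolist()
        muts = make_mutations({"chr1": pos})
        adl = kat.AdlStatistic("S001", 10_000.0, 1000.0, 0, 9)
        assert kat.scan_windows(muts, adl, max_span_bp=10_000) == []
        # at exactly 10,000 bp the window forms
        pos[-1] = 10_000
        muts = make_mutations({"chr1": pos})
        assert len(kat.scan_windows(muts, adl, max_span_bp=10_000)) == 1

    def test_window_matching_background_ratio_is_insignificant(self):
        muts = self._sample_with_cluster(spacing=100_000)
        adl = kat.compute_adl(muts)
        for c in kat.scan_windows(muts, adl):
            if c.below == round(9 * adl.n_below / (adl.n_below + adl.n_above)):
                assert c.p >= 0.05

    def test_fewer_than_window_n_mutations_returns_empty(self):
        muts = make_mutations({"chr1": list(range(0, 50, 10))})
        adl = kat.compute_adl(muts)
        assert kat.scan_windows(muts, adl) == []


class TestMergeAndDetect:
    def test_two_distant_clusters_stay_separate(self, rng):
        bg = np.sort(rng.integers(1, 20_000_000, size=2000))
        c1 = 5_000_001 + np.arange(12) * 3
        c2 = 15_000_001 + np.arange(12) * 3
        muts = make_mutations({"chr1": np.concatenate([bg, c1, c2]).tolist()})
        events = kat.detect_kataegis(muts)
        starts = sorted(e.start for e in events)
        assert len(events) == 2
        assert starts[0] < 6_000_000 < 14_000_000 < starts[1]

    def test_overlapping_candidates_merge_into_one_event(self, rng):
        bg = np.sort(rng.integers(1, 20_000_000, size=2000))
        cluster = 9_000_001 + np.arange(15) * 2
        muts = make_mutations({"chr1": np.concatenate([bg, cluster]).tolist()})
        events = [
            e for e in kat.detect_kataegis(muts)
            if e.end >= 9_000_001 and e.start <= 9_000_029
        ]
        assert len(events) == 1
        assert events[0].n_mutations >= 11
        assert events[0].p < 1e-4

    def test_empty_candidates_give_empty_events(self):
        muts = make_mutations({"chr1": [0, 1_000_000, 2_000_000]})
        adl = kat.compute_adl(muts)
        assert kat.merge_events(muts, [], adl) == []

    def test_record_order_never_changes_the_output(self, rng):
        bg = np.sort(rng.integers(1, 20_000_000, size=1500))
        cluster = 3_000_001 + np.arange(13) * 5
        muts = make_mutations({"chr1": np.concatenate([bg, cluster]).tolist()})
        shuffled = muts.sample(frac=1.0, random_state=7).reset_index(drop=True)
        ev_a = kat.detect_kataegis(muts)
        ev_b = kat.detect_kataegis(shuffled)
        assert [(e.start, e.end, e.p) for e in ev_a] == [(e.start, e.end, e.p) for e in ev_b]

    def test_matches_brute_force_on_a_small_cohort(self, rng):
        for trial in range(5):
            bg = np.sort(rng.integers(1, 20_000_000, size=1200))
            c1 = int(rng.integers(1_000_000, 18_000_000))
            cluster = c1 + np.cumsum(rng.integers(1, 40, size=14))
            muts = make_mutations({"chr1": np.concatenate([bg, cluster]).tolist()})
            events = kat.detect_kataegis(muts)
            expected = brute_force_kataegis(
                [("chr1", p) for p in muts["pos"]], threshold=1e-4
            )
            got = [(e.chrom, e.start, e.end, e.n_mutations) for e in events]
            want = [(e["chrom"], e["start"], e["end"], e["n_mutations"]) for e in expected]
            assert got == want
            for e, w in zip(events, expected):
                assert e.p == pytest.approx(w["p"], abs=1e-12)


class TestDecomposition:
    def _event_from(self, muts):
        grp = muts[muts["sample"] == "S001"]
        return kat.KataegisEvent(
            sample="S001",
            chrom=grp["chrom"].iloc[0],
            start=int(grp["pos"].min()),
            end=int(grp["pos"].max()),
            n_mutations=len(grp),
            p=1e-9,
            member_positions=tuple(grp["pos"]),
        )

    def _cluster_muts(self, ksig, source, n=20, seed=0):
        plan = {"S001": [sim.KataegisPlan("chr1", 5_000_000, n, 5_000, source)]}
        spec = sim.CohortSpec(n_samples=1, background_rate=0, kataegis_plan=plan, seed=seed)
        return sim.simulate_mutations(spec, ksig)

    def test_pure_k1_event_has_contribution_one(self, ksig):
        muts = self._cluster_muts(ksig, "K1-like")
        ev = kat.decompose_event(self._event_from(muts), muts, ksig)
        assert ev.k1_contribution == pytest.approx(1.0, abs=1e-9)
        assert ev.dominance == "K1-dominant"

    def test_pure_k2_event_has_contribution_zero(self, ksig):
        muts = self._cluster_muts(ksig, "K2-like")
        ev = kat.decompose_event(self._event_from(muts), muts, ksig)
        assert ev.k1_contribution == pytest.approx(0.0, abs=1e-9)
        assert ev.dominance == "K2-dominant"

    def test_balanced_orthogonal_mixture_near_half(self, ksig):
        # exactly half the members from each disjoint-support profile
        a = self._cluster_muts(ksig, "K1-like", n=30, seed=1)
        b = self._cluster_muts(ksig, "K2-like", n=30, seed=2)
        b = b.assign(pos=b["pos"] + 6_000)
        muts = pd.concat([a, b], ignore_index=True)
        ev = kat.decompose_event(self._event_from(muts), muts, ksig)
        assert ev.k1_contribution == pytest.approx(0.5, abs=0.05)


class TestSummaries:
    def _event(self, sample, contrib):
        return kat.KataegisEvent(
            sample=sample, chrom="chr1", start=1, end=2, n_mutations=10, p=1e-9,
            member_positions=(1, 2), k1_contribution=contrib,
        )

    def test_sample_mean_is_unweighted_over_events(self):
        events = [self._event("S001", 1.0), self._event("S001", 0.0)]
        summary = kat.summarize_samples(events, ["S001"])
        assert summary.loc[0, "mean_k1_contribution"] == pytest.approx(0.5)

    def test_median_split_groups(self):
        events = [
            self._event(s, c)
            for s, c in [("S001", 0.2), ("S002", 0.4), ("S003", 0.6), ("S004", 0.8)]
        ]
        summary = kat.summarize_samples(events, ["S001", "S002", "S003", "S004", "S005"])
        groups = summary.set_index("sample")["group"]
        assert groups["S001"] == groups["S002"] == "K1-low"
        assert groups["S003"] == groups["S004"] == "K1-high"
        assert groups["S005"] == "no-kataegis"
        assert summary.attrs["median_k1_contribution"] == pytest.approx(0.5)

    def test_single_sample_at_median_is_low(self):
        summary = kat.summarize_samples([self._event("S001", 0.7)], ["S001"])
        assert summary.loc[0, "group"] == "K1-low"


class TestAnnotation:
    IG = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [1000, 5000, 9000],
            "end": [2000, 6000, 9500],
            "name": ["V", "S", "J&C"],
        }
    )
    TSS = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [100_000, 50_000], "gene": ["g1", "g2"]})

    def _event(self, chrom, start, end):
        return kat.KataegisEvent(
            sample="S001", chrom=chrom, start=start, end=end, n_mutations=10, p=1e-9,
            member_positions=(start, end),
        )

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (5100, 5200, "Ig:S"),
            (1500, 1600, "Ig:V"),
            (9100, 9200, "Ig:J&C"),
            (97_900, 98_100, "TSS-proximal"),   # midpoint 1,999+1 bp away -> within 2 kb
            (95_000, 96_000, "TSS-distal"),
        ],
    )
    def test_region_classes(self, start, end, expected):
        [ev] = kat.annotate_events([self._event("chr1", start, end)], self.IG, self.TSS)
        assert ev.region_class == expected

    def test_proximal_boundary_is_inclusive(self):
        # midpoint exactly 2,000 bp from the TSS
        [ev] = kat.annotate_events([self._event("chr1", 97_990, 98_010)], self.IG, self.TSS)
        assert ev.region_class == "TSS-proximal"
        [ev] = kat.annotate_events([self._event("chr1", 97_988, 98_008)], self.IG, self.TSS)
        assert ev.region_class == "TSS-distal"
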