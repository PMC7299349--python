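"""IS-element tallies and the insertion-site-preference randomization test."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from citniche.insertions import (
    InsertionEvent,
    SiteCatalog,
    is150_accumulation,
    merge_tsd_sites,
    site_preference_test,
    tally_insertions,
)
from citniche.simulate import gen_insertion_sites


def event(clone, trt, site, element="IS150", gene="g"):
    return InsertionEvent(clone_id=clone, treatment=trt, element=element,
                          site=site, gene_label=gene)


class TestTally:
    def test_empty_input(self):
        assert tally_insertions([], "site").empty

    def test_site_count_across_genomes(self):
        events = [event(f"c{i}", "DM0", 3_530_000) for i in range(9)]
        events += [event("c9", "DM0", 1_000_000)]
        t = tally_insertions(events, "site")
        assert int(t.loc[t["site"] == 3_530_000, "count"].iloc[0]) == 9

    def test_manual_tally_matches(self):
        events = (
            [event("c1", "DM0", 100)] * 3
            + [event("c2", "DM25", 200, element="IS1")] * 2
            + [event("c3", "DM0", 300, element="IS186")] * 5
        )
        by_el = tally_insertions(events, "element")
        assert dict(zip(by_el["element"], by_el["count"])) == {
            "IS1": 2, "IS150": 3, "IS186": 5,
        }
        by_trt = tally_insertions(events, "treatment")
        assert dict(zip(by_trt["treatment"], by_trt["count"])) == {
            "DM0": 8, "DM25": 2,
        }


class TestSitePreference:
    def test_single_site_catalog_gives_p_one(self):
        cat = SiteCatalog(sites=(100,), weights=(5,))
        assert site_preference_test(cat, 10, 10, 100, n_boot=1000, seed=0) == 1.0

    def test_two_site_binomial_oracle(self):
        # Weights (9, 1): the focal count is Binomial(10, 0.9), so
        # P(count >= 9) = 0.7361 exactly.
        cat = SiteCatalog(sites=(100, 200), weights=(9, 1))
        p = site_preference_test(cat, 10, 9, 100, n_boot=100_000, seed=5)
        exact = float(sps.binom.sf(8, 10, 0.9))
        mc_se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(p - exact) <= 3 * mc_se

    def test_p_monotone_in_observed_count(self):
        cat = SiteCatalog(sites=(1, 2, 3), weights=(5, 3, 2))
        ps = [
            site_preference_test(cat, 20, obs, 1, n_boot=20_000, seed=9)
            for obs in range(0, 21, 4)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_max_statistic_never_smaller_p_than_focal(self):
        cat = SiteCatalog(sites=(1, 2, 3, 4), weights=(4, 3, 2, 1))
        for obs in (3, 5, 8):
            p_focal = site_preference_test(
                cat, 12, obs, 1, n_boot=20_000, statistic="focal", seed=3
            )
            p_max = site_preference_test(
                cat, 12, obs, 1, n_boot=20_000, statistic="max", seed=3
            )
            assert p_max >= p_focal

    def test_uniform_many_sites_single_hit_is_unremarkable(self):
        cat = SiteCatalog(sites=tuple(range(1, 101)), weights=(1,) * 100)
        p = site_preference_test(cat, 50, 1, 7, n_boot=20_000, seed=1)
        assert p > 0.3

    def test_zero_insertions(self):
        cat = SiteCatalog(sites=(1,), weights=(1,))
        assert site_preference_test(cat, 0, 0, 1, n_boot=100, seed=0) == 1.0
        with pytest.raises(ValueError):
            site_preference_test(cat, 0, 1, 1, n_boot=100, seed=0)

    def test_hotspot_detected_with_high_power(self):
        hits = 0
        for s in range(50):
            events, cat, truth = gen_insertion_sites(hotspot_factor=20.0, seed=s)
            dm0 = [e for e in events if e.treatment == "DM0"]
            obs = Counter(e.site for e in dm0)[truth["hotspot_site"]]
            p = site_preference_test(
                cat, len(dm0), obs, truth["hotspot_site"], n_boot=5000, seed=s
            )
            hits += p < 0.01
        assert hits / 50 >= 0.90

    def test_null_generation_is_calibrated(self):
        # hotspot_factor = 1 reproduces the null exactly: the focal-site
        # p-value is approximately uniform (mean ~ 0.5, few small p).
        ps = []
        for s in range(200):
            events, cat, truth = gen_insertion_sites(hotspot_factor=1.0, seed=s)
            dm0 = [e for e in events if e.treatment == "DM0"]
            obs = Counter(e.site for e in dm0)[truth["hotspot_site"]]
            ps.append(
                site_preference_test(
                    cat, len(dm0), obs, truth["hotspot_site"], n_boot=2000, seed=s
                )
            )
        assert 0.40 <= np.mean(ps) <= 0.65  # discrete p is conservative
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.10


class TestCatalog:
    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            SiteCatalog(sites=(1, 2), weights=(1, 0))

    def test_tsd_span_merging(self):
        canon = merge_tsd_sites([100, 102, 103, 200], tsd_span_bp=4)
        assert canon[100] == canon[102] == canon[103] == 100
        assert canon[200] == 200


class TestAccumulation:
    def test_identical_counts_give_p_one(self):
        events = [event(f"a{i}", "DM0", 100 + i) for i in range(3)]
        events += [event(f"b{i}", "DM25", 200 + i) for i in range(3)]
        counts, p = is150_accumulation(events)
        assert p == 1.0

    def test_small_sample_enumeration_oracle(self):
        # Genomes with counts (1,2) vs (3,4) reduce to the exact
        # Mann-Whitney enumeration p = 1/3.
        events = []
        for i, n in enumerate([1, 2]):
            events += [event(f"a{i}", "DM0", 100 + j) for j in range(n)]
        for i, n in enumerate([3, 4]):
            events += [event(f"b{i}", "DM25", 200 + j) for j in range(n)]
        counts, p = is150_accumulation(events)
        assert p == pytest.approx(1 / 3)

    def test_group_difference_detected(self, rng):
        # Poisson counts at the observed group means (8.5 vs 4.9).
        ps = []
        for s in range(100):
            local = np.random.default_rng(s)
            events = []
            for i in range(12):
                for j in range(local.poisson(8.5)):
                    events.append(event(f"a{i}", "DM0", 1000 * i + j))
                events.append(event(f"a{i}", "DM0", 999_000 + i, element="IS1"))
            for i in range(12):
                for j in range(local.poisson(4.9)):
                    events.append(event(f"b{i}", "DM25", 500_000 + 1000 * i + j))
                events.append(event(f"b{i}", "DM25", 888_000 + i, element="IS1"))
            ps.append(is150_accumulation(events)[1])
        assert np.median(ps) < 0.05
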