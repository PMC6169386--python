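"""Coverage, informativeness, sharing, tagging potential, lone/dark sites,
ancestry-stratified accuracy."""

import numpy as np
import pytest

import tagscaffold as tsf
from conftest import brute_force_greedy, pearson_r2, random_panel
from tagscaffold.bins import MAFBinScheme
from tagscaffold.imputer import AccuracyReport, DosageMatrix, HMMParams, leave_one_out_evaluate
from tagscaffold.ld import LDStore
from tagscaffold.metrics import (
    ancestry_stratified_accuracy,
    dark_sites,
    informativeness,
    lone_sites,
    pairwise_coverage,
    sharing_profiles,
    tagging_potential,
)
from tagscaffold.panel import FrequencyTable, allele_frequencies


def store_from_pairs(pairs, n_sites, floor=0.2, population="POP1"):
    a = np.array([p[0] for p in pairs], dtype=np.int64)
    b = np.array([p[1] for p in pairs], dtype=np.int64)
    return LDStore(
        population=population, window_bp=10**9, floor_r2=floor, n_sites=n_sites,
        a_idx=a, b_idx=b, r2=np.array(list(pairs.values())),
    )


def flat_freqs(maf, n, population="POP1"):
    f = FrequencyTable()
    f.alt_freq[population] = np.full(n, maf)
    return f


class TestPairwiseCoverage:
    def test_counts_on_small_fixture(self):
        # tag = site 0; untyped sites 1..4 with r² 0.9, 0.6, 0.3, (none)
        pairs = {(0, 1): 0.9, (0, 2): 0.6, (0, 3): 0.3}
        store = store_from_pairs(pairs, 5)
        freqs = flat_freqs(0.3, 5)
        scaffold = frozenset([0])
        cov05 = pairwise_coverage(store, scaffold, 0.5, freqs)
        cov08 = pairwise_coverage(store, scaffold, 0.8, freqs)
        assert cov05.overall == pytest.approx(2 / 4)
        assert cov08.overall == pytest.approx(1 / 4)

    def test_full_ld_means_full_coverage(self):
        pairs = {(0, j): 1.0 for j in range(1, 6)}
        store = store_from_pairs(pairs, 6)
        cov = pairwise_coverage(store, frozenset([0]), 0.8, flat_freqs(0.2, 6))
        occupied = cov.table[cov.table["n_sites"] > 0]
        assert (occupied["proportion"] == 1.0).all()

    def test_empty_scaffold_covers_nothing(self):
        pairs = {(0, 1): 1.0}
        store = store_from_pairs(pairs, 2)
        cov = pairwise_coverage(store, frozenset(), 0.5, flat_freqs(0.3, 2))
        assert cov.overall == 0.0

    def test_scaffold_sites_excluded_from_denominator(self):
        pairs = {(0, 1): 1.0}
        store = store_from_pairs(pairs, 2)
        cov = pairwise_coverage(store, frozenset([0]), 0.5, flat_freqs(0.3, 2))
        assert cov.table["n_sites"].sum() == 1  # only the untyped site counts

    def test_threshold_below_floor_rejected(self):
        store = store_from_pairs({(0, 1): 0.9}, 2, floor=0.5)
        with pytest.raises(ValueError):
            pairwise_coverage(store, frozenset([0]), 0.2, flat_freqs(0.3, 2))

    def test_monotone_in_threshold_on_study_panel(self, study_state):
        freqs = study_state["freqs"]
        design = study_state["designs"]["crosspop"]
        for pop, store in study_state["ld"].items():
            c5 = pairwise_coverage(store, design, 0.5, freqs)
            c8 = pairwise_coverage(store, design, 0.8, freqs)
            for b5, b8 in zip(c5.table.itertuples(), c8.table.itertuples()):
                if b5.n_sites:
                    assert b8.n_covered <= b5.n_covered


class TestInformativeness:
    def test_monomorphic_tag_not_informative(self):
        panel = tsf.deterministic_fixture("two-pop-shared")
        freqs = allele_frequencies(panel)
        ld = {p: tsf.compute_ld(panel, p, floor_r2=0.2) for p in ("POP1", "POP2")}
        # tag sites 2 (pos 300) and 1 (pos 200); site 2 monomorphic in POP2
        inf = informativeness(frozenset([1, 2]), ld, freqs)
        assert bool(inf.loc[2, "POP1"]) is True
        assert bool(inf.loc[2, "POP2"]) is False

    def test_threshold_is_inclusive_at_half(self):
        pairs_lo = store_from_pairs({(0, 1): 0.49}, 2)
        pairs_hi = store_from_pairs({(0, 1): 0.51}, 2)
        freqs = flat_freqs(0.3, 2)
        assert not informativeness(frozenset([0]), {"POP1": pairs_lo}, freqs).loc[0, "POP1"]
        assert informativeness(frozenset([0]), {"POP1": pairs_hi}, freqs).loc[0, "POP1"]

    def test_scaffold_partner_does_not_count(self):
        """Informativeness needs an *untyped* partner."""
        pairs = store_from_pairs({(0, 1): 0.9}, 3)
        freqs = flat_freqs(0.3, 3)
        inf = informativeness(frozenset([0, 1]), {"POP1": pairs}, freqs)
        assert not inf.loc[0, "POP1"]


class TestSharing:
    def test_identical_ld_gives_full_conditional(self):
        import pandas as pd

        inf = pd.DataFrame({"A": [True, True, False], "B": [True, True, False]})
        prof = sharing_profiles(inf)
        assert prof.conditional.loc["A", "B"] == 1.0
        assert prof.conditional.loc["A", "A"] == 1.0

    def test_disjoint_sets_give_zero(self):
        import pandas as pd

        inf = pd.DataFrame({"A": [True, False], "B": [False, True]})
        prof = sharing_profiles(inf)
        assert prof.conditional.loc["A", "B"] == 0.0

    def test_three_population_fixture_matches_hand_count(self):
        import pandas as pd

        # tags x (A, B, C)
        inf = pd.DataFrame(
            {
                "A": [1, 1, 1, 0, 1],
                "B": [1, 0, 1, 1, 0],
                "C": [0, 0, 1, 1, 0],
            },
            dtype=bool,
        )
        prof = sharing_profiles(inf)
        # informative in A: tags 0,1,2,4 -> B in 2 of 4, C in 1 of 4
        assert prof.conditional.loc["A", "B"] == pytest.approx(0.5)
        assert prof.conditional.loc["A", "C"] == pytest.approx(0.25)
        # breadth distribution for index A: n=1 {1,4}, n=2 {0}, n=3 {2}
        assert prof.distribution.loc["A", 1] == pytest.approx(0.5)
        assert prof.distribution.loc["A", 2] == pytest.approx(0.25)
        assert prof.distribution.loc["A", 3] == pytest.approx(0.25)

    def test_empty_row_flagged(self):
        import pandas as pd

        inf = pd.DataFrame({"A": [False, False], "B": [True, False]})
        prof = sharing_profiles(inf)
        assert prof.undefined_rows == ["A"]
        assert np.isnan(prof.conditional.loc["A", "B"])


class TestTaggingPotential:
    def test_chain_needs_one_tag(self):
        store = store_from_pairs({(0, 1): 0.9, (1, 2): 0.9}, 3)
        n, mean = tagging_potential(store, flat_freqs(0.3, 3), 0.01, 0.5)
        assert n == 1 and mean == pytest.approx(2.0)

    def test_unlinked_sites_need_no_tags(self):
        store = store_from_pairs({}, 5)
        n, mean = tagging_potential(store, flat_freqs(0.3, 5), 0.01, 0.5)
        assert n == 0 and np.isnan(mean)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_greedy(self, seed):
        rng = np.random.default_rng(seed)
        pairs = {}
        for _ in range(60):
            i, j = sorted(rng.choice(30, size=2, replace=False))
            pairs[(int(i), int(j))] = float(rng.uniform(0.5, 1.0))
        store = store_from_pairs(pairs, 30)
        n, mean = tagging_potential(store, flat_freqs(0.3, 30), 0.01, 0.5)
        oracle = brute_force_greedy(set(pairs), np.ones(30, dtype=bool), 30)
        oracle_informative = [(s, d) for s, d, _ in oracle if d > 0]
        assert n == len(oracle_informative)
        assert mean == pytest.approx(
            sum(len(new) for _, d, new in oracle if d > 0) / len(oracle_informative)
        )


class TestLoneAndDarkSites:
    def test_lone_site_fixture(self):
        panel = tsf.deterministic_fixture("lone-site")
        lone = lone_sites(panel, "POP1")
        assert lone == [3]  # the engineered r²=0 site at pos 400

    def test_boundary_exactly_at_threshold_is_lone(self):
        """max r² exactly 0.2 still counts as lone (strict > for correlation)."""
        store = store_from_pairs({(0, 1): 0.2}, 2)
        panel = random_panel(np.random.default_rng(0), n_sites=2, n_samples=10)
        freqs = flat_freqs(0.3, 2)
        lone = lone_sites(panel, "POP1", window_bp=10**9, freqs=freqs, ld=store)
        assert lone == [0, 1]
        store2 = store_from_pairs({(0, 1): 0.21}, 2)
        assert lone_sites(panel, "POP1", window_bp=10**9, freqs=freqs, ld=store2) == []

    def test_low_maf_sites_not_considered(self):
        store = store_from_pairs({}, 3)
        panel = random_panel(np.random.default_rng(0), n_sites=3, n_samples=10)
        f = FrequencyTable()
        f.alt_freq["POP1"] = np.array([0.004, 0.3, 0.006])
        lone = lone_sites(panel, "POP1", window_bp=10**9, freqs=f, ld=store)
        assert lone == [1, 2]

    def test_dark_classification(self):
        r2 = np.array([0.25, 0.1, np.nan, 0.9])
        report = AccuracyReport(site_r2={"POP1": r2}, n_individuals={"POP1": 10})
        lone = [0, 1, 2]
        dark = dark_sites(lone, report, "POP1", r2_acc_floor=0.2)
        assert dark == [1, 2]  # 0.25 recoverable; 0.1 and undefined are dark

    def test_dark_is_subset_of_lone(self):
        r2 = np.array([0.0, 0.0, 0.0, 0.0])
        report = AccuracyReport(site_r2={"POP1": r2}, n_individuals={"POP1": 10})
        assert set(dark_sites([1, 3], report, "POP1")) <= {1, 3}

    def test_genotyped_lone_site_not_dark(self):
        r2 = np.array([np.nan, np.nan])
        report = AccuracyReport(site_r2={"POP1": r2}, n_individuals={"POP1": 10})
        dark = dark_sites([0, 1], report, "POP1", scaffold=frozenset([0]))
        assert dark == [1]


@pytest.fixture(scope="module")
def toy():
    panel = tsf.deterministic_fixture("admixed-toy")
    tracts = tsf.fixture_tracts("admixed-toy")
    # impute the toy with a sparse scaffold; exact values are irrelevant
    # here, the stratification logic is what is under test
    scaffold = frozenset([0, 4])
    dosages, _ = leave_one_out_evaluate(panel, scaffold, HMMParams(ne=1.0), ["ADMIX"])
    return panel, tracts, dosages


class TestAncestryStratified:

    def test_short_tract_dropped_and_cells_masked(self, toy):
        panel, tracts, dosages = toy
        res = ancestry_stratified_accuracy(
            dosages, panel, tracts, min_tract_cm=20, min_individuals=1
        )
        # ADM2 hap0 has a 14 cM ANCA tract: its sites are masked, so ADM2
        # contributes to ANCB-ANCB only where hap0's *retained* ANCB tract
        # overlaps hap1's ANCB
        assert all(t.length_cm >= 20 or t.individual == "ADM2" for t in tracts if t.length_cm < 20)
        cats = set(res.site_r2)
        assert ("ANCA", "ANCB") in cats and ("ANCA", "ANCA") in cats

    def test_small_categories_dropped(self, toy):
        panel, tracts, dosages = toy
        res = ancestry_stratified_accuracy(
            dosages, panel, tracts, min_tract_cm=20, min_individuals=5
        )
        # with 6 admixed individuals no diplotype category reaches 5
        assert res.n_individuals == {}
        assert len(res.dropped_categories) >= 2

    def test_unordered_category_labels(self, toy):
        panel, tracts, dosages = toy
        res = ancestry_stratified_accuracy(
            dosages, panel, tracts, min_tract_cm=20, min_individuals=1
        )
        for cat in res.site_r2:
            assert cat == tuple(sorted(cat))

    def test_category_means_equal_masked_recomputation(self, study_state, study_evaluations):
        """Stratified means equal direct recomputation on matching cells."""
        panel = study_state["panel"]
        tracts = study_state["tracts"]
        dosages, _ = study_evaluations["crosspop"]
        res = ancestry_stratified_accuracy(
            dosages, panel, tracts, min_tract_cm=0.0, min_individuals=2
        )
        positions = panel.positions
        truth = panel.genotypes()
        sample_pos = {s: i for i, s in enumerate(dosages.sample_ids)}
        hap_label = {}
        for t in tracts:
            hap_label.setdefault((t.individual, t.haplotype), []).append(t)
        checked = 0
        for cat, r2 in res.site_r2.items():
            for j in np.flatnonzero(~np.isnan(r2)):
                # recompute membership for this site by scanning tracts
                members = []
                for ind in {t.individual for t in tracts}:
                    labels = []
                    for h in (0, 1):
                        lab = None
                        for t in hap_label[(ind, h)]:
                            if t.start_bp <= positions[j] < t.end_bp:
                                lab = t.ancestry
                        labels.append(lab)
                    if None not in labels and tuple(sorted(labels)) == cat:
                        members.append(sample_pos[ind])
                expected = pearson_r2(
                    truth[members, j], dosages.values[members, j]
                )
                assert r2[j] == pytest.approx(expected, abs=1e-9)
                checked += 1
                if checked >= 50:
                    return
        assert checked > 0
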