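"""Four-category classification, overlap proportions and abundance indices."""

import numpy as np
import pandas as pd
import pytest

from ednacongruence.congruence import (ReadTable, UndefinedProportionError,
                                       classify_species, correct_to_pool,
                                       extra_local_barcode_count,
                                       prop_shared_reads, prop_shared_species,
                                       richness_per_site,
                                       species_mean_site_relabund,
                                       species_total_relabund)
from ednacongruence.coverage import ReferenceDB

from conftest import random_read_table


def _table(data, sites=None):
    idx = pd.Index(list(data), name="species")
    return ReadTable("T", pd.DataFrame(list(data.values()), index=idx,
                                       columns=sites or [f"s{i}" for i in
                                                         range(len(next(iter(data.values()))))]))


class TestClassify:
    def test_identical_sets_all_shared(self):
        part = classify_species({"A a", "B b"}, {"A a", "B b"},
                                {"A a", "B b", "C c"})
        assert part.shared == {"A a", "B b"}
        assert not part.unique_reanalysis
        assert not part.unique_original_local
        assert not part.unique_original_nonlocal

    def test_enumerated_example(self):
        part = classify_species({"A a", "B b", "C c"}, {"B b", "C c", "D d"},
                                {"A a", "B b", "C c", "D d", "E e"})
        assert part.shared == {"B b", "C c"}
        assert part.unique_reanalysis == {"D d"}
        assert part.unique_original_local == {"A a"}
        assert part.unique_original_nonlocal == set()

    def test_nonlocal_original_only(self):
        part = classify_species({"X x"}, set(), {"A a"})
        assert part.unique_original_nonlocal == {"X x"}
        assert not (part.shared | part.unique_reanalysis
                    | part.unique_original_local)

    def test_uncorrected_reanalysis_rejected(self):
        with pytest.raises(ValueError):
            classify_species({"A a"}, {"Z z"}, {"A a"})

    def test_partition_identity_random_triples(self, rng):
        universe = [f"G{i} s{i}" for i in range(30)]
        for _ in range(300):
            orig = {s for s in universe if rng.random() < 0.4}
            pool = {s for s in universe if rng.random() < 0.6}
            rean = {s for s in pool if rng.random() < 0.4}
            part = classify_species(orig, rean, pool)
            sizes = part.sizes()
            assert sum(sizes.values()) == len(orig | rean)
            assert part.universe == orig | rean


class TestProportions:
    def test_prop_shared_species(self):
        part = classify_species({"A a", "B b", "C c"}, {"B b", "C c", "D d"},
                                {"A a", "B b", "C c", "D d"})
        assert prop_shared_species(part) == pytest.approx(2 / 3)

    def test_empty_reanalysis_is_error(self):
        part = classify_species({"X x"}, set(), {"A a"})
        with pytest.raises(UndefinedProportionError):
            prop_shared_species(part)

    def test_prop_shared_reads_hand_sum(self):
        t = _table({"A a": [50, 20], "B b": [20, 10]})
        assert prop_shared_reads(t, {"A a"}) == pytest.approx(0.7)
        assert prop_shared_reads(t, {"A a", "B b"}) == 1.0
        assert prop_shared_reads(t, set()) == 0.0

    def test_zero_reads_is_error(self):
        t = _table({"A a": [0, 0]})
        with pytest.raises(UndefinedProportionError):
            prop_shared_reads(t, {"A a"})


class TestAbundanceIndices:
    def test_hand_computed_example(self):
        t = _table({"A a": [10, 20], "B b": [30, 40]})
        a = species_total_relabund(t)
        assert a["A a"] == pytest.approx(0.3)
        assert a["B b"] == pytest.approx(0.7)
        b = species_mean_site_relabund(t)
        assert b["A a"] == pytest.approx((0.25 + 1 / 3) / 2)
        assert b["B b"] == pytest.approx((0.75 + 2 / 3) / 2)

    def test_single_species_and_single_site(self):
        assert species_total_relabund(_table({"A a": [7]}))["A a"] == 1.0
        t = _table({"A a": [1], "B b": [3]})
        b = species_mean_site_relabund(t)
        assert b["A a"] == pytest.approx(0.25)

    def test_normalization_and_pread_identity_random(self, rng):
        for _ in range(300):
            t = random_read_table(rng)
            a = species_total_relabund(t)
            b = species_mean_site_relabund(t)
            assert abs(a.sum() - 1) < 1e-12
            assert abs(b.sum() - 1) < 1e-12
            shared = {s for s in t.counts.index if rng.random() < 0.5}
            assert prop_shared_reads(t, shared) == pytest.approx(
                a[a.index.isin(shared)].sum(), abs=1e-12)

    def test_zero_total_sites_dropped_from_b(self):
        t = _table({"A a": [10, 0], "B b": [30, 0]})
        b = species_mean_site_relabund(t)
        assert b["A a"] == pytest.approx(0.25)  # only the occupied site counts
        with pytest.raises(UndefinedProportionError):
            species_mean_site_relabund(_table({"A a": [0]}))


class TestCorrectionAndRichness:
    def test_correct_to_pool_examples(self):
        sp = {"A a", "B b", "C c", "D d"}
        assert correct_to_pool(sp, sp | {"E e"}) == sp
        assert correct_to_pool(sp, {"Z z"}) == set()
        assert correct_to_pool(sp, {"A a", "C c", "E e"}) == {"A a", "C c"}

    def test_correct_read_table_drops_rows(self):
        t = _table({"A a": [1, 2], "B b": [3, 4]})
        out = correct_to_pool(t, {"A a"})
        assert list(out.counts.index) == ["A a"]
        assert out.total_reads == 3

    def test_richness_per_site(self):
        t = _table({"A a": [10, 0], "B b": [0, 0], "C c": [3, 0]})
        r = richness_per_site(t)
        assert list(r) == [2, 0]

    def test_richness_monotone_under_correction(self, rng):
        for _ in range(50):
            t = random_read_table(rng)
            pool = {s for s in t.counts.index if rng.random() < 0.6}
            before = richness_per_site(t)
            after = richness_per_site(correct_to_pool(t, pool))
            after = after.reindex(before.index, fill_value=0)
            assert (after <= before).all()


class TestExtraLocalBarcodes:
    def test_counting(self):
        refdb = ReferenceDB("12S", frozenset({"A a", "B b"}))
        assert extra_local_barcode_count(set(), refdb) == 0
        extra = {"A a", "B b", "C c", "D d", "E e"}
        assert extra_local_barcode_count(extra, refdb) == 2
        assert extra_local_barcode_count(extra, refdb) <= len(extra)

    def test_negative_count_rejected_at_table_construction(self):
        with pytest.raises(ValueError):
            _table({"A a": [-1, 2]})
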