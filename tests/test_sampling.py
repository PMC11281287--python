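"""Dataset construction: session equalization, bias schedules with floor
retention, and the two split modes (plant-stratified vs random)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specband.sampling import (BDI_FRACTIONS, BDT_FRACTIONS, BiasSchema,
                               apply_bias, build_dataset, equalize_sessions,
                               split_random, split_stratified)

from conftest import make_manifest, make_plant_manifest


class TestEqualizeSessions:
    def test_already_equal_cells_kept_whole(self):
        m = make_manifest({(s, t): 10 for s in (1, 2) for t in "CD"})
        out = equalize_sessions(m, seed=0)
        assert out.groupby(["imaging", "treatment"]).size().eq(10).all()

    def test_min_rule(self):
        m = make_manifest({(1, "C"): 12, (1, "D"): 9, (2, "C"): 15, (2, "D"): 9})
        out = equalize_sessions(m, seed=0)
        assert out.groupby(["imaging", "treatment"]).size().eq(9).all()

    def test_deterministic_per_seed_and_row_order_invariant(self):
        m = make_manifest({(1, "C"): 12, (1, "D"): 9})
        a = equalize_sessions(m, seed=3)
        b = equalize_sessions(m.sample(frac=1, random_state=7), seed=3)
        assert list(a["sample_id"]) == list(b["sample_id"])

    def test_empty_cell_is_named(self):
        m = make_manifest({(1, "C"): 5, (2, "C"): 5, (2, "D"): 5, (1, "D"): 5})
        m = m[~((m["imaging"] == 2) & (m["treatment"] == "D"))]
        with pytest.raises(ValueError, match=r"\(2, 'D'\)"):
            equalize_sessions(m, seed=0)


class TestApplyBias:
    @pytest.mark.parametrize("n, fraction, kept", [
        (306, 0.20, 61), (306, 0.60, 183), (58, 0.20, 11),
        (151, 0.20, 30), (30, 0.20, 6),
    ])
    def test_floor_retention_reproduces_reference_counts(self, n, fraction, kept):
        m = make_manifest({(1, "C"): n})
        schema = BiasSchema("UD", {(1, "C"): fraction})
        assert len(apply_bias(m, schema, seed=0)) == kept

    @given(n=st.integers(1, 400), pct=st.integers(0, 100))
    @settings(max_examples=60, deadline=None)
    def test_cell_size_equals_floor_of_fraction(self, n, pct):
        f = pct / 100
        m = make_manifest({(1, "D"): n})
        out = apply_bias(m, BiasSchema("UD", {(1, "D"): f}), seed=1)
        assert len(out) == int(np.floor(f * n))

    def test_fraction_one_is_identity_per_cell(self):
        m = make_manifest({(s, t): 17 for s in (1, 2) for t in "CD"})
        schema = BiasSchema("UD", {(s, t): 1.0 for s in (1, 2) for t in "CD"})
        out = apply_bias(m, schema, seed=0)
        assert sorted(out["sample_id"]) == sorted(m["sample_id"])


class TestSplitRandom:
    def test_exact_counts_100(self):
        m = make_plant_manifest(5, 5, n_sessions=2)  # 100 samples
        s = split_random(m, seed=0)
        assert (len(s.train), len(s.test), len(s.validation)) == (65, 20, 15)

    def test_remainder_goes_to_train_101(self):
        m = make_plant_manifest(5, 5, n_sessions=2)
        m = m.iloc[:101] if len(m) > 101 else m
        extra = m.iloc[[0]].assign(sample_id="extra")
        m = __import__("pandas").concat([m, extra], ignore_index=True)
        s = split_random(m, seed=0)
        assert (len(s.train), len(s.test), len(s.validation)) == (66, 20, 15)

    def test_partition_is_disjoint_and_complete(self):
        m = make_plant_manifest(4, 3, n_sessions=2)
        s = split_random(m, seed=5)
        all_ids = s.train + s.test + s.validation
        assert len(set(all_ids)) == len(all_ids) == len(m)


class TestSplitStratified:
    def test_no_plant_spans_train_and_test(self):
        m = make_plant_manifest(6, lambda p: 3 + p % 4, n_sessions=3)
        s = split_stratified(m, seed=2)
        ident = m.set_index("sample_id")["identifier"]
        assert not (set(ident[s.train]) & set(ident[s.test]))

    def test_fractions_close_to_targets_with_equal_counts(self):
        m = make_plant_manifest(10, 4, n_sessions=5)  # 20 plants x 20 tiles
        s = split_stratified(m, seed=0)
        share = 1 / 20  # one plant's share of samples
        assert abs(len(s.train) / len(m) - 0.65) <= share + 1e-9

    def test_row_order_invariance(self):
        m = make_plant_manifest(5, lambda p: 2 + p, n_sessions=2)
        a = split_stratified(m, seed=9)
        b = split_stratified(m.sample(frac=1, random_state=3), seed=9)
        assert a.train == b.train and a.test == b.test

    def test_both_treatments_in_every_set(self):
        m = make_plant_manifest(5, 4, n_sessions=2)
        s = split_stratified(m, seed=1)
        ident = m.set_index("sample_id")["treatment"]
        for ids in (s.train, s.test, s.validation):
            assert set(ident[ids]) == {"C", "D"}

    def test_too_few_plants_rejected(self):
        m = make_plant_manifest(2, 4)
        with pytest.raises(ValueError, match="3 distinct plants"):
            split_stratified(m, seed=0)


class TestBuildDataset:
    def test_udss_composition_equal_session_counts(self):
        m = make_plant_manifest(6, lambda p: 3 + p % 3, n_sessions=3)
        filtered, split = build_dataset(m, "UD-SS", seed=0)
        sizes = filtered.groupby(["imaging", "treatment"]).size()
        assert sizes.nunique() == 1
        assert split.mode == "stratified"

    def test_bdtss_five_session_schedule(self):
        m = make_plant_manifest(8, 4, n_sessions=5)
        filtered, _ = build_dataset(m, "BDT-SS", seed=0)
        sizes = filtered.groupby(["imaging", "treatment"]).size()
        n = 8 * 4  # equalized cell size
        assert sizes.loc[(1, "C")] == n and sizes.loc[(1, "D")] == int(0.2 * n)
        assert sizes.loc[(3, "C")] == sizes.loc[(3, "D")] == int(0.6 * n)
        assert sizes.loc[(5, "C")] == int(0.2 * n) and sizes.loc[(5, "D")] == n
        assert sizes.loc[(3, "D")] > sizes.loc[(1, "D")]

    def test_bdiss_keeps_full_late_sessions(self):
        m = make_plant_manifest(8, 4, n_sessions=5)
        filtered, _ = build_dataset(m, "BDI-SS", seed=0)
        sizes = filtered.groupby(["imaging", "treatment"]).size()
        n = 8 * 4
        for t in "CD":
            assert sizes.loc[(4, t)] == n and sizes.loc[(5, t)] == n
            assert sizes.loc[(1, t)] == int(0.2 * n)

    def test_udrs_uses_random_split(self):
        m = make_plant_manifest(5, 4, n_sessions=2)
        _, split = build_dataset(m, "UD-RS", seed=0)
        assert split.mode == "random"

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError, match="unknown schema"):
            build_dataset(make_plant_manifest(4, 4), "XX-SS", seed=0)

    def test_default_bias_schedules_cover_five_sessions(self):
        assert set(BDT_FRACTIONS) == {(s, t) for s in range(1, 6) for t in "CD"}
        assert set(BDI_FRACTIONS) == {(s, t) for s in range(1, 6) for t in "CD"}
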