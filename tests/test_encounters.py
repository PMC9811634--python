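"""Encounter table validation, inclusion filters and per-individual summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefcontests import encounters as ed
from conftest import enc, make_records, pair_block


class TestReadValidate:
    def test_round_trip_three_rows(self, toy_records, tmp_path):
        path = tmp_path / "enc.csv"
        ed.write_encounters(toy_records, path)
        records, rejects = ed.read_encounters(path)
        assert len(records) == len(toy_records)
        assert rejects.empty
        assert list(records.columns) == ed.COLUMNS

    def test_tab_delimiter_sniffed(self, toy_records, tmp_path):
        path = tmp_path / "enc.tsv"
        ed.write_encounters(toy_records, path, delimiter="\t")
        records, _ = ed.read_encounters(path)
        assert len(records) == len(toy_records)

    def test_chase_without_distance_is_invalid(self):
        df = make_records([enc(outcome="chase", dist=np.nan)])
        with pytest.raises(ed.ValidationError, match="row 0"):
            ed.validate_encounters(df)

    def test_distance_on_non_chase_is_invalid(self):
        df = make_records([enc(outcome="signal", dist=1.0)])
        with pytest.raises(ed.ValidationError):
            ed.validate_encounters(df)

    @pytest.mark.parametrize(
        "label,expected",
        [("0–24 cm", 1), ("25-49 cm", 2), ("50–74", 3), ("75-100 cm", 4), ("2", 2)],
    )
    def test_proximity_label_dialect(self, label, expected):
        df = make_records([enc(prox=label)])
        valid, _ = ed.validate_encounters(df)
        assert valid["proximity_cat"].iloc[0] == expected

    def test_collect_mode_preserves_row_count(self):
        df = make_records(
            [enc(), enc(prox=7), enc(period="during"), enc(outcome="chase", dist=3.0)]
        )
        valid, rejects = ed.validate_encounters(df, on_invalid="collect")
        assert len(valid) + len(rejects) == len(df)
        assert set(rejects.index) == {1, 2}
        assert rejects["reason"].str.len().gt(0).all()

    def test_missing_column_is_configuration_error(self, toy_records):
        with pytest.raises(ed.ConfigurationError, match="focal_species"):
            ed.validate_encounters(toy_records.drop(columns=["focal_species"]))

    def test_column_map(self, toy_records, tmp_path):
        renamed = toy_records.rename(columns={"focal_species": "sp_focal"})
        path = tmp_path / "enc.csv"
        renamed.to_csv(path, index=False)
        records, _ = ed.read_encounters(path, column_map={"sp_focal": "focal_species"})
        assert len(records) == len(toy_records)

    def test_negative_chase_distance_rejected(self):
        df = make_records([enc(outcome="chase", dist=-1.0)])
        with pytest.raises(ed.ValidationError):
            ed.validate_encounters(df)


class TestClassify:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("C. trifascialis", "C. trifascialis", "conspecific"),
            ("C. trifascialis", "C. baronessa", "heterospecific"),
            ("  C. trifascialis ", "c. trifascialis", "conspecific"),
        ],
    )
    def test_classification(self, a, b, expected):
        assert ed.classify_encounter(a, b) == expected

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            ed.classify_encounter("", "x")

    def test_pair_key_order_independent(self):
        assert ed.PairKey("x", "y") == ed.PairKey("y", "x")
        assert ed.PairKey("x", "x").is_conspecific
        assert not ed.PairKey("x", "y").is_conspecific

    def test_every_record_classified_exactly_once(self, toy_records):
        valid, _ = ed.validate_encounters(toy_records)
        df = ed.add_pair_columns(valid)
        assert df["pair_class"].isin(["conspecific", "heterospecific"]).all()


class TestPairFilter:
    def test_toy_set_keeps_only_sufficient_pair(self):
        # P1: 5 encounters over 5 individuals; P2: 5 encounters over 2 individuals
        rows = pair_block("sp_a", "sp_b", 5) + pair_block("sp_c", "sp_d", 5, distinct_ids=2)
        records, _ = ed.validate_encounters(make_records(rows))
        kept, pairs, audit = ed.apply_pair_filter(records)
        assert pairs == {ed.PairKey("sp_a", "sp_b")}
        assert len(kept) == 5
        assert len(audit) == 2 and audit["kept"].sum() == 1

    @pytest.mark.parametrize(
        "n_enc,n_ids,expect_kept", [(4, 4, False), (6, 3, False), (5, 5, True)]
    )
    def test_thresholds(self, n_enc, n_ids, expect_kept):
        rows = pair_block("sp_a", "sp_b", n_enc, distinct_ids=n_ids)
        records, _ = ed.validate_encounters(make_records(rows))
        _, pairs, _ = ed.apply_pair_filter(records)
        assert bool(pairs) is expect_kept

    def test_empty_input(self):
        empty = make_records([]).astype(object)
        kept, pairs, audit = ed.apply_pair_filter(empty)
        assert kept.empty and not pairs and audit.empty

    def test_audit_counts_satisfy_thresholds_for_kept_pairs(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            a, b = f"sp{rng.integers(4)}", f"sp{rng.integers(4)}"
            rows.append(enc(a, b, fid=f"f{rng.integers(8)}"))
        records, _ = ed.validate_encounters(make_records(rows))
        crit = ed.FilterCriteria(min_encounters=3, min_individuals=2)
        _, _, audit = ed.apply_pair_filter(records, crit)
        kept = audit[audit["kept"]]
        assert (kept["n_encounters"] >= 3).all() and (kept["n_individuals"] >= 2).all()

    @given(
        min_enc=st.integers(1, 8),
        min_ind=st.integers(1, 8),
        data_seed=st.integers(0, 10),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_filter_monotone(self, min_enc, min_ind, data_seed):
        """Raising either threshold never enlarges the kept record set."""
        rng = np.random.default_rng(data_seed)
        rows = [
            enc(f"sp{rng.integers(3)}", f"sp{rng.integers(3)}", fid=f"f{rng.integers(6)}")
            for _ in range(30)
        ]
        records, _ = ed.validate_encounters(make_records(rows))
        kept_loose, _, _ = ed.apply_pair_filter(records, ed.FilterCriteria(min_enc, min_ind))
        kept_tight, _, _ = ed.apply_pair_filter(
            records, ed.FilterCriteria(min_enc + 1, min_ind + 1)
        )
        assert set(kept_tight.index) <= set(kept_loose.index)

    def test_row_order_independence(self):
        rows = pair_block("sp_a", "sp_b", 6) + pair_block("sp_a", "sp_a", 7) + pair_block(
            "sp_b", "sp_c", 3
        )
        records, _ = ed.validate_encounters(make_records(rows))
        shuffled = records.sample(frac=1, random_state=4)
        _, pairs1, audit1 = ed.apply_pair_filter(records)
        _, pairs2, audit2 = ed.apply_pair_filter(shuffled)
        assert pairs1 == pairs2
        pd.testing.assert_frame_equal(
            audit1.reset_index(drop=True), audit2.reset_index(drop=True)
        )

    def test_per_period_switch_is_stricter_here(self):
        # 5 individuals pooled, but split 3/2 across periods
        rows = pair_block("sp_a", "sp_b", 3, period="before") + pair_block(
            "sp_a", "sp_b", 2, start_id=3, period="after"
        )
        records, _ = ed.validate_encounters(make_records(rows))
        _, pooled, _ = ed.apply_pair_filter(records)
        _, per_period, _ = ed.apply_pair_filter(records, per_period=True)
        assert pooled and not per_period


class TestMatchedSubset:
    def _three_species_records(self):
        # sp_a and sp_b pass in both classes; sp_c only heterospecifically
        rows = (
            pair_block("sp_a", "sp_a", 5)
            + pair_block("sp_b", "sp_b", 5)
            + pair_block("sp_a", "sp_b", 5)
            + pair_block("sp_b", "sp_a", 5)
            + pair_block("sp_c", "sp_a", 6)
        )
        records, _ = ed.validate_encounters(make_records(rows))
        return records

    def test_exactly_two_species_qualify(self):
        out = ed.build_matched_subset(self._three_species_records())
        assert set(out["focal_species"]) == {"sp_a", "sp_b"}

    def test_species_with_only_one_class_excluded(self):
        rows = pair_block("sp_a", "sp_a", 6)  # conspecific only
        records, _ = ed.validate_encounters(make_records(rows))
        assert ed.build_matched_subset(records).empty

    def test_idempotent(self):
        once = ed.build_matched_subset(self._three_species_records())
        twice = ed.build_matched_subset(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExcludeAfter:
    def test_after_record_in_region_removed_before_retained(self):
        rows = [
            enc(region="PH", period="after", fid="f1"),
            enc(region="PH", period="before", fid="f2"),
            enc(region="JP", period="after", fid="f3"),
        ]
        records, _ = ed.validate_encounters(make_records(rows))
        out = ed.exclude_after_period(records, {"PH"})
        assert len(out) == 2
        assert not ((out["region"] == "PH") & (out["period"] == "after")).any()

    def test_empty_exclusion_is_identity(self, toy_records):
        records, _ = ed.validate_encounters(toy_records)
        pd.testing.assert_frame_equal(ed.exclude_after_period(records, set()), records)

    def test_unknown_region_warns(self, toy_records):
        records, _ = ed.validate_encounters(toy_records)
        with pytest.warns(UserWarning, match="unknown region"):
            ed.exclude_after_period(records, {"atlantis"})


class TestIndividualMeans:
    def test_hand_computed_means(self):
        rows = [
            enc("sp_a", "sp_a", prox=1, fid="f1"),
            enc("sp_a", "sp_a", prox=3, fid="f1"),
            enc("sp_a", "sp_b", prox=4, fid="f1"),
            enc("sp_b", "sp_a", prox=2, fid="f2"),
            enc("sp_b", "sp_a", prox=3, fid="f2"),
            enc("sp_c", "sp_c", prox=4, fid="f3"),
        ]
        records, _ = ed.validate_encounters(make_records(rows))
        out = ed.individual_mean_proximity(records).set_index(["focal_id", "class"])
        assert out.loc[("f1", "conspecific"), "mean_proximity"] == 2.0
        assert out.loc[("f1", "heterospecific"), "mean_proximity"] == 4.0
        assert out.loc[("f2", "heterospecific"), "mean_proximity"] == 2.5
        assert out.loc[("f3", "conspecific"), "mean_proximity"] == 4.0
        assert (out["n_encounters"] >= 1).all()

    def test_mean_bounded_in_category_range(self):
        rng = np.random.default_rng(1)
        rows = [
            enc(fid=f"f{rng.integers(5)}", prox=int(rng.integers(1, 5)))
            for _ in range(50)
        ]
        records, _ = ed.validate_encounters(make_records(rows))
        out = ed.individual_mean_proximity(records)
        assert out["mean_proximity"].between(1, 4).all()


class TestCap:
    @pytest.mark.parametrize("d,expected", [(12.4, 10.0), (3.5, 3.5), (10.0, 10.0)])
    def test_cap_values(self, d, expected):
        assert ed.cap_chase_distance(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ed.ValidationError):
            ed.cap_chase_distance(-0.1)

    def test_vectorized_and_configurable(self):
        out = ed.cap_chase_distance(np.array([1.0, 6.0, 30.0]), cap=5.0)
        assert list(out) == [1.0, 5.0, 5.0]
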