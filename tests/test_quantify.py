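import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caaquant.quantify import (StudyTable, assign_compartment,
                               exclude_images_without_arterioles,
                               remove_extreme_outliers, vessel_coverage)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for y, x in coords:
        m[y, x] = True
    return m


class TestVesselCoverage:
    def test_full_overlap_is_100(self):
        wall = np.zeros((8, 8), bool)
        wall[2:5, 2:5] = True
        assert vessel_coverage(wall, wall) == 100.0

    def test_no_overlap_is_0(self):
        wall = np.zeros((8, 8), bool)
        wall[0:2, 0:2] = True
        ab = np.zeros((8, 8), bool)
        ab[6:8, 6:8] = True
        assert vessel_coverage(wall, ab) == 0.0

    def test_counted_fraction(self):
        wall = np.zeros((20, 20), bool)
        wall[:10, :20] = True          # 200 px
        ab = np.zeros((20, 20), bool)
        ab[:5, :10] = True             # 50 px inside the wall
        assert vessel_coverage(wall, ab) == pytest.approx(25.0)

    def test_empty_wall_rejected(self):
        with pytest.raises(ValueError):
            vessel_coverage(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    def test_bounds(self, rng):
        wall = rng.random((16, 16)) < 0.4
        wall[0, 0] = True
        ab = rng.random((16, 16)) < 0.3
        cov = vessel_coverage(wall, ab)
        assert 0.0 <= cov <= 100.0


class TestAssignCompartment:
    def test_fully_inside_wall_is_intramural(self):
        wall = np.ones((8, 8), bool)
        agg = _mask((8, 8), [(2, 2), (2, 3)])
        assert assign_compartment(agg, wall) == "intramural"

    def test_fully_outside_is_extramural(self):
        wall = np.zeros((8, 8), bool)
        agg = _mask((8, 8), [(2, 2)])
        assert assign_compartment(agg, wall) == "extramural"

    def test_strict_majority_boundary(self):
        shape = (4, 10)
        wall = np.zeros(shape, bool)
        wall[:, :6] = True
        six_in = _mask(shape, [(0, c) for c in range(10)])     # 6 on wall
        assert assign_compartment(six_in, wall) == "intramural"
        wall5 = np.zeros(shape, bool)
        wall5[:, :5] = True
        assert assign_compartment(six_in, wall5) == "extramural"  # exactly half

    def test_any_overlap_rule(self):
        wall = np.zeros((4, 4), bool)
        wall[0, 0] = True
        agg = _mask((4, 4), [(0, 0), (1, 1), (2, 2)])
        assert assign_compartment(agg, wall, rule="any") == "intramural"
        assert assign_compartment(agg, wall, rule="majority") == "extramural"


class TestOutlierRule:
    def test_twenty_fold_outlier_removed(self):
        kept, removed = remove_extreme_outliers([1, 2, 3, 100])
        assert list(removed) == [100]
        assert sorted(kept) == [1, 2, 3]

    def test_fifty_not_removed_against_three(self):
        kept, removed = remove_extreme_outliers([1, 2, 3, 50])
        assert len(removed) == 0
        assert sorted(kept) == [1, 2, 3, 50]

    @pytest.mark.parametrize("values", [[], [7]])
    def test_no_next_largest_means_no_removal(self, values):
        kept, removed = remove_extreme_outliers(values)
        assert list(kept) == values and len(removed) == 0

    def test_iterative_removal_of_stacked_outliers(self):
        kept, removed = remove_extreme_outliers([1, 2, 3, 100, 5000])
        assert sorted(removed) == [100, 5000]

    @given(st.lists(st.integers(1, 10**6), max_size=30))
    def test_idempotent(self, values):
        kept1, _ = remove_extreme_outliers(values)
        kept2, removed2 = remove_extreme_outliers(kept1)
        assert list(kept2) == list(kept1) and len(removed2) == 0

    def test_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            remove_extreme_outliers([1, 2], factor=1.0)


def _toy_table():
    vessels = pd.DataFrame({
        "group": ["control"] * 3,
        "mouse_id": ["m1"] * 3,
        "image_id": ["i1", "i1", "i2"],
        "vessel_id": ["v1", "v2", "v3"],
        "kind": ["arteriole", "capillary", "capillary"],
        "wall_area_px": [200, 40, 40],
        "abeta_px": [20, 0, 4],
        "coverage_pct": [10.0, 0.0, 10.0],
    })
    aggregates = pd.DataFrame({
        "group": ["control"] * 4,
        "mouse_id": ["m1"] * 4,
        "image_id": ["i1", "i1", "i2", "i2"],
        "agg_id": ["a1", "a2", "a3", "a4"],
        "size_px": [5, 9, 7, 11],
        "compartment": ["intramural", "extramural"] * 2,
    })
    return StudyTable(vessels=vessels, aggregates=aggregates)


class TestImageExclusion:
    def test_image_with_arterioles_retained(self):
        table = _toy_table()
        out = exclude_images_without_arterioles(table)
        assert "i1" not in out.exclusions["image_id"].tolist()
        assert set(out.aggregates.loc[out.aggregates.image_id == "i1", "agg_id"]) == {"a1", "a2"}

    def test_image_without_arterioles_excluded_and_logged(self):
        table = _toy_table()
        out = exclude_images_without_arterioles(table)
        assert out.exclusions["image_id"].tolist() == ["i2"]
        assert not (out.aggregates["image_id"] == "i2").any()

    def test_all_images_with_arterioles_is_identity(self):
        table = _toy_table()
        v = table.vessels.copy()
        v.loc[2, "kind"] = "arteriole"
        table2 = StudyTable(vessels=v, aggregates=table.aggregates)
        out = exclude_images_without_arterioles(table2)
        pd.testing.assert_frame_equal(out.aggregates, table2.aggregates)
        assert len(out.exclusions) == 0


class TestStudyTableInvariants:
    def test_image_mapped_to_two_mice_rejected(self):
        v = _toy_table().vessels.copy()
        v.loc[1, "mouse_id"] = "m2"
        with pytest.raises(ValueError, match="multiple mouse_ids"):
            StudyTable(vessels=v, aggregates=_toy_table().aggregates)

    def test_mouse_mapped_to_two_groups_rejected(self):
        t = _toy_table()
        a = t.aggregates.copy()
        a.loc[3, "group"] = "clu"
        with pytest.raises(ValueError, match="multiple groups"):
            StudyTable(vessels=t.vessels, aggregates=a)

    def test_compartment_partition_is_exhaustive(self):
        t = _toy_table()
        counts = t.aggregates["compartment"].value_counts()
        assert counts.sum() == len(t.aggregates)
        assert set(counts.index) <= {"intramural", "extramural"}
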