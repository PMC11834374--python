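"""IO, validation, filtering and community-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from symnet.observations import (
    NO_ASSOCIATION,
    ConfigurationError,
    FilterConfig,
    ValidationError,
    align_species,
    build_community_matrix,
    filter_observations,
    read_observations,
)

from conftest import make_table


CSV = """sample_id,year,location,aphid_species,plant_species,parasitoid_species,strain_id,source
S1,2021,site01,Aphis fabae,Vicia faba,Lysiphlebus fabarum,H231,mummy
S2,2021,site01,Aphis fabae,Vicia faba,No Association,H231,live
S3,2022,site02,Acyrthosiphon pisum,Vicia faba,Aphidius ervi,,mummy
"""


class TestReadObservations:
    def test_wellformed_csv(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(CSV)
        table = read_observations(p)
        assert len(table) == 3
        assert table.records.loc[0, "aphid_species"] == "Aphis fabae"

    def test_tsv_autodetected(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text(CSV.replace(",", "\t"))
        assert len(read_observations(p)) == 3

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text("sample_id,plant_species\nS1,Vicia faba\n")
        with pytest.raises(ConfigurationError):
            read_observations(p)

    def test_duplicate_sample_ids_reported(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(
            "sample_id,aphid_species,plant_species\nS1,a,p\nS1,b,q\n"
        )
        with pytest.raises(ValidationError, match="S1"):
            read_observations(p)

    def test_no_association_sentinel_distinct_from_missing(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text(CSV)
        df = read_observations(p).records
        # sentinel survives parsing as a value, missing becomes NaN
        assert df.loc[1, "parasitoid_species"] == NO_ASSOCIATION
        assert pd.isna(df.loc[2, "strain_id"])

    def test_column_mapping_case_insensitive(self, tmp_path):
        p = tmp_path / "obs.csv"
        p.write_text("ID,Aphid,Plant\nS1,a,p\n")
        t = read_observations(
            p, column_map={"id": "sample_id", "aphid": "aphid_species",
                           "plant": "plant_species"}
        )
        assert len(t) == 1


class TestFilterObservations:
    def test_singleton_transient_pair_removed(self):
        table = make_table(
            [
                {"aphid_species": "a1", "plant_species": "p1"},
                {"aphid_species": "a1", "plant_species": "p1"},
                {"aphid_species": "a2", "plant_species": "p9"},  # singleton
            ]
        )
        out = filter_observations(table, FilterConfig())
        assert len(out) == 2
        assert not (out.records.aphid_species == "a2").any()
        assert any("singleton" in line for line in out.provenance)

    def test_host_list_rescues_singleton(self):
        table = make_table(
            [
                {"aphid_species": "a1", "plant_species": "p1"},
                {"aphid_species": "a1", "plant_species": "p1"},
                {"aphid_species": "a2", "plant_species": "p9"},
            ]
        )
        out = filter_observations(
            table, FilterConfig(host_list={"a2": ["p9"]})
        )
        assert len(out) == 3

    def test_all_no_association_gives_empty_with_warning(self):
        table = make_table(
            [
                {"aphid_species": "a1", "plant_species": "p1",
                 "strain_id": NO_ASSOCIATION},
                {"aphid_species": "a1", "plant_species": "p1",
                 "strain_id": NO_ASSOCIATION},
            ]
        )
        out = filter_observations(table, FilterConfig(partner_kind="strain"))
        assert len(out) == 0
        assert any("warning" in line for line in out.provenance)

    def test_clean_table_unchanged(self):
        table = make_table(
            [
                {"aphid_species": "a1", "plant_species": "p1", "strain_id": "h1"},
                {"aphid_species": "a1", "plant_species": "p1", "strain_id": "h2"},
            ]
        )
        out = filter_observations(table, FilterConfig(partner_kind="strain"))
        pd.testing.assert_frame_equal(out.records, table.records)

    def test_idempotent(self):
        table = make_table(
            [
                {"aphid_species": "a1", "plant_species": "p1", "strain_id": "h1"},
                {"aphid_species": "a1", "plant_species": "p1"},
                {"aphid_species": "a2", "plant_species": "p7", "strain_id": "h1"},
            ]
        )
        rules = FilterConfig(partner_kind="strain")
        once = filter_observations(table, rules)
        twice = filter_observations(once, rules)
        pd.testing.assert_frame_equal(once.records, twice.records)


class TestCommunityMatrix:
    def test_hand_tally(self):
        table = make_table(
            [
                {"aphid_species": "aphA", "parasitoid_species": "p1"},
                {"aphid_species": "aphA", "parasitoid_species": "p1"},
                {"aphid_species": "aphA", "parasitoid_species": "p2"},
                {"aphid_species": "aphB", "parasitoid_species": "p2"},
            ]
        )
        M = build_community_matrix(table, "parasitoid")
        assert M.focal_labels == ["aphA", "aphB"]
        assert M.partner_labels == ["p1", "p2"]
        assert M.values.tolist() == [[2, 1], [0, 1]]

    def test_single_record(self):
        table = make_table([{"aphid_species": "a", "parasitoid_species": "p"}])
        M = build_community_matrix(table, "parasitoid")
        assert M.values.tolist() == [[1]]

    def test_all_absent_raises(self):
        table = make_table(
            [{"aphid_species": "a", "plant_species": "p",
              "strain_id": NO_ASSOCIATION}]
        )
        with pytest.raises(ValidationError, match="strain"):
            build_community_matrix(table, "strain")

    def test_record_conservation(self, rng):
        rows = [
            {"aphid_species": f"a{rng.integers(5)}",
             "parasitoid_species": f"p{rng.integers(4)}"}
            for _ in range(60)
        ]
        table = make_table(rows)
        M = build_community_matrix(table, "parasitoid")
        assert M.values.sum() == 60

    def test_lexicographic_and_deterministic(self):
        rows = [
            {"aphid_species": "zz", "parasitoid_species": "q"},
            {"aphid_species": "aa", "parasitoid_species": "z"},
            {"aphid_species": "mm", "parasitoid_species": "a"},
        ]
        M = build_community_matrix(make_table(rows), "parasitoid")
        assert M.focal_labels == sorted(M.focal_labels)
        assert M.partner_labels == sorted(M.partner_labels)


class TestAlignSpecies:
    def _matrix(self, species, partner_kind="parasitoid"):
        rows = [
            {"aphid_species": s, "parasitoid_species": f"p{k % 2}"}
            for k, s in enumerate(species)
        ]
        return build_community_matrix(make_table(rows), partner_kind)

    def test_small_intersection_errors(self):
        m1 = self._matrix(["A", "B", "C"])
        m2 = self._matrix(["B", "C", "D"])
        with pytest.raises(ValidationError, match="2 species"):
            align_species([m1, m2])

    def test_identical_sets_common_order(self):
        m1 = self._matrix(["C", "A", "B"])
        m2 = self._matrix(["B", "C", "A"])
        aligned, rel, dropped = align_species([m1, m2])
        assert dropped == []
        assert aligned[0].focal_labels == aligned[1].focal_labels == ["A", "B", "C"]

    def test_relatedness_restricted_with_matrices(self):
        m1 = self._matrix(["A", "B", "C", "D"])
        m2 = self._matrix(["A", "B", "C"])
        rel = pd.DataFrame(
            np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD")
        )
        aligned, rel_out, dropped = align_species([m1, m2], rel)
        assert list(rel_out.index) == ["A", "B", "C"]
        assert dropped == ["D"]
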