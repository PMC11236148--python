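import itertools

import numpy as np
import pandas as pd
import pytest

from ciliatecomm.tables import (
    AbundanceTable,
    TaxonomyTable,
    ValidationError,
    read_abundance,
    round_half_up,
    shared_species,
    summarize_composition,
    write_abundance,
)


class TestReadAbundance:
    def test_toy_parse_row_sums(self, tmp_path):
        f = tmp_path / "toy.csv"
        f.write_text("id,spA,spB\ns1,1,2\ns2,0,4\ns3,5,\n")
        ab = read_abundance(f)
        assert ab.sample_totals.tolist() == [3.0, 4.0, 5.0]
        # blank cell is a true zero
        assert ab.counts.loc["s3", "spB"] == 0

    def test_transposed_orientation(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("id,s1,s2\nspA,1,0\nspB,2,4\n")
        ab = read_abundance(f, orientation="species_rows")
        assert ab.samples == ["s1", "s2"]
        assert ab.counts.loc["s2", "spB"] == 4

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("")
        with pytest.raises(ValidationError):
            read_abundance(f)

    def test_negative_cell_names_coordinates(self, tmp_path):
        f = tmp_path / "neg.csv"
        f.write_text("id,spA,spB\ns1,1,2\ns2,0,-4\n")
        with pytest.raises(ValidationError, match=r"s2.*spB"):
            read_abundance(f)

    def test_duplicate_sample_id_named(self, tmp_path):
        f = tmp_path / "dup.csv"
        f.write_text("id,spA\ns1,1\ns1,2\n")
        with pytest.raises(ValidationError, match="s1"):
            read_abundance(f)

    def test_round_trip_identity(self, toy_abundance, tmp_path):
        path = tmp_path / "rt.tsv"
        write_abundance(toy_abundance, path)
        back = read_abundance(path)
        pd.testing.assert_frame_equal(
            back.counts, toy_abundance.counts, check_dtype=False
        )


class TestTaxonomyValidation:
    def test_inconsistent_family_order_mapping_rejected(self):
        df = pd.DataFrame(
            {
                "genus": ["g1", "g2"],
                "family": ["F", "F"],
                "order": ["O1", "O2"],
                "class": ["C", "C"],
            },
            index=["a", "b"],
        )
        with pytest.raises(ValidationError, match="family"):
            TaxonomyTable(df)


class TestComposition:
    def test_published_order_percentages(self, basin_community):
        ab, tax = basin_community
        comp = summarize_composition(ab, tax, "order").set_index("taxon")
        assert comp.loc["Haptorida", "species_count"] == 35
        assert comp.loc["Haptorida", "percent_of_total"] == 17.59
        assert comp.loc["Sessilida", "species_count"] == 19
        assert comp.loc["Sessilida", "percent_of_total"] == 9.55

    @pytest.mark.parametrize("rank", ["genus", "family", "order", "class"])
    def test_percent_sums_to_100_within_rounding(self, basin_community, rank):
        ab, tax = basin_community
        comp = summarize_composition(ab, tax, rank)
        # each 2-dp rounded percentage contributes at most 0.005 of error
        tol = max(0.05, 0.005 * len(comp))
        assert comp["percent_of_total"].sum() == pytest.approx(100.0, abs=tol)
        assert comp["species_count"].sum() == 199

    def test_single_species_is_100_percent(self):
        ab = AbundanceTable(pd.DataFrame({"spX": [3]}, index=["s1"]))
        tax = TaxonomyTable(
            pd.DataFrame(
                {"genus": ["g"], "family": ["f"], "order": ["o"], "class": ["c"]},
                index=["spX"],
            )
        )
        comp = summarize_composition(ab, tax, "class")
        assert len(comp) == 1
        assert comp["percent_of_total"].iloc[0] == 100.00

    def test_unmapped_species_listed(self, basin_community):
        ab, tax = basin_community
        trimmed = TaxonomyTable(tax.lineages.iloc[:-1])
        with pytest.raises(ValidationError, match=tax.species[-1]):
            summarize_composition(ab, trimmed, "order")


def test_round_half_up_matches_printed_convention():
    assert round_half_up(17.585) == 17.59
    assert round_half_up(9.545) == 9.55
    assert round_half_up(0.325) == 0.33


class TestSharedSpecies:
    def test_identical_groups_share_everything(self, toy_abundance):
        ab = toy_abundance
        dup = AbundanceTable(
            pd.concat([ab.counts.iloc[:3], ab.counts.iloc[:3].set_axis([f"x{i}" for i in range(3)])]),
            metadata=pd.DataFrame(
                {"ecosystem": ["a"] * 3 + ["b"] * 3},
                index=list(ab.counts.index[:3]) + [f"x{i}" for i in range(3)],
            ),
        )
        res = shared_species(dup, "ecosystem").set_index("groups")
        present = (dup.counts.sum(axis=0) > 0).sum()
        assert res.loc["a&b", "species_count"] == present
        assert res.loc["a", "species_count"] == 0
        assert res.loc["b", "species_count"] == 0

    def test_disjoint_groups_share_nothing(self):
        counts = pd.DataFrame(
            [[3, 0], [0, 5]], index=["s1", "s2"], columns=["spA", "spB"]
        )
        meta = pd.DataFrame({"ecosystem": ["a", "b"]}, index=["s1", "s2"])
        res = shared_species(AbundanceTable(counts, meta), "ecosystem").set_index("groups")
        assert res.loc["a&b", "species_count"] == 0
        assert res.loc["a", "species_count"] == 1

    def test_four_groups_match_brute_force(self):
        rng = np.random.default_rng(5)
        groups = ["g1", "g2", "g3", "g4"]
        counts = pd.DataFrame(
            rng.integers(0, 2, size=(8, 30)) * rng.integers(1, 9, size=(8, 30)),
            index=[f"s{i}" for i in range(8)],
            columns=[f"sp{j}" for j in range(30)],
        )
        meta = pd.DataFrame({"ecosystem": np.repeat(groups, 2)}, index=counts.index)
        ab = AbundanceTable(counts, meta)
        res = shared_species(ab, "ecosystem").set_index("groups")["species_count"]

        # independent oracle: enumerate each species' membership pattern
        expected = {}
        for r in range(1, 5):
            for sub in itertools.combinations(groups, r):
                expected["&".join(sub)] = 0
        for sp in counts.columns:
            members = tuple(
                g for g in groups
                if counts.loc[meta["ecosystem"] == g, sp].sum() > 0
            )
            if members:
                expected["&".join(members)] += 1
        for key, val in expected.items():
            assert res[key] == val, key

        observed_total = int((counts.sum(axis=0) > 0).sum())
        assert res.sum() == observed_total

    def test_single_group_rejected(self, toy_abundance):
        ab = toy_abundance
        ab.metadata["ecosystem"] = "only"
        with pytest.raises(ValidationError):
            shared_species(ab, "ecosystem")
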