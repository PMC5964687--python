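"""Rank aggregation, common levels, log-CPM normalization, KS platform check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cityprints as cp


def build_dataset(rows, columns, lineage_texts, metas=None):
    counts = pd.DataFrame(rows, columns=columns,
                          index=[f"OTU{i}" for i in range(len(rows))])
    return cp.OtuDataset(
        counts=counts.astype("int64"),
        lineages=[cp.Lineage.parse(t) for t in lineage_texts],
        samples=metas or [],
    )


FIVE_OTUS = build_dataset(
    rows=[[3, 0], [4, 1], [2, 2], [5, 0], [1, 9]],
    columns=["S1", "S2"],
    lineage_texts=[
        "k__B; o__Clostridiales; f__Lachnospiraceae; g__Blautia",
        "k__B; o__Clostridiales; f__Lachnospiraceae; g__Dorea",
        "k__B; o__Clostridiales; f__Ruminococcaceae; g__",     # no genus
        "k__B; o__Enterobacteriales; f__Enterobacteriaceae; g__Escherichia",
        "k__B; o__; f__; g__",                                  # no ranks
    ],
)


class TestAggregation:
    def test_same_order_otus_are_summed(self):
        table = cp.aggregate_to_rank(FIVE_OTUS, "order")
        assert table.counts.loc["Clostridiales", "S1"] == 3 + 4 + 2

    def test_missing_rank_goes_to_excluded_mass(self):
        at_family = cp.aggregate_to_rank(FIVE_OTUS, "family")
        at_genus = cp.aggregate_to_rank(FIVE_OTUS, "genus")
        # OTU4 lacks every rank; OTU2 additionally lacks genus
        assert at_family.excluded_mass.tolist() == [1, 9]
        assert at_genus.excluded_mass.tolist() == [1 + 2, 9 + 2]
        assert "Ruminococcaceae" in at_family.counts.index

    @pytest.mark.parametrize("rank", ["order", "family", "genus"])
    def test_mass_conservation_assigned_plus_excluded(self, rank):
        table = cp.aggregate_to_rank(FIVE_OTUS, rank)
        totals = table.counts.sum(axis=0) + table.excluded_mass
        assert totals.tolist() == FIVE_OTUS.counts.sum(axis=0).tolist()

    def test_unknown_rank_rejected(self):
        with pytest.raises(cp.PreconditionError):
            cp.aggregate_to_rank(FIVE_OTUS, "phylum")

    def test_conservation_on_synthetic_dataset(self, small_dataset):
        _, ds = small_dataset
        for rank in cp.AGGREGATION_RANKS:
            table = cp.aggregate_to_rank(ds, rank)
            lhs = table.counts.sum(axis=0) + table.excluded_mass
            assert lhs.tolist() == ds.counts.sum(axis=0).tolist()


def rank_table(rank, counts, cities):
    meta = pd.DataFrame(
        {"city": cities, "platform": ["WGS"] * len(cities)},
        index=pd.Index(list(counts.columns), name="sample_id"),
    )
    return cp.RankTable(rank=rank, counts=counts.astype("int64"), meta=meta)


class TestCommonLevels:
    @staticmethod
    def tables_from_supports(supports):
        out = {}
        levels = sorted(set().union(*supports.values()))
        for i, (city, levs) in enumerate(supports.items()):
            counts = pd.DataFrame(
                {f"{city}_s": [1 if lv in levs else 0 for lv in levels]},
                index=levels,
            )
            out[city] = rank_table("order", counts, [city])
        return out

    def test_intersection_and_venn_regions(self):
        tables = self.tables_from_supports(
            {"X": {"A", "B"}, "Y": {"B", "C"}, "Z": {"B"}}
        )
        common, venn = cp.common_levels(tables)
        assert common == ["B"]
        assert venn[frozenset({"X"})] == 1            # A
        assert venn[frozenset({"Y"})] == 1            # C
        assert venn[frozenset({"X", "Y", "Z"})] == 1  # B
        assert sum(venn.values()) == 3

    def test_zero_count_level_excluded_from_support(self):
        tables = self.tables_from_supports({"X": {"A", "B"}, "Y": {"A"}})
        tables["Y"].counts.loc["B"] = 0    # present as a row but zero
        common, _ = cp.common_levels(tables)
        assert common == ["A"]

    def test_intersection_order_invariant_and_idempotent(self):
        supports = {"X": {"A", "B", "C"}, "Y": {"B", "C"}, "Z": {"C", "B"}}
        tables = self.tables_from_supports(supports)
        c1, _ = cp.common_levels(tables)
        c2, _ = cp.common_levels(dict(reversed(list(tables.items()))))
        assert c1 == c2 == ["B", "C"]

    def test_generator_ground_truth_intersection(self, small_dataset):
        spec, ds = small_dataset
        table = cp.aggregate_to_rank(ds, "genus")
        common, _ = cp.common_levels(cp.split_by_city(table))
        assert len(common) == len(spec.shared_taxa)

    def test_rank_mismatch_rejected(self):
        tables = self.tables_from_supports({"X": {"A"}, "Y": {"A"}})
        tables["Y"].rank = "genus"
        with pytest.raises(cp.PreconditionError):
            cp.common_levels(tables)


class TestNormalization:
    def test_zero_count_in_near_million_sample_gives_minus_one(self):
        counts = pd.DataFrame({"S1": [0, 999_999]}, index=["A", "B"])
        norm = cp.normalize_log_cpm(rank_table("order", counts, ["X"]))
        assert norm.values.loc["A", "S1"] == pytest.approx(-1.0, abs=1e-12)

    def test_count_one_gives_log2_of_one_and_a_half(self):
        counts = pd.DataFrame({"S1": [1, 999_998]}, index=["A", "B"])
        norm = cp.normalize_log_cpm(rank_table("order", counts, ["X"]))
        assert norm.values.loc["A", "S1"] == pytest.approx(
            np.log2(1.5), rel=1e-9
        )

    def test_full_sample_count_stays_below_cpm_bound(self):
        counts = pd.DataFrame({"S1": [100, 0]}, index=["A", "B"])
        norm = cp.normalize_log_cpm(rank_table("order", counts, ["X"]))
        assert norm.values.loc["A", "S1"] < np.log2(1e6)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"S1": [1, 2], "S2": [0, 0]}, index=["A", "B"])
        with pytest.raises(cp.ValidationError, match="S2"):
            cp.normalize_log_cpm(rank_table("order", counts, ["X", "X"]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10**6),
                    min_size=2, max_size=12).filter(lambda xs: sum(xs) > 0))
    def test_ratio_strictly_inside_unit_interval(self, column):
        counts = pd.DataFrame({"S1": column},
                              index=[f"L{i}" for i in range(len(column))])
        norm = cp.normalize_log_cpm(rank_table("order", counts, ["X"]))
        values = norm.values["S1"].to_numpy()
        total = sum(column)
        assert (values < np.log2(1e6)).all()
        assert (values > np.log2(0.5 / (total + 1) * 1e6) - 1e-9).all()

    def test_monotone_in_count_at_fixed_sample_total(self):
        a = pd.DataFrame({"S1": [10, 90]}, index=["A", "B"])
        b = pd.DataFrame({"S1": [11, 89]}, index=["A", "B"])
        na = cp.normalize_log_cpm(rank_table("order", a, ["X"]))
        nb = cp.normalize_log_cpm(rank_table("order", b, ["X"]))
        assert nb.values.loc["A", "S1"] > na.values.loc["A", "S1"]


class TestKsPlatformCheck:
    @staticmethod
    def norm_with_platforms(platforms, shift=0.0, n_levels=4, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n_levels, len(platforms)))
        values[:, np.array(platforms) == "Amplicon"] += shift
        frame = pd.DataFrame(values, index=[f"L{i}" for i in range(n_levels)],
                             columns=[f"S{i}" for i in range(len(platforms))])
        meta = pd.DataFrame({"city": ["X"] * len(platforms),
                             "platform": platforms},
                            index=frame.columns)
        return cp.NormalizedTable(rank="order", values=frame, meta=meta)

    def test_identical_platform_values_give_p_one(self):
        values = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["L0"],
                              columns=["S0", "S1", "S2", "S3"])
        meta = pd.DataFrame({"city": ["X"] * 4,
                             "platform": ["WGS", "WGS", "Amplicon", "Amplicon"]},
                            index=values.columns)
        report = cp.ks_platform_check(
            cp.NormalizedTable(rank="order", values=values, meta=meta)
        )
        assert report.table.loc["L0", "statistic"] == 0.0
        assert report.table.loc["L0", "p_value"] == 1.0

    def test_large_shift_detected(self):
        norm = self.norm_with_platforms(["WGS"] * 50 + ["Amplicon"] * 50,
                                        shift=5.0)
        report = cp.ks_platform_check(norm)
        assert report.p_max < 0.001

    def test_single_platform_skipped_with_notice(self, caplog):
        norm = self.norm_with_platforms(["WGS"] * 6)
        with caplog.at_level("WARNING"):
            report = cp.ks_platform_check(norm)
        assert report.skipped and report.p_min is None
        assert "skipped" in caplog.text
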