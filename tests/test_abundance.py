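"""Balanced-subsample ANOVA, BH selection, Tukey letter patterns."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import cityprints as cp


def norm_from_groups(groups, cities=("A", "B", "C"), rank="order"):
    """NormalizedTable from a dict level -> list of per-city value arrays."""
    levels = list(groups)
    blocks, metas = [], []
    n_per = [len(v) for v in groups[levels[0]]]
    columns = []
    for k, city in enumerate(cities):
        for j in range(n_per[k]):
            columns.append(f"{city}{j}")
            metas.append((city, "WGS"))
    values = np.array([
        np.concatenate([np.asarray(v, dtype=float) for v in groups[lv]])
        for lv in levels
    ])
    frame = pd.DataFrame(values, index=levels, columns=columns)
    meta = pd.DataFrame({"city": [m[0] for m in metas],
                         "platform": [m[1] for m in metas]},
                        index=pd.Index(columns, name="sample_id"))
    return cp.NormalizedTable(rank=rank, values=frame, meta=meta)


class TestLetterPattern:
    # pairwise significance bits (d01, d02, d12) -> pattern class
    CASES = {
        (0, 0, 0): "a-a-a",
        (0, 0, 1): "other",
        (0, 1, 0): "other",
        (0, 1, 1): "a-a-b",
        (1, 0, 0): "other",
        (1, 0, 1): "a-b-a",
        (1, 1, 0): "a-b-b",
        (1, 1, 1): "a-b-c",
    }

    def test_exhaustive_enumeration_of_all_bit_combinations(self):
        for bits, expected in self.CASES.items():
            d01, d02, d12 = (bool(b) for b in bits)
            got = cp.letter_pattern({(0, 1): d01, (0, 2): d02, (1, 2): d12})
            assert got == expected, bits

    def test_every_combination_maps_to_exactly_one_class(self):
        targets = {"a-a-a", "a-a-b", "a-b-a", "a-b-b", "a-b-c", "other"}
        seen = set()
        for bits in itertools.product([0, 1], repeat=3):
            pattern = cp.letter_pattern(
                {(0, 1): bool(bits[0]), (0, 2): bool(bits[1]),
                 (1, 2): bool(bits[2])}
            )
            assert pattern in targets
            seen.add(pattern)
        assert seen == targets


class TestBalancedSubsample:
    @staticmethod
    def unbalanced_norm(sizes=(40, 60, 18)):
        rng = np.random.default_rng(0)
        groups = {
            "L0": [rng.normal(size=s) for s in sizes],
            "L1": [rng.normal(size=s) for s in sizes],
        }
        return norm_from_groups(groups)

    def test_draws_equal_sizes_keeping_smallest_city_whole(self):
        norm = self.unbalanced_norm()
        sub = cp.balanced_subsample(norm, 18, seed=1)
        counts = sub.meta["city"].value_counts()
        assert set(counts) == {18}
        c_ids = set(norm.meta.index[norm.meta["city"] == "C"])
        assert set(sub.meta.index[sub.meta["city"] == "C"]) == c_ids

    def test_n_exceeding_smallest_city_rejected(self):
        with pytest.raises(cp.PreconditionError):
            cp.balanced_subsample(self.unbalanced_norm(), 19, seed=0)

    def test_two_seeds_differ_only_in_subsampled_cities(self):
        norm = self.unbalanced_norm()
        s1 = cp.balanced_subsample(norm, 18, seed=1)
        s2 = cp.balanced_subsample(norm, 18, seed=2)
        a_1 = set(s1.meta.index[s1.meta["city"] == "A"])
        a_2 = set(s2.meta.index[s2.meta["city"] == "A"])
        assert a_1 != a_2
        c_1 = set(s1.meta.index[s1.meta["city"] == "C"])
        c_2 = set(s2.meta.index[s2.meta["city"] == "C"])
        assert c_1 == c_2


class TestAnovaTukeyReplicate:
    def test_f_and_p_match_hand_computed_anova(self):
        groups = {"L0": [[1.0, 2, 3, 4], [2.0, 3, 4, 5], [8.0, 9, 10, 11]]}
        norm = norm_from_groups(groups)
        out = cp.anova_tukey_replicate(norm, fdr=0.05, tukey_alpha=0.05)
        f_oracle = stats.f_oneway(*groups["L0"])
        assert out.loc["L0", "p_value"] == pytest.approx(f_oracle.pvalue,
                                                         rel=1e-9)

    def test_identical_city_values_not_selected(self):
        groups = {"L0": [[1.0, 2, 3], [1.0, 2, 3], [1.0, 2, 3]],
                  "L1": [[0.0, 5, 9], [9.0, 0, 5], [5.0, 9, 0]]}
        out = cp.anova_tukey_replicate(norm_from_groups(groups))
        assert not out["selected"].any()
        assert out["pattern"].isna().all()

    @pytest.mark.parametrize("shifts,expected", [
        ((0.0, 30.0, 60.0), "a-b-c"),
        ((0.0, 0.0, 30.0), "a-a-b"),
        ((0.0, 30.0, 0.0), "a-b-a"),
        ((0.0, 30.0, 30.0), "a-b-b"),
    ])
    def test_planted_mean_structure_recovers_each_pattern(self, shifts,
                                                          expected):
        rng = np.random.default_rng(1)
        groups = {"L0": [rng.normal(s, 1.0, size=10) for s in shifts]}
        out = cp.anova_tukey_replicate(norm_from_groups(groups), fdr=0.05,
                                       tukey_alpha=0.05)
        assert out.loc["L0", "pattern"] == expected

    def test_tukey_decisions_match_statsmodels_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(25):
            shift = rng.uniform(0, 3, size=3)
            data = [rng.normal(shift[g], 1.0, size=8) for g in range(3)]
            norm = norm_from_groups({"L0": data})
            out = cp.anova_tukey_replicate(norm, fdr=0.999999,
                                           tukey_alpha=0.05)
            if not out.loc["L0", "selected"]:
                continue
            flat = np.concatenate(data)
            labels = np.repeat(["A", "B", "C"], 8)
            oracle = pairwise_tukeyhsd(flat, labels, alpha=0.05)
            oracle_bits = {
                (0, 1): bool(oracle.reject[0]),
                (0, 2): bool(oracle.reject[1]),
                (1, 2): bool(oracle.reject[2]),
            }
            assert out.loc["L0", "pattern"] == cp.letter_pattern(oracle_bits)

    def test_zero_within_variance_with_between_signal_selected(self):
        groups = {"L0": [[1.0, 1, 1], [2.0, 2, 2], [3.0, 3, 3]]}
        out = cp.anova_tukey_replicate(norm_from_groups(groups))
        assert out.loc["L0", "p_value"] == 0.0
        assert out.loc["L0", "selected"]
        assert out.loc["L0", "pattern"] == "a-b-c"

    def test_adjusted_pairwise_p_values_available_on_request(self):
        rng = np.random.default_rng(3)
        groups = {"L0": [rng.normal(s, 1, 10) for s in (0, 5, 10)]}
        out = cp.anova_tukey_replicate(norm_from_groups(groups),
                                       adjusted_p=True)
        cols = [c for c in out.columns if c.startswith("tukey_p_")]
        assert len(cols) == 3
        assert (out[cols].loc["L0"] < 0.01).all()

    def test_unbalanced_groups_rejected(self):
        groups = {"L0": [[1.0, 2], [1.0, 2, 3], [1.0, 2]]}
        with pytest.raises(cp.PreconditionError):
            cp.anova_tukey_replicate(norm_from_groups(groups))


class TestBhMonotonicity:
    def test_lowering_fdr_never_selects_more_levels(self):
        rng = np.random.default_rng(4)
        groups = {
            f"L{i}": [rng.normal(rng.uniform(0, 1.5), 1, 12)
                      for _ in range(3)]
            for i in range(15)
        }
        norm = norm_from_groups(groups)
        previous = None
        for fdr in (0.2, 0.1, 0.05, 0.01, 0.001):
            selected = set(
                cp.anova_tukey_replicate(norm, fdr=fdr).query("selected").index
            )
            if previous is not None:
                assert selected <= previous
            previous = selected


class TestReplicateSummary:
    def test_single_replicate_equals_one_replicate_run(self):
        rng = np.random.default_rng(5)
        groups = {f"L{i}": [rng.normal(3 * g, 1, 18) for g in range(3)]
                  for i in range(4)}
        norm = norm_from_groups(groups)
        summary = cp.replicate_summary(norm, replicates=1, n=18, seed=7)
        single = cp.anova_tukey_replicate(norm)
        for level in single.index:
            level_counts = summary.table.loc[level]["count"]
            if single.loc[level, "selected"]:
                pattern = single.loc[level, "pattern"]
                assert level_counts.sum() == (pattern in cp.PATTERNS)
                if pattern in cp.PATTERNS:
                    assert level_counts[pattern] == 1
                    assert summary.table.loc[(level, pattern), "p_mean"] == \
                        pytest.approx(single.loc[level, "p_value"])
            else:
                assert level_counts.sum() == 0

    def test_counts_never_exceed_replicates_and_pmin_le_pmax(self, small_norm):
        summary = cp.replicate_summary(small_norm, replicates=40, n=18, seed=3)
        per_level = summary.table["count"].groupby("level").sum()
        assert (per_level <= 40).all()
        counted = summary.table.dropna(subset=["p_min"])
        assert (counted["p_min"] <= counted["p_mean"] + 1e-15).all()
        assert (counted["p_mean"] <= counted["p_max"] + 1e-15).all()
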