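"""Rank aggregation, cross-city common levels, log-CPM normalization, KS check.

OTU counts are summed into named taxa at one of three ranks (order, family,
genus); OTUs whose lineage lacks the rank are excluded and their count mass
reported.  Cross-city analyses are restricted to *common levels* — taxa with
nonzero total count in every city.  Counts are then normalized to log2
counts-per-million with a half-count offset and a library offset of one:

    y_gi = log2( (r_gi + 0.5) / (N * R_i + 1) * 1e6 )

where r_gi is the count of level g in sample i, N the number of levels and
R_i the mean per-level count of sample i, so N * R_i is sample i's total.
The offsets bound the ratio strictly inside (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AGGREGATION_RANKS, OtuDataset
from .errors import PreconditionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RankTable",
    "NormalizedTable",
    "KsReport",
    "aggregate_to_rank",
    "split_by_city",
    "common_levels",
    "restrict_to_common",
    "normalize_log_cpm",
    "ks_platform_check",
]


@dataclass
class RankTable:
    """Level x sample integer counts at one taxonomic rank."""

    rank: str
    counts: pd.DataFrame                 # level x sample, int
    meta: pd.DataFrame                   # sample_id-indexed city/platform
    common_only: bool = False
    excluded_mass: pd.Series = field(default_factory=lambda: pd.Series(dtype="int64"))

    def cities(self) -> list:
        seen: dict = {}
        for c in self.meta["city"]:
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class NormalizedTable:
    """log2-CPM values on a RankTable's levels."""

    rank: str
    values: pd.DataFrame                 # level x sample, float
    meta: pd.DataFrame
    common_only: bool = False

    def cities(self) -> list:
        seen: dict = {}
        for c in self.meta["city"]:
            seen.setdefault(c, None)
        return list(seen)


def aggregate_to_rank(dataset: OtuDataset, rank: str) -> RankTable:
    """Sum OTU counts into named levels at ``rank``.

    OTUs with a missing rank token contribute to no level; their per-sample
    count mass is returned in ``excluded_mass`` so aggregation conserves
    totals (assigned + excluded = original).
    """
    if rank not in AGGREGATION_RANKS:
        raise PreconditionError(
            f"rank {rank!r} not in {AGGREGATION_RANKS}"
        )
    dataset.validate(require_metadata=bool(dataset.samples))
    names = [lin.get(rank) for lin in dataset.lineages]
    assigned = pd.Series(names, index=dataset.counts.index)
    mask = assigned.notna()
    excluded = dataset.counts.loc[~mask.to_numpy()].sum(axis=0)
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info(
            "rank %s: %d OTUs lack the rank; %d counts excluded",
            rank, n_excluded, int(excluded.sum()),
        )
    grouped = dataset.counts.loc[mask.to_numpy()].groupby(
        assigned[mask].to_numpy()
    ).sum()
    grouped.index.name = rank
    meta = dataset.metadata_frame() if dataset.samples else pd.DataFrame(
        index=dataset.counts.columns
    )
    return RankTable(rank=rank, counts=grouped.astype("int64"), meta=meta,
                     excluded_mass=excluded.astype("int64"))


def split_by_city(table: RankTable) -> dict:
    """One RankTable per city, columns restricted to that city's samples."""
    out = {}
    for city in table.cities():
        cols = table.meta.index[table.meta["city"] == city]
        out[city] = RankTable(
            rank=table.rank,
            counts=table.counts[list(cols)],
            meta=table.meta.loc[list(cols)],
            common_only=table.common_only,
            excluded_mass=table.excluded_mass.reindex(list(cols)).fillna(0).astype("int64")
            if len(table.excluded_mass) else table.excluded_mass,
        )
    return out


def common_levels(tables: dict) -> tuple:
    """Intersection of per-city level supports plus the Venn region counts.

    A level is *present* in a city when its summed count there is nonzero.
    Returns ``(sorted common level list, venn dict)``; the Venn dict maps each
    nonempty city subset (frozenset) to the number of levels present in
    exactly those cities.
    """
    if len(tables) < 2:
        raise PreconditionError("need at least 2 cities for common levels")
    ranks = {t.rank for t in tables.values()}
    if len(ranks) != 1:
        raise PreconditionError(f"rank mismatch across cities: {sorted(ranks)}")
    supports = {
        city: set(t.counts.index[t.counts.sum(axis=1) > 0])
        for city, t in tables.items()
    }
    cities = list(supports)
    universe = set().union(*supports.values())
    venn: dict = {}
    for level in universe:
        members = frozenset(c for c in cities if level in supports[c])
        venn[members] = venn.get(members, 0) + 1
    common = set.intersection(*supports.values())
    return sorted(common), venn


def restrict_to_common(table: RankTable, levels) -> RankTable:
    """Slice a RankTable down to the given (common) levels."""
    missing = [lv for lv in levels if lv not in table.counts.index]
    if missing:
        raise ValidationError(f"levels absent from table: {missing[:5]}")
    return replace(table, counts=table.counts.loc[list(levels)], common_only=True)


def normalize_log_cpm(table: RankTable) -> NormalizedTable:
    """Apply the log2-CPM transform entrywise to a RankTable.

    Samples with zero total count cannot represent a library and are
    rejected; drop them upstream.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(table.counts.columns[totals == 0])
        raise ValidationError(
            f"samples with zero total count at rank {table.rank!r}: {bad[:5]}"
        )
    # N * R_i = total count of sample i over the table's levels
    ratio = (counts + 0.5) / (totals[None, :] + 1.0)
    values = np.log2(ratio * 1e6)
    frame = pd.DataFrame(values, index=table.counts.index,
                         columns=table.counts.columns)
    return NormalizedTable(rank=table.rank, values=frame, meta=table.meta,
                           common_only=table.common_only)


@dataclass
class KsReport:
    """Per-level two-sample Kolmogorov-Smirnov comparison of WGS vs Amplicon."""

    rank: str
    table: pd.DataFrame        # level x (statistic, p_value)
    skipped: bool = False
    reason: str = ""

    @property
    def p_min(self):
        return float(self.table["p_value"].min()) if not self.skipped else None

    @property
    def p_max(self):
        return float(self.table["p_value"].max()) if not self.skipped else None


def ks_platform_check(norm: NormalizedTable) -> KsReport:
    """Two-sided two-sample KS test per level, WGS vs Amplicon samples.

    Skipped (with a notice) unless both platforms have at least two samples.
    """
    platforms = norm.meta["platform"]
    wgs = norm.values.loc[:, (platforms == "WGS").to_numpy()]
    amp = norm.values.loc[:, (platforms == "Amplicon").to_numpy()]
    if wgs.shape[1] < 2 or amp.shape[1] < 2:
        reason = (
            f"need >=2 samples per platform, got WGS={wgs.shape[1]} "
            f"Amplicon={amp.shape[1]}"
        )
        logger.warning("KS platform check skipped: %s", reason)
        return KsReport(rank=norm.rank, table=pd.DataFrame(), skipped=True,
                        reason=reason)
    rows = []
    for level in norm.values.index:
        res = stats.ks_2samp(wgs.loc[level], amp.loc[level],
                             alternative="two-sided")
        rows.append((level, res.statistic, res.pvalue))
    table = pd.DataFrame(rows, columns=[norm.rank, "statistic", "p_value"])
    table = table.set_index(norm.rank)
    return KsReport(rank=norm.rank, table=table)
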