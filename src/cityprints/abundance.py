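"""Balanced-subsample differential abundance with Tukey letter patterns.

The city sample sizes are strongly unbalanced, so each replicate draws an
equal number of samples per city (without replacement), runs a one-way
fixed-effects ANOVA per taxon level on the normalized values, controls the
false discovery rate across levels with Benjamini-Hochberg inside the
replicate, and encodes Tukey honest-significant-difference all-pairs
outcomes as compact letters per city.  Over many replicates the per-level
occurrence counts of each letter pattern, with the min/mean/max of the
significant ANOVA p-values, summarize which taxa separate which cities.

Letter encoding over the declared city order: the first city gets 'a'; each
subsequent city reuses the letter of the earliest city it is NOT
significantly different from, otherwise takes the next unused letter.
Non-transitive significance triples cannot be lettered and fall in class
``other``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PreconditionError
from .preprocess import NormalizedTable
from .rng import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "PATTERNS",
    "letter_pattern",
    "balanced_subsample",
    "anova_tukey_replicate",
    "replicate_summary",
    "TukeySummary",
]

#: Pattern classes tallied in the replicate summary (three-city case).
PATTERNS = ("a-b-c", "a-a-b", "a-b-b", "a-b-a", "other")


def letter_pattern(bits) -> str:
    """Compact letter pattern from pairwise significance bits.

    ``bits[(i, j)]`` (i < j, city positions in declared order) is True when
    cities i and j differ significantly.  Returns e.g. ``"a-b-c"``; a
    non-transitive combination returns ``"other"``.
    """
    k = max(max(i, j) for i, j in bits) + 1
    letters = [None] * k
    letters[0] = "a"
    next_letter = 1
    for j in range(1, k):
        assigned = None
        for i in range(j):
            key = (i, j)
            if not bits[key]:
                assigned = letters[i]
                break
        if assigned is None:
            assigned = chr(ord("a") + next_letter)
            next_letter += 1
        letters[j] = assigned
    # consistency: equal letters must be non-significant pairs and vice versa
    for (i, j), sig in bits.items():
        same = letters[i] == letters[j]
        if same == sig:
            return "other"
    return "-".join(letters)


def balanced_subsample(norm: NormalizedTable, n: int, seed=0,
                       rng=None) -> NormalizedTable:
    """Uniform without-replacement draw of ``n`` samples per city.

    Cities already at exactly ``n`` samples are passed through whole.
    """
    if rng is None:
        rng = stage_rng(seed, "balanced_subsample")
    cols = []
    for city in norm.cities():
        ids = np.asarray(norm.meta.index[norm.meta["city"] == city])
        if len(ids) < n:
            raise PreconditionError(
                f"city {city!r} has {len(ids)} samples, fewer than n={n}"
            )
        if len(ids) == n:
            cols.extend(ids)
        else:
            cols.extend(ids[rng.choice(len(ids), size=n, replace=False)])
    return replace(norm, values=norm.values[cols], meta=norm.meta.loc[cols])


def _anova_arrays(groups):
    """Vectorized one-way ANOVA over levels. groups: list of level x n arrays."""
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    total_n = ns.sum()
    means = np.stack([g.mean(axis=1) for g in groups])          # k x levels
    grand = (means * ns[:, None]).sum(axis=0) / total_n
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = np.stack(
        [((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means)]
    ).sum(axis=0)
    df1, df2 = k - 1, total_n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    # degenerate within-group variance
    zero_w = ssw == 0
    p[zero_w & (ssb > 0)] = 0.0
    skipped = zero_w & (ssb == 0)
    p[skipped] = np.nan
    return means, ssw, p, df2, skipped


def anova_tukey_replicate(
    balanced: NormalizedTable,
    fdr: float = 0.01,
    tukey_alpha: float = 0.01,
    adjusted_p: bool = False,
) -> pd.DataFrame:
    """One balanced replicate: per-level ANOVA p, BH selection, Tukey letters.

    Returns a frame indexed by level with columns ``p_value``, ``selected``,
    ``pattern`` (None when unselected), and optionally the Tukey-adjusted
    p-value of each city pair.  Requires balanced groups with >= 2 samples
    per city.
    """
    cities = balanced.cities()
    if len(cities) < 2:
        raise PreconditionError("need >= 2 cities")
    groups = []
    for city in cities:
        cols = balanced.meta.index[balanced.meta["city"] == city]
        g = balanced.values[list(cols)].to_numpy(dtype=float)
        if g.shape[1] < 2:
            raise PreconditionError(f"city {city!r} has < 2 samples")
        groups.append(g)
    sizes = {g.shape[1] for g in groups}
    if len(sizes) != 1:
        raise PreconditionError("groups are not balanced")
    n = sizes.pop()
    k = len(groups)

    means, ssw, p, df2, skipped = _anova_arrays(groups)
    levels = balanced.values.index
    if skipped.any():
        logger.warning("%d levels skipped (zero variance everywhere)",
                       int(skipped.sum()))

    usable = ~skipped
    selected = np.zeros(len(levels), dtype=bool)
    if usable.any():
        selected[usable] = multipletests(p[usable], alpha=fdr,
                                         method="fdr_bh")[0]

    mse = ssw / df2
    qcrit = stats.studentized_range.ppf(1 - tukey_alpha, k, df2)
    patterns = [None] * len(levels)
    pair_keys = [(i, j) for i in range(k) for j in range(i + 1, k)]
    adj = {key: np.full(len(levels), np.nan) for key in pair_keys} if adjusted_p else None
    for idx in np.nonzero(selected)[0]:
        bits = {}
        for key in pair_keys:
            i, j = key
            diff = abs(means[i, idx] - means[j, idx])
            se = np.sqrt(mse[idx] / n)
            if se == 0:
                bits[key] = diff > 0
                if adjusted_p:
                    adj[key][idx] = 0.0 if diff > 0 else 1.0
                continue
            q = diff / se
            bits[key] = q > qcrit
            if adjusted_p:
                adj[key][idx] = float(stats.studentized_range.sf(q, k, df2))
        patterns[idx] = letter_pattern(bits)

    out = pd.DataFrame(
        {"p_value": p, "selected": selected, "pattern": patterns},
        index=levels,
    )
    if adjusted_p:
        for (i, j), values in adj.items():
            out[f"tukey_p_{cities[i]}_vs_{cities[j]}"] = values
    return out


@dataclass
class TukeySummary:
    """Per-level, per-pattern tallies over balanced-subsample replicates."""

    rank: str
    table: pd.DataFrame        # (level, pattern) -> count, p_min, p_mean, p_max
    replicates: int
    subsample_size: int
    fdr: float
    tukey_alpha: float
    city_order: tuple
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()


def replicate_summary(
    norm: NormalizedTable,
    replicates: int = 5000,
    n: int = 18,
    fdr: float = 0.01,
    tukey_alpha: float = 0.01,
    seed: int = 0,
) -> TukeySummary:
    """Tally Tukey letter patterns over repeated balanced subsamples.

    A replicate contributes to a level's tally only when the level survives
    the within-replicate BH selection, so pattern counts per level sum to at
    most ``replicates``.  The p-value summaries are over the ANOVA p-values
    of the counted occurrences.
    """
    if replicates < 1:
        raise PreconditionError("replicates must be >= 1")
    rng = stage_rng(seed, "replicate_summary")
    cities = norm.cities()
    k = len(cities)
    levels = norm.values.index
    city_cols = {
        c: norm.values[
            list(norm.meta.index[norm.meta["city"] == c])
        ].to_numpy(dtype=float)
        for c in cities
    }
    for c, g in city_cols.items():
        if g.shape[1] < n:
            raise PreconditionError(
                f"city {c!r} has {g.shape[1]} samples, fewer than n={n}"
            )
    df2 = k * n - k
    qcrit = stats.studentized_range.ppf(1 - tukey_alpha, k, df2)
    pair_keys = [(i, j) for i in range(k) for j in range(i + 1, k)]

    counts = {pat: np.zeros(len(levels), dtype=int) for pat in PATTERNS}
    p_sums = {pat: np.zeros(len(levels)) for pat in PATTERNS}
    p_min = {pat: np.full(len(levels), np.inf) for pat in PATTERNS}
    p_max = {pat: np.full(len(levels), -np.inf) for pat in PATTERNS}

    for _ in range(int(replicates)):
        groups = []
        for c in cities:
            g = city_cols[c]
            if g.shape[1] == n:
                groups.append(g)
            else:
                idx = rng.choice(g.shape[1], size=n, replace=False)
                groups.append(g[:, idx])
        means, ssw, p, _, skipped = _anova_arrays(groups)
        usable = ~skipped
        if not usable.any():
            continue
        selected = np.zeros(len(levels), dtype=bool)
        selected[usable] = multipletests(p[usable], alpha=fdr,
                                         method="fdr_bh")[0]
        mse = ssw / df2
        for idx in np.nonzero(selected)[0]:
            se = np.sqrt(mse[idx] / n)
            bits = {}
            for key in pair_keys:
                i, j = key
                diff = abs(means[i, idx] - means[j, idx])
                bits[key] = (diff > 0) if se == 0 else (diff / se > qcrit)
            pat = letter_pattern(bits)
            if pat not in counts:          # a-a-a etc. -> not tallied
                continue
            counts[pat][idx] += 1
            p_sums[pat][idx] += p[idx]
            p_min[pat][idx] = min(p_min[pat][idx], p[idx])
            p_max[pat][idx] = max(p_max[pat][idx], p[idx])

    rows = []
    for level_i, level in enumerate(levels):
        for pat in PATTERNS:
            c = counts[pat][level_i]
            rows.append(
                {
                    "level": level,
                    "pattern": pat,
                    "count": int(c),
                    "p_min": p_min[pat][level_i] if c else np.nan,
                    "p_mean": p_sums[pat][level_i] / c if c else np.nan,
                    "p_max": p_max[pat][level_i] if c else np.nan,
                }
            )
    table = pd.DataFrame(rows).set_index(["level", "pattern"])
    return TukeySummary(
        rank=norm.rank,
        table=table,
        replicates=int(replicates),
        subsample_size=int(n),
        fdr=float(fdr),
        tukey_alpha=float(tukey_alpha),
        city_order=tuple(cities),
        seed=int(seed),
    )
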