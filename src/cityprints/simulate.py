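"""Synthetic three-city OTU datasets with known ground truth.

The generator emulates the structure of an urban-subway 16S survey: a taxon
catalogue split into taxa shared by all cities plus small city-specific sets,
strongly unbalanced sample sizes, heterogeneous library sizes, and a WGS /
Amplicon platform covariate.  Counts follow a compound Dirichlet-multinomial
scheme: each sample's taxon proportions are its city's mean profile perturbed
by a Dirichlet draw (overdispersion), then counts are multinomial at the
sample's library size.  Zero overdispersion degenerates to exact multinomial
sampling from the city profile.

City effects are planted on a designated subset of mid-abundance shared taxa:
city ``k`` (0-based, in declared city order) multiplies those taxa by
``effect_size ** (k - (n_cities - 1) / 2)`` before renormalisation, so
consecutive cities differ by the stated factor and ``effect_size == 1`` is
the exchangeable null.  The multipliers are centred and the effect taxa are
drawn from the middle of the abundance ranking so that compositional
renormalisation does not swallow the planted log-fold changes (multiplying
dominant taxa would mostly rescale the whole vector instead).  By default the platform
covariate has no distributional effect; ``platform_shift`` plants one so the
platform-equality check can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .datatypes import Lineage, OtuDataset, SampleMeta
from .errors import PreconditionError
from .rng import stage_rng

__all__ = ["CityProfileSpec", "make_spec", "simulate_dataset", "write_spec", "read_spec"]

DEFAULT_CITIES = ("Boston", "NewYork", "Sacramento")
#: Effective per-city sample sizes of the three-city subway survey.
DEFAULT_N_PER_CITY = (134, 777, 18)


@dataclass
class CityProfileSpec:
    """Full description of a synthetic three-city community."""

    cities: tuple
    taxa: list
    profiles: pd.DataFrame            # taxon x city mean relative abundances
    shared_taxa: list
    specific_taxa: dict               # city -> list of taxa private to it
    effect_taxa: list                 # shared taxa carrying the planted effect
    effect_size: float
    overdispersion: float
    n_per_city: dict                  # city -> sample count
    library_size_range: dict          # city -> (lo, hi) inclusive
    amplicon_frac: dict               # city -> fraction of Amplicon samples
    platform_shift: float = 0.0
    lineage_share_frac: float = 0.25
    seed: int = 0

    def validate(self) -> "CityProfileSpec":
        p = self.profiles
        if (p.to_numpy() < 0).any():
            raise PreconditionError("negative mean abundance in spec")
        sums = p.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0):
            raise PreconditionError("city mean abundance vectors must sum to 1")
        for city in self.cities:
            for t in self.shared_taxa:
                if p.loc[t, city] <= 0:
                    raise PreconditionError(
                        f"shared taxon {t!r} has zero mean in {city!r}"
                    )
        if self.effect_size < 1:
            raise PreconditionError("effect_size must be >= 1")
        if self.overdispersion < 0:
            raise PreconditionError("overdispersion must be >= 0")
        for city, n in self.n_per_city.items():
            if n < 1:
                raise PreconditionError(f"n_per_city[{city!r}] must be >= 1")
        return self


def make_spec(
    n_shared: int = 19,
    n_specific_per_city=(2, 2, 2),
    effect_size: float = 1.0,
    n_per_city=DEFAULT_N_PER_CITY,
    seed: int = 0,
    cities=DEFAULT_CITIES,
    n_effect_taxa: int = 5,
    overdispersion: float = 0.02,
    library_size_range=(20_000, 100_000),
    amplicon_frac=(0.75, 0.0, 0.0),
    platform_shift: float = 0.0,
    lineage_share_frac: float = 0.25,
) -> CityProfileSpec:
    """Build a :class:`CityProfileSpec`.

    ``n_shared`` taxa are common to all cities with lognormal baseline
    abundances (sorted, most abundant first); each city additionally owns
    ``n_specific_per_city[k]`` private taxa.  ``min(n_effect_taxa, n_shared)``
    mid-ranked shared taxa are the planted-effect set.  ``effect_size == 1``
    with no private taxa yields identical city profiles (the exchangeable
    null).
    """
    if n_shared < 1:
        raise PreconditionError("n_shared must be >= 1")
    if effect_size < 1:
        raise PreconditionError("effect_size must be >= 1 (1 = null)")
    n_specific_per_city = tuple(int(v) for v in n_specific_per_city)
    if any(v < 0 for v in n_specific_per_city):
        raise PreconditionError("n_specific_per_city entries must be >= 0")
    if len(n_specific_per_city) != len(cities) or len(n_per_city) != len(cities):
        raise PreconditionError("per-city argument lengths must match cities")

    rng = stage_rng(seed, "make_spec")
    shared = [f"Taxon{i:03d}" for i in range(n_shared)]
    specific = {}
    idx = n_shared
    for city, k in zip(cities, n_specific_per_city):
        specific[city] = [f"Taxon{i:03d}" for i in range(idx, idx + k)]
        idx += k
    taxa = shared + [t for c in cities for t in specific[c]]

    # lognormal baseline over shared taxa; private taxa split a 5% mass slice
    base = np.sort(rng.lognormal(mean=0.0, sigma=1.0, size=n_shared))[::-1]
    base /= base.sum()
    n_effect = min(n_effect_taxa, n_shared)
    start = max(0, (n_shared - n_effect) // 2)
    effect_taxa = shared[start : start + n_effect]

    offset = (len(cities) - 1) / 2.0
    profiles = pd.DataFrame(0.0, index=pd.Index(taxa, name="taxon"),
                            columns=list(cities))
    for k, city in enumerate(cities):
        vec = pd.Series(0.0, index=taxa)
        vec[shared] = base
        for t in effect_taxa:
            vec[t] *= effect_size ** (k - offset)
        own = specific[city]
        if own:
            vec[shared] *= 0.95 / vec[shared].sum()
            vec[own] = 0.05 / len(own)
        else:
            vec[shared] /= vec[shared].sum()
        profiles[city] = vec

    return CityProfileSpec(
        cities=tuple(cities),
        taxa=taxa,
        profiles=profiles,
        shared_taxa=shared,
        specific_taxa=specific,
        effect_taxa=effect_taxa,
        effect_size=float(effect_size),
        overdispersion=float(overdispersion),
        n_per_city={c: int(n) for c, n in zip(cities, n_per_city)},
        library_size_range={c: tuple(int(v) for v in library_size_range)
                            for c in cities},
        amplicon_frac={c: float(f) for c, f in zip(cities, amplicon_frac)},
        platform_shift=float(platform_shift),
        lineage_share_frac=float(lineage_share_frac),
        seed=int(seed),
    ).validate()


def _make_lineages(taxa, share_frac: float, rng) -> list:
    """Distinct (order, family, genus) per taxon; a fraction share higher ranks."""
    lineages = []
    order_name, family_name = None, None
    for i, taxon in enumerate(taxa):
        share = i > 0 and rng.random() < share_frac
        if not share or order_name is None:
            order_name = f"Order{i:03d}"
            family_name = f"Family{i:03d}"
        lineages.append(
            Lineage(
                names={
                    "kingdom": "Bacteria",
                    "phylum": f"Phylum{i % 7:02d}",
                    "class": f"Class{i % 11:02d}",
                    "order": order_name,
                    "family": family_name,
                    "genus": f"Genus_{taxon}",
                    "species": None,
                }
            )
        )
    return lineages


def simulate_dataset(spec: CityProfileSpec, seed=None) -> OtuDataset:
    """Draw one OTU dataset from ``spec``; same spec + seed gives identical counts."""
    spec.validate()
    root = spec.seed if seed is None else int(seed)
    rng = stage_rng(root, "simulate_dataset")

    lineages = _make_lineages(spec.taxa, spec.lineage_share_frac, rng)
    n_taxa = len(spec.taxa)
    columns, metas, count_cols = [], [], []
    for city in spec.cities:
        p_city = spec.profiles[city].to_numpy()
        lo, hi = spec.library_size_range[city]
        n = spec.n_per_city[city]
        frac = spec.amplicon_frac[city]
        for j in range(n):
            platform = "Amplicon" if rng.random() < frac else "WGS"
            lib = int(rng.integers(lo, hi + 1))
            p = p_city.copy()
            if platform == "Amplicon" and spec.platform_shift != 0.0:
                half = n_taxa // 2
                p[:half] = p[:half] * 2.0**spec.platform_shift
                p = p / p.sum()
            if spec.overdispersion > 0:
                support = p > 0
                alpha = p[support] / spec.overdispersion
                drawn = rng.dirichlet(alpha)
                p = np.zeros_like(p)
                p[support] = drawn
            counts = rng.multinomial(lib, p)
            sid = f"{city[:3]}_{j:04d}"
            columns.append(sid)
            metas.append(SampleMeta(sample_id=sid, city=city, platform=platform))
            count_cols.append(counts)

    counts = pd.DataFrame(
        np.column_stack(count_cols),
        index=pd.Index([f"OTU_{t}" for t in spec.taxa], name="otu_id"),
        columns=columns,
        dtype="int64",
    )
    return OtuDataset(counts=counts, lineages=lineages, samples=metas).validate()


def write_spec(spec: CityProfileSpec, path) -> None:
    """Serialize a spec to flat YAML (profiles as taxon -> city -> value)."""
    payload = asdict(spec)
    payload["profiles"] = {
        t: {c: float(spec.profiles.loc[t, c]) for c in spec.cities}
        for t in spec.taxa
    }
    payload["cities"] = list(spec.cities)
    payload["library_size_range"] = {
        c: list(v) for c, v in spec.library_size_range.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_spec(path) -> CityProfileSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cities = tuple(payload["cities"])
    taxa = list(payload["taxa"])
    profiles = pd.DataFrame(
        [[payload["profiles"][t][c] for c in cities] for t in taxa],
        index=pd.Index(taxa, name="taxon"),
        columns=list(cities),
    )
    payload["profiles"] = profiles
    payload["cities"] = cities
    payload["library_size_range"] = {
        c: tuple(v) for c, v in payload["library_size_range"].items()
    }
    return CityProfileSpec(**payload).validate()
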