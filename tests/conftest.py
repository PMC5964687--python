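import numpy as np
import pandas as pd
import pytest

import cityprints as cp


@pytest.fixture(scope="session")
def small_dataset():
    """Three-city dataset with planted effects, small enough for every stage."""
    spec = cp.make_spec(
        n_shared=12,
        n_specific_per_city=(2, 2, 2),
        effect_size=4.0,
        n_per_city=(30, 40, 18),
        library_size_range=(5_000, 20_000),
        seed=11,
    )
    return spec, cp.simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    """Common-level normalized genus table of the small dataset."""
    _, ds = small_dataset
    table = cp.aggregate_to_rank(ds, "genus")
    common, _ = cp.common_levels(cp.split_by_city(table))
    return cp.normalize_log_cpm(cp.restrict_to_common(table, common))


def make_two_city_norm(n_per_city=30, n_levels=10, shift=10.0, seed=0,
                       cities=("A", "B"), shuffle_labels=False):
    """Synthetic NormalizedTable with a constant log2 shift between cities."""
    rng = np.random.default_rng(seed)
    blocks, metas = [], []
    for k, city in enumerate(cities):
        block = rng.normal(size=(n_levels, n_per_city))
        block[: n_levels // 2] += k * shift
        blocks.append(block)
        metas += [(f"{city}{j}", city, "WGS") for j in range(n_per_city)]
    values = pd.DataFrame(
        np.hstack(blocks),
        index=[f"L{i}" for i in range(n_levels)],
        columns=[m[0] for m in metas],
    )
    meta = pd.DataFrame(
        {"city": [m[1] for m in metas], "platform": [m[2] for m in metas]},
        index=pd.Index([m[0] for m in metas], name="sample_id"),
    )
    if shuffle_labels:
        meta["city"] = rng.permutation(meta["city"].to_numpy())
    return cp.NormalizedTable(rank="genus", values=values, meta=meta)
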