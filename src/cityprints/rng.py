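"""Seeding policy: one root seed, independent substreams per pipeline stage.

Every stochastic stage derives its generator from the root seed plus a stable
hash of the stage name.  Changing the replicate count of one stage therefore
never perturbs the draws of another, and reruns of a single stage reproduce
the full-pipeline result.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]

_MOD = 2**31


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic 31-bit child seed for ``stage`` under root ``seed``."""
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    return (int.from_bytes(digest[:4], "little") ^ (seed % _MOD)) % _MOD


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for one named stage, independent of all other stages."""
    return np.random.default_rng(
        np.random.SeedSequence([seed % _MOD, stage_seed(seed, stage)])
    )
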