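"""Core domain types: taxonomic lineages, sample metadata, OTU datasets.

An :class:`OtuDataset` bundles the three pieces every downstream stage needs:
a non-negative integer OTU-by-sample count matrix, one greengenes-style
:class:`Lineage` per OTU row, and per-sample metadata (city of origin and
sequencing platform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Canonical greengenes rank order, prefix -> rank name.
RANK_PREFIXES = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
CANONICAL_RANKS = tuple(RANK_PREFIXES.values())

#: Ranks at which OTU counts are aggregated for the cross-city analyses.
AGGREGATION_RANKS = ("order", "family", "genus")

PLATFORMS = ("WGS", "Amplicon")


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage parsed from a greengenes-style string.

    ``names[rank]`` is ``None`` when the rank token was absent or empty
    (e.g. a bare ``o__``); an empty-string level name never occurs.
    """

    names: dict

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        names: dict = {rank: None for rank in CANONICAL_RANKS}
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            if len(token) >= 3 and token[1:3] == "__":
                rank = RANK_PREFIXES.get(token[0].lower())
                name = token[3:].strip()
            else:
                rank, name = None, None
            if rank is not None:
                names[rank] = name if name else None
        return cls(names=names)

    def get(self, rank: str):
        if rank not in CANONICAL_RANKS:
            raise KeyError(f"unknown taxonomic rank {rank!r}")
        return self.names.get(rank)

    def has(self, rank: str) -> bool:
        return self.get(rank) is not None

    def to_string(self) -> str:
        """Render back to a greengenes-style string (empty token for missing)."""
        parts = []
        for prefix, rank in RANK_PREFIXES.items():
            name = self.names.get(rank)
            parts.append(f"{prefix}__{name if name is not None else ''}")
        return "; ".join(parts)


@dataclass(frozen=True)
class SampleMeta:
    """City label and sequencing platform for one sample."""

    sample_id: str
    city: str
    platform: str

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"sample {self.sample_id!r}: platform {self.platform!r} "
                f"not in {PLATFORMS}"
            )
        if not self.city:
            raise ValidationError(f"sample {self.sample_id!r}: empty city label")


@dataclass
class OtuDataset:
    """OTU x sample count matrix plus lineages and (optional) sample metadata.

    ``counts`` rows are OTU ids, columns sample ids.  ``samples`` may be empty
    until metadata is attached with :func:`attach_metadata`.
    """

    counts: pd.DataFrame
    lineages: list = field(default_factory=list)
    samples: list = field(default_factory=list)

    def validate(self, require_metadata: bool = True) -> "OtuDataset":
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate OTU ids in count matrix")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("non-integer counts in OTU table")
            values = values.astype(np.int64)
        if (values < 0).any():
            raise ValidationError("negative counts in OTU table")
        if len(self.lineages) != c.shape[0]:
            raise ValidationError(
                f"{len(self.lineages)} lineages for {c.shape[0]} OTU rows"
            )
        if require_metadata:
            ids = [m.sample_id for m in self.samples]
            if len(set(ids)) != len(ids):
                raise ValidationError("duplicate sample_id in metadata")
            if set(ids) != set(c.columns):
                raise ValidationError("metadata samples do not match count columns")
            if not any(m.city for m in self.samples):
                raise ValidationError("no city label present")
        return self

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def cities(self) -> list:
        """Distinct city labels in metadata order of first appearance."""
        seen: dict = {}
        for m in self.samples:
            seen.setdefault(m.city, None)
        return list(seen)

    def metadata_frame(self) -> pd.DataFrame:
        """Per-sample metadata as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            {
                "city": [m.city for m in self.samples],
                "platform": [m.platform for m in self.samples],
            },
            index=pd.Index([m.sample_id for m in self.samples], name="sample_id"),
        )


def attach_metadata(dataset: OtuDataset, samples: list) -> OtuDataset:
    """Join metadata onto a count-only dataset.

    Samples present on only one side of the join are dropped with a warning;
    the returned dataset keeps the count-matrix column order.
    """
    by_id = {}
    for m in samples:
        if m.sample_id in by_id:
            raise ValidationError(f"duplicate sample_id {m.sample_id!r} in metadata")
        by_id[m.sample_id] = m
    cols = [c for c in dataset.counts.columns if c in by_id]
    dropped_counts = [c for c in dataset.counts.columns if c not in by_id]
    dropped_meta = [s for s in by_id if s not in set(dataset.counts.columns)]
    if dropped_counts:
        logger.warning(
            "dropping %d count columns without metadata: %s",
            len(dropped_counts),
            ", ".join(dropped_counts[:5]) + ("..." if len(dropped_counts) > 5 else ""),
        )
    if dropped_meta:
        logger.warning(
            "dropping %d metadata rows without count columns: %s",
            len(dropped_meta),
            ", ".join(dropped_meta[:5]) + ("..." if len(dropped_meta) > 5 else ""),
        )
    out = OtuDataset(
        counts=dataset.counts[cols],
        lineages=list(dataset.lineages),
        samples=[by_id[c] for c in cols],
    )
    return out.validate()
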