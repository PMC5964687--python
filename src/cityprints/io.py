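"""Readers and writers for the QIIME-classic OTU TSV and metadata TSV dialects.

The OTU dialect is the text form of a biom table: an optional leading
``# Constructed from biom file`` comment, a header row whose first cell is
the OTU-id column and whose last column is ``taxonomy`` (case-insensitive),
then one row per OTU with integer counts and a greengenes lineage string.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import Lineage, OtuDataset, SampleMeta
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "write_result_table",
]


def read_otu_table(path) -> OtuDataset:
    """Read a QIIME-classic OTU TSV into an :class:`OtuDataset` (no metadata).

    Leading ``#``-comment lines are tolerated except that a line starting with
    ``#OTU`` is treated as the header (the classic dialect writes the header
    as ``#OTU ID``).
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#") and not line.lstrip("#").lower().startswith("otu"):
            continue
        header_idx = i
        break
    if header_idx is None:
        raise FormatError(f"{path}: no header row found")
    header = lines[header_idx].lstrip("#").split("\t")
    header = [h.strip() for h in header]
    if len(header) < 3:
        raise FormatError(f"{path}: header must have id, >=1 sample, taxonomy")
    if header[-1].lower() != "taxonomy":
        raise FormatError(
            f"{path}: last column is {header[-1]!r}, expected 'taxonomy'"
        )
    sample_ids = header[1:-1]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample id in header")

    otu_ids, rows, lineages = [], [], []
    for lineno, line in enumerate(lines[header_idx + 1 :], header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: {len(fields)} fields, expected {len(header)}"
            )
        otu_ids.append(fields[0].strip())
        row = []
        for col, cell in zip(sample_ids, fields[1:-1]):
            try:
                value = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {cell!r} "
                    f"in column {col!r}"
                ) from exc
            if value < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative count {cell!r} in column {col!r}"
                )
            if value != int(value):
                raise ValidationError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"in column {col!r}"
                )
            row.append(int(value))
        rows.append(row)
        lineages.append(Lineage.parse(fields[-1]))

    counts = pd.DataFrame(rows, index=pd.Index(otu_ids, name="otu_id"),
                          columns=sample_ids, dtype="int64")
    dataset = OtuDataset(counts=counts, lineages=lineages)
    dataset.validate(require_metadata=False)
    return dataset


def write_otu_table(dataset: OtuDataset, path, biom_comment: bool = True) -> None:
    """Write the QIIME-classic TSV consumed by :func:`read_otu_table`."""
    path = Path(path)
    with path.open("w") as fh:
        if biom_comment:
            fh.write("# Constructed from biom file\n")
        fh.write("#OTU ID\t" + "\t".join(dataset.counts.columns) + "\ttaxonomy\n")
        for otu_id, lineage in zip(dataset.counts.index, dataset.lineages):
            row = dataset.counts.loc[otu_id]
            fh.write(
                str(otu_id)
                + "\t"
                + "\t".join(str(int(v)) for v in row)
                + "\t"
                + lineage.to_string()
                + "\n"
            )


_PLATFORM_ALIASES = {"wgs": "WGS", "amplicon": "Amplicon"}


def read_metadata(path) -> list:
    """Read a sample metadata TSV (columns sample_id, city, platform)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    table.columns = [c.lstrip("#").strip().lower() for c in table.columns]
    for col in ("sample_id", "city", "platform"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    metas = []
    seen = set()
    for _, row in table.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        city = "" if pd.isna(row["city"]) else str(row["city"]).strip()
        if not city:
            raise ValidationError(f"{path}: empty city for sample {sid!r}")
        platform_raw = str(row["platform"]).strip()
        platform = _PLATFORM_ALIASES.get(platform_raw.lower())
        if platform is None:
            raise ValidationError(
                f"{path}: unknown platform {platform_raw!r} for sample {sid!r}"
            )
        metas.append(SampleMeta(sample_id=sid, city=city, platform=platform))
    return metas


def write_metadata(samples: list, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tcity\tplatform\n")
        for m in samples:
            fh.write(f"{m.sample_id}\t{m.city}\t{m.platform}\n")


def write_result_table(frame: pd.DataFrame, path, seed=None, config_hash=None,
                       index: bool = True, extra: str = "") -> None:
    """Write a result table as TSV with a one-line provenance comment."""
    path = Path(path)
    bits = []
    if seed is not None:
        bits.append(f"seed={seed}")
    if config_hash is not None:
        bits.append(f"config={config_hash}")
    if extra:
        bits.append(extra)
    with path.open("w") as fh:
        fh.write("# cityprints " + " ".join(bits) + "\n")
        frame.to_csv(fh, sep="\t", index=index)
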