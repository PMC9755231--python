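"""Tabular I/O and the joined study data model.

All on-disk formats are plain tab-separated text:

* OTU table — rows are OTUs, columns are samples, first column holds the
  OTU identifier, the header row holds sample identifiers.  Cells are
  non-negative numbers (raw counts or normalized abundances; absence is 0).
* Sample metadata — one row per sample with the columns
  ``sample_id, host_species, site_id, head_length_mm, head_width_mm,
  body_length_mm``.  Trait units are millimetres.
* Taxonomy — two columns, ``otu_id<TAB>phylum``.

Writers optionally emit a sibling provenance log (``<path>.prov``) with one
``key=value`` line per option so a run can be audited afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometry import Morphometrics

logger = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "sample_id",
    "host_species",
    "site_id",
    "head_length_mm",
    "head_width_mm",
    "body_length_mm",
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Parsed values violate a data-model invariant."""


@dataclass(frozen=True)
class OtuTable:
    """Non-negative abundance matrix, OTUs in rows and samples in columns.

    ``counts`` is a float DataFrame indexed by OTU id with sample ids as
    columns.  Values may be raw counts or normalized abundances; the class
    only enforces non-negativity and id uniqueness.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.isna().any().any():
            raise ValidationError("OTU table contains missing cells")
        if (df.to_numpy() < 0).any():
            raise ValidationError("OTU table contains negative abundances")
        df.index.name = "otu_id"
        df.columns.name = None

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[:, list(sample_ids)])

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.index]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(self.counts.loc[list(otu_ids), :])

    def relative(self) -> "OtuTable":
        """Per-sample relative abundances (columns sum to 1).

        All-zero samples are left as zeros rather than producing NaNs.
        """
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1.0)
        return OtuTable(self.counts.div(safe, axis=1))


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    host_species: str
    site_id: str
    morphometrics: Morphometrics


@dataclass
class Study:
    """OTU table joined with per-sample metadata.

    Only samples present in both inputs are retained; the ids of samples
    that were present in the table but lacked metadata (or vice versa) are
    kept in ``dropped_samples`` for auditability.
    """

    table: OtuTable
    metadata: pd.DataFrame  # indexed by sample_id, METADATA_COLUMNS[1:]
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    def species_groups(self) -> dict[str, list[str]]:
        """Sample ids grouped by host species (insertion order preserved)."""
        groups: dict[str, list[str]] = {}
        for sid in self.table.sample_ids:
            groups.setdefault(self.metadata.at[sid, "host_species"], []).append(sid)
        return groups

    def site_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for sid in self.table.sample_ids:
            groups.setdefault(self.metadata.at[sid, "site_id"], []).append(sid)
        return groups

    def species_labels(self) -> list[str]:
        return [self.metadata.at[s, "host_species"] for s in self.table.sample_ids]


def _read_header(path: Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if not first:
        raise FormatError(f"{path}: empty file")
    return first.split("\t")


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a tab-separated OTU-by-sample abundance table.

    The first column holds OTU ids; the header row holds sample ids.
    Duplicate ids, negative values and non-numeric cells are format errors.
    """
    path = Path(path)
    header = _read_header(path)
    sample_ids = header[1:]
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise FormatError(f"{path}: duplicate sample ids in header: {sorted(dup)}")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    raw.columns = sample_ids  # undo pandas' mangling of any duplicate names
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate OTU ids: {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at OTU {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    neg = numeric < 0
    if neg.any().any():
        r, c = np.argwhere(neg.to_numpy())[0]
        raise FormatError(
            f"{path}: negative abundance at OTU {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return OtuTable(numeric.astype(float))


def write_otu_table(
    table: OtuTable, path: str | Path, provenance: Mapping[str, object] | None = None
) -> None:
    path = Path(path)
    table.counts.to_csv(path, sep="\t")
    if provenance is not None:
        write_provenance(path, provenance)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the six-column sample metadata TSV (traits in mm, must be > 0)."""
    path = Path(path)
    header = _read_header(path)
    missing = [c for c in METADATA_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {missing}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "host_species": str, "site_id": str})
    records: list[SampleMetadata] = []
    for i, row in df.iterrows():
        traits = {}
        for col in METADATA_COLUMNS[3:]:
            val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(val) or val <= 0:
                raise ValidationError(
                    f"{path}: row {i + 2}: {col} must be a positive number, got {row[col]!r}"
                )
            traits[col] = float(val)
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                host_species=str(row["host_species"]),
                site_id=str(row["site_id"]),
                morphometrics=Morphometrics(
                    head_length_mm=traits["head_length_mm"],
                    head_width_mm=traits["head_width_mm"],
                    body_length_mm=traits["body_length_mm"],
                ),
            )
        )
    return records


def write_metadata(
    records: Iterable[SampleMetadata],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    rows = [
        {
            "sample_id": r.sample_id,
            "host_species": r.host_species,
            "site_id": r.site_id,
            "head_length_mm": r.morphometrics.head_length_mm,
            "head_width_mm": r.morphometrics.head_width_mm,
            "body_length_mm": r.morphometrics.body_length_mm,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)
    if provenance is not None:
        write_provenance(path, provenance)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column ``otu_id<TAB>phylum`` map (header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: taxonomy must have exactly 2 columns, got {df.shape[1]}")
    if list(df.iloc[0]) == ["otu_id", "phylum"]:
        df = df.iloc[1:]
    if df[0].duplicated().any():
        dups = sorted(df[0][df[0].duplicated()].unique())
        raise FormatError(f"{path}: otu_id mapped more than once: {dups}")
    return dict(zip(df[0], df[1]))


def write_taxonomy(
    taxonomy: Mapping[str, str],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tphylum\n")
        for otu, phylum in taxonomy.items():
            fh.write(f"{otu}\t{phylum}\n")
    if provenance is not None:
        write_provenance(path, provenance)


def write_provenance(path: str | Path, options: Mapping[str, object]) -> Path:
    """Write ``<path>.prov`` with one sorted ``key=value`` line per option."""
    prov_path = Path(str(path) + ".prov")
    with open(prov_path, "w", encoding="utf-8") as fh:
        for key in sorted(options):
            fh.write(f"{key}={options[key]}\n")
    return prov_path


def join_tables(table: OtuTable, meta: Iterable[SampleMetadata]) -> Study:
    """Join an OTU table with sample metadata on sample id.

    Samples missing from either side are warned about and dropped; zero
    overlap is an error.  The join never invents samples.
    """
    records = list(meta)
    by_id: dict[str, SampleMetadata] = {}
    for r in records:
        if r.sample_id in by_id:
            raise ValidationError(f"duplicate metadata row for sample {r.sample_id!r}")
        by_id[r.sample_id] = r
    kept = [s for s in table.sample_ids if s in by_id]
    if not kept:
        raise ValidationError("no overlapping samples between OTU table and metadata")
    dropped = [s for s in table.sample_ids if s not in by_id]
    dropped += [r.sample_id for r in records if r.sample_id not in set(table.sample_ids)]
    if dropped:
        logger.warning("join dropped %d sample(s) without a match: %s", len(dropped), dropped)
    meta_df = pd.DataFrame(
        {
            "host_species": [by_id[s].host_species for s in kept],
            "site_id": [by_id[s].site_id for s in kept],
            "head_length_mm": [by_id[s].morphometrics.head_length_mm for s in kept],
            "head_width_mm": [by_id[s].morphometrics.head_width_mm for s in kept],
            "body_length_mm": [by_id[s].morphometrics.body_length_mm for s in kept],
        },
        index=pd.Index(kept, name="sample_id"),
    )
    return Study(table=table.subset_samples(kept), metadata=meta_df, dropped_samples=dropped)
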